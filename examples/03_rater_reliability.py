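"""Simulated rater panels and the agreement statistics that qualify them.

Two training raters produce 'fair' chance-corrected agreement (kappa near
.40); a four-rater panel over 30 narratives yields the average-measures
reliability ICC(2,4) used to qualify a beta-test panel.
"""

import numpy as np

from sitr import GeneratorSpec, cohens_kappa, icc_2k, sample_corpus
from sitr.synthetic import rater_agreement

corpus = sample_corpus(
    GeneratorSpec(subset_sizes={"A": 60, "B": 130, "C": 130, "D": 60}), seed=3
)
kappa = rater_agreement(corpus.judgments)
print(f"mean pairwise Cohen's kappa across two raters: {kappa:.3f}")

sev_a = [corpus.judgments[c][0].severity for c in sorted(corpus.judgments)]
sev_b = [corpus.judgments[c][1].severity for c in sorted(corpus.judgments)]
r = cohens_kappa(sev_a, sev_b)
print(f"severity-only kappa: {r.value:.3f} ({r.band})")

# a 30-narrative, 4-rater panel: two-way random effects, average measures
rng = np.random.default_rng(3)
truth = rng.uniform(2.2, 5.8, size=30)
panel = np.clip(np.round(truth[:, None] + rng.normal(0, 0.4, (30, 4))), 1, 7)
icc = icc_2k(panel)
print(f"ICC(2,4) = {icc.value:.3f}, F({icc.df1:.0f},{icc.df2:.0f}) = "
      f"{icc.F:.2f}, p = {icc.p:.2g}")
print("(values above ~.75 indicate the panel judges consistently)")
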