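"""Incremental validity by hierarchical regression.

Does a text-derived severity score explain outcome variance beyond an
existing questionnaire?  Block 1 enters the questionnaire; block 2 adds
the text score; the R-squared change and its F test quantify the added
explanatory value.
"""

import numpy as np

from sitr import assumption_checks, hierarchical_regression, pearson

rng = np.random.default_rng(42)
n = 50
latent = rng.normal(size=n)                      # true self-injury severity
questionnaire = 0.5 * latent + rng.normal(size=n)
text_score = 0.7 * latent + rng.normal(size=n)
frequency = 0.6 * latent + rng.normal(size=n)    # weekly self-injury count

rep = assumption_checks(frequency)
print(f"normality check on the outcome: W = {rep.shapiro['all'][0]:.3f}, "
      f"p = {rep.shapiro['all'][1]:.3f} "
      f"({'violated' if rep.normality_violated else 'ok'})")

r, p = pearson(text_score, frequency)
print(f"text score vs frequency: r = {r:.2f} (p = {p:.3g})")

steps = hierarchical_regression(
    frequency, [{"questionnaire": questionnaire}, {"text_score": text_score}]
)
for i, s in enumerate(steps, start=1):
    print(f"step {i}: R2 = {s.r_squared:.3f}, dR2 = {s.delta_r_squared:.3f}, "
          f"F_change = {s.F_change:.2f} (p = {s.p_change:.3g})")
b = steps[1]
print(f"standardized beta of the text score at step 2: "
      f"{b.beta['text_score']:.2f}")
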