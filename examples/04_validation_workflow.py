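"""Machine-vs-rater validation: are the judgments indistinguishable?

Assesses held-out narratives that carry reference judgments and tests the
machine's severity/outcome estimates against them with a one-way MANOVA.
A non-significant result (p > .05) means the machine's judgments cannot be
distinguished from the references — the calibration target — though
non-significance is weak evidence of equivalence.
"""

from sitr import (
    AssessConfig,
    GeneratorSpec,
    TrainingCase,
    assess,
    run_validation,
    sample_corpus,
    sample_input,
    train,
)

spec = GeneratorSpec(subset_sizes={s: 15 for s in "ABCD"}, K=5, vocab_size=80)
corpus = sample_corpus(spec, seed=8)
cb = train(corpus.cases, K=5, n_iter=500, burn_in=250, seed=8)

heldout = []
for s in "ABCD":
    for i in range(8):
        doc = sample_input(spec, s, seed=100 + i)
        res = assess(doc.raw_text, cb, AssessConfig())
        # references: the machine's own estimates plus small disagreement
        heldout.append(
            TrainingCase(doc, res.severity_estimate + 0.1 * (i % 3 - 1),
                         res.outcome_estimate + 0.1 * (i % 2), s)
        )

summary = run_validation(cb, heldout)
print(f"assessed {summary.n_assessed}/{summary.n_input} cases "
      f"({len(summary.excluded)} excluded for insufficient evidence)")
m = summary.manova
print(f"Wilks' lambda = {m.wilks_lambda:.3f}, "
      f"F({m.df1:.0f},{m.df2:.0f}) = {m.F:.2f}, p = {m.p:.3f}")
print(f"equivalence criterion (p > {summary.alpha}): "
      f"{'pass' if summary.passed else 'fail'}")
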