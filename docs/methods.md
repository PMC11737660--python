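# Methods

This note documents the models, parameter choices, and numerical
conventions behind `sitr`, and what the synthetic evaluation does and does
not establish about real clinical text.

## Corpus model and labelling

A training case is one narrative plus a panel of rater judgments: 7-point
Likert ratings of case severity, intervention difficulty, and expected
negative treatment outcome, and a 1–5 ranking of five intervention domains
(traits/personality, thoughts, emotions, past environment, current
environment). Severity and difficulty ratings are strongly collinear in
panels of this kind, so they are pooled into one merged severity: the
arithmetic mean of all severity *and* difficulty values across raters.
(Averaging per rater first is equivalent when raters rate both; we average
the pooled values.) The merged severity and mean outcome partition cases
into the four subsets with inclusive thresholds — serious iff merged
severity ≥ 4.0, negative-outcome iff mean outcome ≥ 3.5. The thresholds
are configuration; the defaults are the midpoint-style pair that cleanly
separates typical subset judgment means (A 4.44/2.88, B 4.53/3.94,
C 3.30/2.55, D 3.58/3.65).

Tokenization is NFC-normalization followed by Unicode word-character
splitting with lowercasing; Korean text, being caseless, passes through
unchanged. A morphological analyzer for agglutinative languages can be
substituted via `register_tokenizer`; every downstream component sees only
the token sequence, so the analysis is tokenizer-agnostic. The default
stoplist and risk lexicon are plain-text files and fully user-replaceable.

## Topic models

Per-subset LDA is fit by collapsed Gibbs sampling with defaults α = 0.1,
β = 0.01, 1000 sweeps with 500 burn-in, K = 10. These are standard
sparse-topic defaults; all are exposed. Point estimates come from the
final count state rather than sample averaging — this keeps topic indices
stable for codebook construction and makes fits bit-reproducible per seed;
posterior-mean averaging over post-burn-in sweeps is available behind
`average_samples`. Proportion estimates are column means of the document
mixtures × 100, rounded half-up (`floor(x + 0.5)`), so printed codebooks
are platform-stable; they sum to 100 within ⌈K/2⌉ rounding slack. The
sampler's inner loop is numba-compiled; the kernel seeds its own RNG, so
two fits with the same inputs and seed are identical to the bit. UMass
document-co-occurrence coherence is provided purely as a model-selection
diagnostic.

## Codebook

Each topic contributes its top-n key tokens (default n = 20, minimum
topic-token weight 0.001; ties broken lexicographically). A token ranking
in several topics of one subset is housed in its maximum-weight topic so
the audit trail from any match back to one codebook entry is unambiguous.
Representativeness is within-subset min–max standardization of raw token
frequency to [0, 1] (all-equal frequencies score 1.0). Min–max was chosen
over z-scoring to keep additive scoring non-negative and to make a "+1"
bonus weight commensurate with doubling the strongest token's
contribution. Topic titles are user configuration (in practice they are
expert-assigned); defaults are `topic-<k>`. The codebook also stores each
subset's judgment summary (n, mean/SD merged severity and outcome; sample
SDs) and each training case's topic profile and consensus priority
ranking, serialized as schema-versioned JSON with a flat CSV export.

## Assessment

H1 scores each subset by summing, over distinct matched input token types
(first occurrence only — repetition must not accumulate, or score would
track verbosity), the entry's representativeness score plus at most one
bonus: w_pos (default 1.0) if the type is among the first three distinct
matched types globally, else w_risk (default 1.0) if it is risk-flagged; a
doubly eligible token receives the stronger bonus, never both. Subsets are
ranked by score, then match count, then the fixed severity-conservative
precedence B ≻ A ≻ D ≻ C — when the evidence cannot discriminate, the
machine errs toward the more concerning reading. Severity and outcome
estimates are the winning subset's stored means (subset-level retrieval);
the H2-matched case contributes only the priority ranking. H2 similarity
is cosine over the integer profile vectors — scale-free over
proportion-valued profiles — with ties resolved by more shared nonzero
topics, then smallest case id; an all-zero input profile has similarity 0
everywhere. Inputs with fewer than `min_matches = 3` distinct matched
types are refused ("insufficient evidence") rather than scored.

## Psychometrics

Cohen's kappa is computed from the contingency table with optional
linear/quadratic disagreement weights; 7-point judgments default to
unweighted, and Landis–Koch bands are attached. Note the unweighted-kappa
estimator is what makes "fair" (.21–.40) the typical regime for noisy
7-point panels. ICC is fixed to Shrout–Fleiss ICC(2,k): two-way random
effects, absolute agreement, average measures, computed from the two-way
ANOVA mean squares with its F test; the raw estimator can exceed 1 only
when its denominator goes negative (no-signal pathologies), and is
reported unclamped as standard implementations do. One-way MANOVA uses
Wilks' Λ = det(E)/det(E+H) with Rao's F approximation and univariate
follow-up Fs; with one DV it reduces exactly to one-way ANOVA.
Hierarchical regression reports per-step B, SE, standardized β, t, model
F, R², ΔR², and F_change = (ΔR²/q)/((1−R²)/(n−p−1)). Assumption checks
are Shapiro–Wilk per group and median-centered Levene. All of these are
implemented from their ANOVA/normal-equation decompositions (scipy
supplies distributions and the Shapiro/Levene tests) and are cross-checked
in the test suite against sklearn, pingouin, statsmodels, and brute-force
oracles at 1e-8.

## Synthetic corpora

The generator emulates the statistical shape of a small expert-labelled
clinical corpus: four subsets of sizes 26/62/64/26; document token counts
lognormal with mean 103.85 and SD 61.38 (moment-matched, clamped ≥ 5 —
positive and right-skewed, as token counts are); per-document topic
mixtures Dirichlet(0.3); topics uniform over disjoint round-robin slices
of the subset vocabulary. A single difficulty knob ω ∈ [0,1] sets the
fraction of each subset's vocabulary drawn from a pool shared by all four
subsets: ω = 0 gives disjoint vocabularies (easy), ω = 1 identical ones
(chance). True judgments are Gaussian around subset-conditional means
(the subset-conditional defaults above); simulated raters add Gaussian noise
(SD 0.4, set once by calibration search so two raters' mean pairwise kappa
is ≈ .40, the "fair" band), round, and clamp to 1–7. The (truth, panel)
pair is rejection-sampled until the merged judgments land in the
generating subset's partition region, so generating labels and judgment
labels always agree and subset counts are exact. Priority rankings
perturb a subset-typical base ranking (emotions first everywhere) and are
re-ranked; the consensus is the rank of mean ranks. All randomness flows
through `numpy` SeedSequences with disjoint spawn keys for corpus,
held-out inputs, and raters, so held-out inputs can never collide with
training documents and regeneration is bit-identical.

**What passing tests show — and don't.** Perfect recovery at ω = 0 and
graceful, monotone degradation as ω grows establish that the pipeline is
correctly wired end-to-end and that its accuracy tracks the real
discriminability of the vocabulary. They do not establish clinical
validity on real narratives: real language has no disjoint subset
vocabularies, morphology matters, raters have structured (not i.i.d.)
disagreement, and codebook quality depends on expert topic curation. The
synthetic results bound the machinery, not the construct.

## Evaluation sizes and numerical conventions

The acceptance script and heavy tests use 40 cases/subset, V = 400,
K = 10, 10 held-out inputs per subset, and 10 seeds per overlap level,
with 400 Gibbs sweeps in the sweep (1000 where a single fit is reported);
these sizes give stable means while keeping a full run in tens of seconds.
Ties anywhere (key tokens, topic housing, H1, H2) are broken
deterministically (lexicographic / fixed precedence), degenerate inputs
raise typed errors rather than returning NaNs, and every report and
serialized artifact is byte-stable for fixed inputs (timestamps appear
only when explicitly passed).

## Known limitations

No Korean morphological analyzer is bundled; the default tokenizer is a
reasonable stand-in for space-delimited text only. PDF report rendering is
not included (JSON/markdown carry the full content). The H1 bonus scheme
is additive and hand-weighted, not learned; `min_matches = 3` is a
conservative floor, not an optimized threshold. Longitudinal tracking of
repeated writings by one client is out of scope.
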