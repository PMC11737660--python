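"""Train the machine on a synthetic labelled corpus and assess a new writing.

Generates a four-subset corpus with disjoint subset vocabularies, fits one
10-topic LDA model per subset, builds the scored codebook, then runs the
two-tier assessment on a held-out narrative generated from subset B.
"""

from sitr import (
    AssessConfig,
    GeneratorSpec,
    SUBSET_SEMANTICS,
    assess,
    sample_corpus,
    sample_input,
    train,
)

spec = GeneratorSpec(subset_sizes={"A": 26, "B": 62, "C": 64, "D": 26})
corpus = sample_corpus(spec, seed=1)
print(f"training corpus: {len(corpus.cases)} labelled cases")

codebook = train(corpus.cases, seed=1)
print(f"codebook: {len(codebook.entries)} scored token entries over 4 subsets")

doc = sample_input(spec, "B", seed=99)
result = assess(doc.raw_text, codebook, AssessConfig())

print(f"\npredicted subset : {result.predicted_subset} "
      f"({SUBSET_SEMANTICS[result.predicted_subset]})")
print(f"severity estimate: {result.severity_estimate:.2f}  (1-7 scale; "
      "mean rater judgment of similar training cases)")
print(f"outcome estimate : {result.outcome_estimate:.2f}  (1-7; higher = "
      "more concern about a negative treatment outcome)")
print(f"matched case     : {result.matched_case_id} "
      f"(profile cosine {result.case_similarity:.3f})")
print("intervention priorities (1 = highest):")
for domain, rank in sorted(result.priority_ranking.items(), key=lambda kv: kv[1]):
    print(f"  {rank}. {domain}")
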