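"""Inspect the scored codebook: entries, representativeness, topic profiles.

Builds a small codebook, prints its highest-scoring entries for one
subset, and shows how an input's topic profile keeps unmatched topics at
zero — the object the H2 case match compares by cosine similarity.
"""

from sitr import GeneratorSpec, sample_corpus, topic_profile, train

spec = GeneratorSpec(subset_sizes={s: 15 for s in "ABCD"}, K=5, vocab_size=80)
corpus = sample_corpus(spec, seed=5)
cb = train(corpus.cases, K=5, n_iter=500, burn_in=250, seed=5)

print("top entries of subset A (token, rep score, topic, estimate):")
for e in sorted(cb.entries_for("A"), key=lambda e: -e.rep_score)[:5]:
    print(f"  {e.token:8s} {e.rep_score:.3f}  {e.topic_title:8s} "
          f"{e.proportion_estimate}%")

case = corpus.cases[0]
print(f"\ntopic profile of training case {case.case_id} "
      "(0 = no matching token for that topic):")
for title, value in case.profile.items():
    print(f"  {title:10s} {value}")

partial = list(case.document.tokens[:10])
print(f"\nprofile of only its first 10 tokens: "
      f"{topic_profile(partial, cb, case.subset)}")
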