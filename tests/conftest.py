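import pytest

from sitr.codebook import (
    Codebook,
    CaseProfile,
    CodebookEntry,
    SubsetSummary,
)
from sitr.corpus import SUBSETS
from sitr.pipeline import train
from sitr.synthetic import GeneratorSpec, sample_corpus

#: Judgment summaries of a typical four-subset training corpus, used as a
#: read-only fixture for severity/outcome retrieval tests.
SUBSET_SUMMARIES = {
    "A": SubsetSummary(26, 4.44, 0.38, 2.88, 0.26),
    "B": SubsetSummary(62, 4.53, 0.40, 3.94, 0.37),
    "C": SubsetSummary(64, 3.30, 0.52, 2.55, 0.52),
    "D": SubsetSummary(26, 3.58, 0.37, 3.65, 0.27),
}


def make_codebook(
    subset_tokens: dict[str, dict[str, float]],
    risk=(),
    titles: dict[str, dict[int, str]] | None = None,
    estimates: dict[str, dict[int, int]] | None = None,
    topic_of: dict[str, dict[str, int]] | None = None,
    case_profiles: dict[str, CaseProfile] | None = None,
) -> Codebook:
    """Hand-build a codebook: subset -> {token: rep_score}.

    Unless given, every token is housed in topic 0 ("topic-0", estimate
    100) of its subset.  All four subsets exist regardless.
    """
    titles = titles or {}
    estimates = estimates or {}
    topic_of = topic_of or {}
    entries = []
    full_titles: dict[str, dict[int, str]] = {}
    full_est: dict[str, dict[int, int]] = {}
    for s in SUBSETS:
        full_titles[s] = titles.get(s, {0: "topic-0"})
        full_est[s] = estimates.get(s, {0: 100})
        for tok, rep in sorted(subset_tokens.get(s, {}).items()):
            k = topic_of.get(s, {}).get(tok, min(full_titles[s]))
            entries.append(
                CodebookEntry(
                    subset=s,
                    token=tok,
                    rep_score=rep,
                    topic_index=k,
                    topic_title=full_titles[s][k],
                    proportion_estimate=full_est[s][k],
                    is_risk=tok in set(risk),
                )
            )
    return Codebook(
        entries=entries,
        subsets=dict(SUBSET_SUMMARIES),
        risk_lexicon=frozenset(risk),
        case_profiles=dict(case_profiles or {}),
        titles=full_titles,
        proportion_estimates=full_est,
    )


@pytest.fixture()
def h1_codebook():
    """The hand-tallied screening fixture: A={pain:.8, alone:.5},
    B={knife:.9, pain:.6}, risk={knife}."""
    cb = make_codebook(
        {"A": {"pain": 0.8, "alone": 0.5}, "B": {"knife": 0.9, "pain": 0.6}},
        risk={"knife"},
    )
    cb.case_profiles = {
        "caseB1": CaseProfile("caseB1", "B", {"topic-0": 100}, None),
        "caseA1": CaseProfile("caseA1", "A", {"topic-0": 100}, None),
        "caseC1": CaseProfile("caseC1", "C", {"topic-0": 0}, None),
        "caseD1": CaseProfile("caseD1", "D", {"topic-0": 0}, None),
    }
    return cb


@pytest.fixture(scope="session")
def small_spec():
    return GeneratorSpec(
        subset_sizes={"A": 12, "B": 12, "C": 12, "D": 12},
        K=5,
        vocab_size=100,
        overlap=0.0,
    )


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    return sample_corpus(small_spec, seed=11)


@pytest.fixture(scope="session")
def small_codebook(small_corpus):
    return train(
        small_corpus.cases,
        risk_lexicon={"a0001", "b0001"},
        K=5,
        n_iter=300,
        burn_in=150,
        seed=11,
    )
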