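"""The two-tier assessment of a single narrative.

H1 (lower tier) screens the input tokens against the codebook and
accumulates a weighted *probability score* per subset:

* each distinct input token type is scored at most once per subset, at its
  first occurrence (repetition does not accumulate);
* the base contribution is the token's representativeness score in that
  subset;
* the first three distinct token types that match *any* subset during the
  screening receive a position bonus ``w_pos`` on every subset where they
  match — in natural narratives the main points tend to precede elaboration;
* tokens in the risk lexicon (suicide-related terms, cutting instruments,
  signs of depression, trauma, personality pathology) receive ``w_risk``;
* a token eligible for both bonuses receives only the stronger one — a
  single "additional point" per matched token, never a stacked pair.

The subset with the highest score wins; exact score ties fall to the higher
match count, and residual ties to the severity-conservative precedence
B > A > D > C.  The winning subset's stored judgment summary supplies the
severity and outcome estimates.

H2 (higher tier) computes the input's topic profile within the winning
subset and retrieves the training case whose cached profile has the highest
cosine similarity; that case contributes the intervention-priority ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .codebook import Codebook, topic_profile
from .corpus import SUBSETS, SUBSET_SEMANTICS, filter_tokens, tokenize
from .errors import InsufficientEvidenceError

__all__ = [
    "Weights",
    "AssessConfig",
    "MatchEvent",
    "SubsetScore",
    "AssessmentResult",
    "match_tokens",
    "h1_select_subset",
    "h2_best_case",
    "assess",
]

#: Ranking precedence for exact ties: clinically conservative, preferring
#: the more severe / more concerning subset.
TIE_PRECEDENCE = ("B", "A", "D", "C")

#: How many leading distinct matched token types receive the position bonus.
N_POSITION_BONUS = 3


@dataclass(frozen=True)
class Weights:
    """Additive bonus magnitudes on the standardized [0, 1] score scale."""

    w_pos: float = 1.0
    w_risk: float = 1.0


@dataclass(frozen=True)
class AssessConfig:
    tokenizer: str = "default"
    stoplist: frozenset[str] = frozenset()
    weights: Weights = Weights()
    min_matches: int = 3


@dataclass(frozen=True)
class MatchEvent:
    input_position: int
    token: str
    subset: str
    base_rep_score: float
    position_bonus: float = 0.0
    risk_bonus: float = 0.0

    @property
    def contribution(self) -> float:
        return self.base_rep_score + self.position_bonus + self.risk_bonus


@dataclass
class SubsetScore:
    subset: str
    probability_score: float = 0.0
    match_count: int = 0
    match_events: list[MatchEvent] = field(default_factory=list)


@dataclass
class AssessmentResult:
    predicted_subset: str
    subset_scores: dict[str, SubsetScore]
    severity_estimate: float
    outcome_estimate: float
    input_profile: dict[str, int]
    matched_case_id: str
    case_similarity: float
    priority_ranking: Mapping[str, int] | None
    config: AssessConfig

    def to_dict(self) -> dict:
        """JSON-ready dict with stable key order."""
        return {
            "predicted_subset": self.predicted_subset,
            "subset_semantics": SUBSET_SEMANTICS[self.predicted_subset],
            "severity_estimate": self.severity_estimate,
            "outcome_estimate": self.outcome_estimate,
            "subset_scores": {
                s: {
                    "probability_score": sc.probability_score,
                    "match_count": sc.match_count,
                    "matched_tokens": [
                        {
                            "position": e.input_position,
                            "token": e.token,
                            "base": e.base_rep_score,
                            "position_bonus": e.position_bonus,
                            "risk_bonus": e.risk_bonus,
                        }
                        for e in sc.match_events
                    ],
                }
                for s, sc in sorted(self.subset_scores.items())
            },
            "input_profile": self.input_profile,
            "matched_case_id": self.matched_case_id,
            "case_similarity": self.case_similarity,
            "priority_ranking": dict(self.priority_ranking)
            if self.priority_ranking
            else None,
            "config": {
                "tokenizer": self.config.tokenizer,
                "w_pos": self.config.weights.w_pos,
                "w_risk": self.config.weights.w_risk,
                "min_matches": self.config.min_matches,
            },
        }


def match_tokens(
    input_tokens: Sequence[str],
    codebook: Codebook,
    weights: Weights = Weights(),
) -> dict[str, SubsetScore]:
    """Screen tokens against the codebook; return per-subset score ledgers.

    The input is scanned in order.  A token type is scored at most once per
    subset (at its first occurrence); the first ``N_POSITION_BONUS``
    distinct types that match anywhere get ``w_pos`` wherever they match,
    and risk-lexicon tokens get ``w_risk``; a doubly eligible token gets
    only the stronger bonus.  Every probability score equals the sum of its
    logged match-event contributions.
    """
    maps = {s: codebook.token_map(s) for s in SUBSETS}
    scores = {s: SubsetScore(subset=s) for s in SUBSETS}
    scored: dict[str, set[str]] = {s: set() for s in SUBSETS}
    leading: list[str] = []  # first distinct matched types, in match order
    for pos, tok in enumerate(input_tokens):
        tok_matches = [s for s in SUBSETS if tok in maps[s]]
        if not tok_matches:
            continue
        if tok not in leading:
            leading.append(tok)
        in_lead = leading.index(tok) < N_POSITION_BONUS
        for s in tok_matches:
            if tok in scored[s]:
                continue
            scored[s].add(tok)
            entry = maps[s][tok]
            pos_b = weights.w_pos if in_lead else 0.0
            risk_b = weights.w_risk if entry.is_risk else 0.0
            # bonuses do not stack: a token eligible for both receives only
            # the stronger one (ties go to the position bonus)
            if pos_b > 0.0 and risk_b > 0.0:
                if pos_b >= risk_b:
                    risk_b = 0.0
                else:
                    pos_b = 0.0
            ev = MatchEvent(
                input_position=pos,
                token=tok,
                subset=s,
                base_rep_score=entry.rep_score,
                position_bonus=pos_b,
                risk_bonus=risk_b,
            )
            scores[s].match_events.append(ev)
            scores[s].probability_score += ev.contribution
            scores[s].match_count += 1
    return scores


def h1_select_subset(subset_scores: Mapping[str, SubsetScore]) -> str:
    """Pick the winning subset: score, then match count, then precedence.

    Raises :class:`InsufficientEvidenceError` when nothing matched at all.
    """
    if all(
        subset_scores[s].probability_score == 0
        and subset_scores[s].match_count == 0
        for s in SUBSETS
    ):
        raise InsufficientEvidenceError(0, 1)
    return min(
        SUBSETS,
        key=lambda s: (
            -subset_scores[s].probability_score,
            -subset_scores[s].match_count,
            TIE_PRECEDENCE.index(s),
        ),
    )


def _cosine(u: Sequence[float], v: Sequence[float]) -> float:
    nu = math.sqrt(sum(x * x for x in u))
    nv = math.sqrt(sum(x * x for x in v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return sum(a * b for a, b in zip(u, v)) / (nu * nv)


def h2_best_case(
    input_profile: Mapping[str, int],
    codebook: Codebook,
    subset: str,
) -> tuple[str, float]:
    """Find the training case whose topic profile best matches the input.

    Similarity is the cosine between the integer profile vectors over the
    subset's topic-title axis.  Ties prefer the case sharing more nonzero
    topics with the input, then the lexicographically smallest case id.  An
    all-zero input profile has similarity 0 to every case and resolves by
    the tie rules.
    """
    cases = codebook.cases_in(subset)
    if not cases:
        raise ValueError(f"subset {subset!r} has no cached training cases")
    titles = codebook.topic_titles(subset)
    u = [input_profile.get(t, 0) for t in titles]
    best: tuple[float, int, str] | None = None
    best_case = None
    for c in cases:
        v = [c.profile.get(t, 0) for t in titles]
        sim = _cosine(u, v)
        shared = sum(1 for a, b in zip(u, v) if a > 0 and b > 0)
        key = (-sim, -shared, c.case_id)
        if best is None or key < best:
            best = key
            best_case = c
    assert best is not None and best_case is not None
    return best_case.case_id, -best[0]


def assess(
    raw_text: str,
    codebook: Codebook,
    config: AssessConfig = AssessConfig(),
) -> AssessmentResult:
    """Run the full two-tier assessment of one narrative.

    tokenize -> stoplist filter -> H1 token screening and subset selection
    -> input topic profile within the winning subset -> H2 case match.
    Severity and outcome estimates are the winning subset's stored mean
    merged severity and mean outcome; the matched case contributes only the
    priority ranking.  Fully deterministic.

    Raises :class:`InsufficientEvidenceError` when fewer than
    ``config.min_matches`` distinct token types match the codebook —
    narratives that thin support no reliable inference.
    """
    tokens = filter_tokens(tokenize(raw_text, config.tokenizer), config.stoplist)
    scores = match_tokens(tokens, codebook, config.weights)
    distinct = {e.token for s in SUBSETS for e in scores[s].match_events}
    if len(distinct) < config.min_matches:
        raise InsufficientEvidenceError(len(distinct), config.min_matches)
    subset = h1_select_subset(scores)
    profile = topic_profile(tokens, codebook, subset)
    case_id, sim = h2_best_case(profile, codebook, subset)
    summary = codebook.subsets[subset]
    return AssessmentResult(
        predicted_subset=subset,
        subset_scores=scores,
        severity_estimate=summary.mean_severity,
        outcome_estimate=summary.mean_outcome,
        input_profile=profile,
        matched_case_id=case_id,
        case_similarity=sim,
        priority_ranking=codebook.case_profiles[case_id].priorities,
        config=config,
    )
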