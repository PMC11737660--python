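"""The scored codebook: the machine's knowledge store.

The codebook fuses, for each of the four training subsets:

* the subset topic model's key tokens, each carrying a *representativeness
  score* (its within-subset token frequency min-max standardized to [0, 1]),
  its housing topic (index, title, integer proportion estimate), and a risk
  flag when the token is in the risk lexicon;
* the subset judgment summary (n cases, mean/SD merged severity, mean/SD
  outcome) that supplies the severity and outcome estimates reported for
  inputs matched to the subset;
* the cached topic profile and priority ranking of every training case,
  against which new inputs are matched.

Serialized as schema-versioned JSON with a flat CSV export of the entries
(columns: subset, token, rep_score, topic_index, topic_title,
proportion_estimate, is_risk).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import SUBSETS, TrainingCase
from .errors import CodebookIOError
from .topics import TopicModel, key_tokens

__all__ = [
    "SCHEMA_VERSION",
    "CodebookEntry",
    "SubsetSummary",
    "CaseProfile",
    "Codebook",
    "CodebookConfig",
    "representativeness_scores",
    "build_codebook",
    "topic_profile",
    "write_codebook",
    "read_codebook",
    "export_csv",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class CodebookEntry:
    subset: str
    token: str
    rep_score: float
    topic_index: int
    topic_title: str
    proportion_estimate: int
    is_risk: bool


@dataclass(frozen=True)
class SubsetSummary:
    """Judgment summary of one training subset (SDs are sample SDs)."""

    n_cases: int
    mean_severity: float
    sd_severity: float
    mean_outcome: float
    sd_outcome: float


@dataclass(frozen=True)
class CaseProfile:
    case_id: str
    subset: str
    profile: Mapping[str, int]
    priorities: Mapping[str, int] | None


@dataclass(frozen=True)
class CodebookConfig:
    """Build-time knobs.

    ``tokens_per_topic`` bounds how many key tokens each topic contributes
    (printed codebooks show only a few examples per topic, but the working
    store holds more; bounded for score stability).  ``min_topic_weight``
    drops tokens whose within-topic weight is negligible.
    """

    tokens_per_topic: int = 20
    min_topic_weight: float = 0.001


@dataclass
class Codebook:
    entries: list[CodebookEntry]
    subsets: dict[str, SubsetSummary]
    risk_lexicon: frozenset[str]
    case_profiles: dict[str, CaseProfile]
    titles: dict[str, dict[int, str]]
    proportion_estimates: dict[str, dict[int, int]]
    schema_version: int = SCHEMA_VERSION
    meta: dict = field(default_factory=dict)

    def entries_for(self, subset: str) -> list[CodebookEntry]:
        return [e for e in self.entries if e.subset == subset]

    def token_map(self, subset: str) -> dict[str, CodebookEntry]:
        """token -> entry for one subset (tokens are unique per subset)."""
        return {e.token: e for e in self.entries if e.subset == subset}

    def topic_titles(self, subset: str) -> list[str]:
        """The subset's topic titles in topic-index order."""
        return [self.titles[subset][i] for i in sorted(self.titles[subset])]

    def cases_in(self, subset: str) -> list[CaseProfile]:
        return sorted(
            (c for c in self.case_profiles.values() if c.subset == subset),
            key=lambda c: c.case_id,
        )


def representativeness_scores(frequencies: Mapping[str, int | float]) -> dict[str, float]:
    """Min-max standardize within-subset token frequencies to [0, 1].

    The most frequent token scores 1, the least frequent 0.  When all
    frequencies are equal (including a single-token table) every token
    scores 1.0 — the zero-range convention.
    """
    if not frequencies:
        raise ValueError("empty frequency table")
    vals = list(frequencies.values())
    lo, hi = min(vals), max(vals)
    if hi == lo:
        return {t: 1.0 for t in frequencies}
    return {t: (f - lo) / (hi - lo) for t, f in frequencies.items()}


def topic_profile(
    tokens: Iterable[str], codebook: Codebook, subset: str
) -> dict[str, int]:
    """The topic profile of a token sequence within one subset.

    Keys are exactly the subset's topic titles; a topic's value is its
    integer proportion estimate if any input token matches any codebook
    entry housed in that topic, else 0.  Matched-but-absent topics are how
    an individual narrative resembles only *part* of a subset's model.
    """
    if subset not in codebook.titles:
        raise KeyError(f"unknown subset {subset!r}")
    tmap = codebook.token_map(subset)
    hit_topics = {tmap[t].topic_index for t in set(tokens) if t in tmap}
    return {
        title: (
            codebook.proportion_estimates[subset][idx] if idx in hit_topics else 0
        )
        for idx, title in sorted(codebook.titles[subset].items())
    }


def build_codebook(
    subset_models: Mapping[str, TopicModel],
    cases: Sequence[TrainingCase],
    risk_lexicon: Iterable[str] = (),
    titles: Mapping[str, Mapping[int, str]] | None = None,
    config: CodebookConfig = CodebookConfig(),
    meta: Mapping | None = None,
) -> Codebook:
    """Fuse the four subset topic models and labelled cases into a codebook.

    Each subset contributes its topics' key tokens as entries; a token that
    ranks among several topics of one subset is housed in the topic where
    its weight is maximal (lexical weight ties go to the lower topic
    index), so every token's audit trail is unambiguous.  Representativeness
    scores are computed from the token's raw frequency in the subset's
    training documents.  Each training case's topic profile is computed and
    cached, and ``case.profile`` is filled in place.
    """
    missing = [s for s in SUBSETS if s not in subset_models]
    if missing:
        raise ValueError(f"missing topic model(s) for subset(s): {missing}")
    risk = frozenset(risk_lexicon)

    title_map: dict[str, dict[int, str]] = {}
    prop_map: dict[str, dict[int, int]] = {}
    for s in SUBSETS:
        model = subset_models[s]
        ests = model.proportion_estimates
        sub_titles = dict((titles or {}).get(s, {}))
        for k in range(model.K):
            sub_titles.setdefault(k, f"topic-{k}")
        if len(set(sub_titles.values())) != model.K:
            raise ValueError(f"subset {s}: topic titles must be unique")
        title_map[s] = {k: sub_titles[k] for k in range(model.K)}
        prop_map[s] = {k: int(ests[k]) for k in range(model.K)}

    cases_by_subset: dict[str, list[TrainingCase]] = {s: [] for s in SUBSETS}
    for c in cases:
        cases_by_subset[c.subset].append(c)

    entries: list[CodebookEntry] = []
    for s in SUBSETS:
        model = subset_models[s]
        # house each candidate token in its max-weight topic
        housing: dict[str, int] = {}
        widx = {tok: i for i, tok in enumerate(model.vocabulary)}
        for k in range(model.K):
            for tok in key_tokens(
                model, k, n=config.tokens_per_topic,
                min_weight=config.min_topic_weight,
            ):
                if tok not in housing:
                    housing[tok] = k
                else:
                    w_new = model.topic_token_weights[k, widx[tok]]
                    w_old = model.topic_token_weights[housing[tok], widx[tok]]
                    if w_new > w_old:
                        housing[tok] = k
        freqs: dict[str, int] = {}
        subset_tokens = [
            t for c in cases_by_subset[s] for t in c.document.tokens
        ]
        for t in subset_tokens:
            if t in housing:
                freqs[t] = freqs.get(t, 0) + 1
        for t in housing:
            freqs.setdefault(t, 0)
        rep = representativeness_scores(freqs) if freqs else {}
        for tok in sorted(housing):
            k = housing[tok]
            entries.append(
                CodebookEntry(
                    subset=s,
                    token=tok,
                    rep_score=rep[tok],
                    topic_index=k,
                    topic_title=title_map[s][k],
                    proportion_estimate=prop_map[s][k],
                    is_risk=tok in risk,
                )
            )

    summaries: dict[str, SubsetSummary] = {}
    for s in SUBSETS:
        cs = cases_by_subset[s]
        sev = np.array([c.merged_severity for c in cs], dtype=float)
        out = np.array([c.mean_outcome for c in cs], dtype=float)
        summaries[s] = SubsetSummary(
            n_cases=len(cs),
            mean_severity=float(sev.mean()) if len(cs) else float("nan"),
            sd_severity=float(sev.std(ddof=1)) if len(cs) > 1 else 0.0,
            mean_outcome=float(out.mean()) if len(cs) else float("nan"),
            sd_outcome=float(out.std(ddof=1)) if len(cs) > 1 else 0.0,
        )

    cb = Codebook(
        entries=entries,
        subsets=summaries,
        risk_lexicon=risk,
        case_profiles={},
        titles=title_map,
        proportion_estimates=prop_map,
        meta=dict(meta or {}),
    )
    for s in SUBSETS:
        for c in cases_by_subset[s]:
            prof = topic_profile(c.document.tokens, cb, s)
            c.profile = prof
            cb.case_profiles[c.case_id] = CaseProfile(
                case_id=c.case_id,
                subset=s,
                profile=prof,
                priorities=dict(c.priority_consensus)
                if c.priority_consensus is not None
                else None,
            )
    return cb


# ---------------------------------------------------------------------------
# serialization


def _codebook_to_dict(cb: Codebook) -> dict:
    return {
        "schema_version": cb.schema_version,
        "meta": cb.meta,
        "risk_lexicon": sorted(cb.risk_lexicon),
        "titles": {s: {str(k): t for k, t in cb.titles[s].items()} for s in cb.titles},
        "proportion_estimates": {
            s: {str(k): v for k, v in cb.proportion_estimates[s].items()}
            for s in cb.proportion_estimates
        },
        "subsets": {
            s: {
                "n_cases": sm.n_cases,
                "mean_severity": sm.mean_severity,
                "sd_severity": sm.sd_severity,
                "mean_outcome": sm.mean_outcome,
                "sd_outcome": sm.sd_outcome,
            }
            for s, sm in cb.subsets.items()
        },
        "entries": [
            {
                "subset": e.subset,
                "token": e.token,
                "rep_score": e.rep_score,
                "topic_index": e.topic_index,
                "topic_title": e.topic_title,
                "proportion_estimate": e.proportion_estimate,
                "is_risk": e.is_risk,
            }
            for e in cb.entries
        ],
        "case_profiles": {
            cid: {
                "subset": cp.subset,
                "profile": dict(cp.profile),
                "priorities": dict(cp.priorities) if cp.priorities else None,
            }
            for cid, cp in sorted(cb.case_profiles.items())
        },
    }


def write_codebook(cb: Codebook, path: str | Path) -> None:
    """Serialize to schema-versioned JSON (round-trip lossless)."""
    Path(path).write_text(
        json.dumps(_codebook_to_dict(cb), ensure_ascii=False, sort_keys=True, indent=1),
        encoding="utf-8",
    )


def read_codebook(path: str | Path) -> Codebook:
    path = Path(path)
    if not path.exists():
        raise CodebookIOError(f"no such codebook file: {path}")
    try:
        d = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise CodebookIOError(f"malformed codebook JSON: {e}") from e
    if d.get("schema_version") != SCHEMA_VERSION:
        raise CodebookIOError(
            f"unsupported schema_version {d.get('schema_version')!r}; "
            f"expected {SCHEMA_VERSION}"
        )
    for s in SUBSETS:
        if s not in d.get("subsets", {}) or s not in d.get("titles", {}):
            raise CodebookIOError(f"codebook is missing subset {s!r}")
    try:
        return Codebook(
            entries=[CodebookEntry(**e) for e in d["entries"]],
            subsets={
                s: SubsetSummary(**sm) for s, sm in d["subsets"].items()
            },
            risk_lexicon=frozenset(d["risk_lexicon"]),
            case_profiles={
                cid: CaseProfile(
                    case_id=cid,
                    subset=cp["subset"],
                    profile=cp["profile"],
                    priorities=cp["priorities"],
                )
                for cid, cp in d["case_profiles"].items()
            },
            titles={
                s: {int(k): t for k, t in tm.items()}
                for s, tm in d["titles"].items()
            },
            proportion_estimates={
                s: {int(k): v for k, v in pm.items()}
                for s, pm in d["proportion_estimates"].items()
            },
            schema_version=d["schema_version"],
            meta=d.get("meta", {}),
        )
    except (KeyError, TypeError) as e:
        raise CodebookIOError(f"malformed codebook structure: {e}") from e


def export_csv(cb: Codebook, path: str | Path) -> None:
    """Flat CSV of the entries, one row per (subset, token)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["subset", "token", "rep_score", "topic_index", "topic_title",
             "proportion_estimate", "is_risk"]
        )
        for e in cb.entries:
            w.writerow(
                [e.subset, e.token, f"{e.rep_score:.6f}", e.topic_index,
                 e.topic_title, e.proportion_estimate, int(e.is_risk)]
            )
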