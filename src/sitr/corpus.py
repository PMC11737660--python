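"""Documents, tokenization, screening, and training-case labelling.

A training corpus is a set of free-text narratives, each judged by two or
more raters on 7-point Likert scales for case severity, expected
intervention difficulty, and expected (negative) treatment outcome, plus a
ranking of five intervention domains.  Severity and difficulty are highly
collinear in practice and are merged into a single severity indicator; the
merged severity and the mean outcome then partition the corpus into four
subsets:

=======  ==========================================
subset   semantics
=======  ==========================================
A        serious, but positive outcome expected
B        serious, and negative outcome concerning
C        not as serious, positive outcome expected
D        not as serious, negative outcome concerning
=======  ==========================================
"""

from __future__ import annotations

import csv
import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .errors import ConfigurationError

__all__ = [
    "SUBSETS",
    "SUBSET_SEMANTICS",
    "PRIORITY_DOMAINS",
    "Document",
    "RaterJudgment",
    "TrainingCase",
    "InclusionConfig",
    "tokenize",
    "register_tokenizer",
    "filter_tokens",
    "screen_documents",
    "merge_severity",
    "partition_subset",
    "partition_subsets",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
    "read_corpus_csv",
    "read_token_list",
]

SUBSETS = ("A", "B", "C", "D")

SUBSET_SEMANTICS = {
    "A": "serious, but positive outcome expected",
    "B": "serious, and negative outcome concerning",
    "C": "not as serious, positive outcome expected",
    "D": "not as serious, but negative outcome concerning",
}

#: The five counselling intervention domains ranked 1 (highest priority) to 5.
PRIORITY_DOMAINS = (
    "traits/personality",
    "thoughts",
    "emotions",
    "past environment",
    "current environment",
)

_WORD_RE = re.compile(r"\w+", re.UNICODE)


def _default_tokenizer(text: str) -> list[str]:
    # Unicode word characters; lowercasing only affects cased scripts, so
    # Korean (caseless) passes through unchanged.
    return [m.group(0).lower() for m in _WORD_RE.finditer(text)]


_TOKENIZERS: dict[str, Callable[[str], list[str]]] = {
    "default": _default_tokenizer,
    "whitespace": lambda text: text.split(),
}


def register_tokenizer(name: str, fn: Callable[[str], list[str]]) -> None:
    """Register an external tokenizer adapter (e.g. a morphological analyzer).

    The adapter receives NFC-normalized text and must return tokens in text
    order, deterministically.
    """
    _TOKENIZERS[name] = fn


def tokenize(raw_text: str, tokenizer: str = "default") -> list[str]:
    """Split ``raw_text`` into unigram tokens in text order.

    Text is Unicode-normalized (NFC) before splitting so that composed and
    decomposed forms of the same syllable tokenize identically.  The default
    tokenizer splits on Unicode word characters and lowercases; a registered
    adapter (see :func:`register_tokenizer`) can substitute a morphological
    analyzer for agglutinative languages.
    """
    try:
        fn = _TOKENIZERS[tokenizer]
    except KeyError:
        raise ConfigurationError(
            f"unknown tokenizer {tokenizer!r}; known: {sorted(_TOKENIZERS)}"
        ) from None
    return fn(unicodedata.normalize("NFC", raw_text))


def filter_tokens(tokens: Sequence[str], stoplist: Iterable[str]) -> list[str]:
    """Drop stoplist tokens (empty morphemes, function words); keep order."""
    stop = frozenset(stoplist)
    return [t for t in tokens if t not in stop]


@dataclass(frozen=True)
class Document:
    """A single narrative with its deterministic tokenization."""

    doc_id: str
    raw_text: str
    tokens: tuple[str, ...]
    suitability: float | None = None

    @property
    def char_count(self) -> int:
        return len(self.raw_text)

    @classmethod
    def from_text(
        cls,
        doc_id: str,
        raw_text: str,
        tokenizer: str = "default",
        stoplist: Iterable[str] = (),
        suitability: float | None = None,
    ) -> "Document":
        toks = filter_tokens(tokenize(raw_text, tokenizer), stoplist)
        return cls(doc_id, raw_text, tuple(toks), suitability)


@dataclass(frozen=True)
class RaterJudgment:
    """One rater's Likert judgments and priority ranking for one case.

    ``priorities`` maps each of the five intervention domains to a rank in
    1..5 (a bijection).  All Likert values are integers in [1, 7].
    """

    case_id: str
    rater_id: str
    severity: int
    difficulty: int
    outcome: int
    priorities: Mapping[str, int] | None = None

    def __post_init__(self):
        for name in ("severity", "difficulty", "outcome"):
            v = getattr(self, name)
            if not (isinstance(v, int) and 1 <= v <= 7):
                raise ValueError(f"{name} must be an integer in [1, 7], got {v!r}")
        if self.priorities is not None:
            if set(self.priorities) != set(PRIORITY_DOMAINS) or sorted(
                self.priorities.values()
            ) != [1, 2, 3, 4, 5]:
                raise ValueError(
                    "priorities must rank the five domains with ranks {1..5}"
                )


@dataclass
class TrainingCase:
    """A labelled training document.

    ``profile`` (topic title -> integer proportion value) is filled in when
    the codebook is built; until then it is ``None``.
    """

    document: Document
    merged_severity: float
    mean_outcome: float
    subset: str
    priority_consensus: Mapping[str, int] | None = None
    profile: Mapping[str, int] | None = None

    @property
    def case_id(self) -> str:
        return self.document.doc_id


@dataclass(frozen=True)
class InclusionConfig:
    """Screening criteria; a criterion set to ``None`` is not applied.

    ``min_suitability`` is checked only on documents that carry a
    suitability rating (ratings are attached upstream, never elicited here).
    """

    min_chars: int | None = None
    min_tokens: int | None = None
    required_keyword: str | None = None
    min_suitability: float | None = None


def screen_documents(
    docs: Sequence[Document], config: InclusionConfig
) -> tuple[list[Document], list[tuple[str, str]]]:
    """Apply inclusion criteria; return (retained, rejection log).

    The log records ``(doc_id, first_failed_criterion)`` for every rejected
    document, in input order.  Criteria are checked in the fixed order
    min_chars, min_tokens, required_keyword, min_suitability.
    """
    retained: list[Document] = []
    rejected: list[tuple[str, str]] = []
    for doc in docs:
        reason = None
        if config.min_chars is not None and doc.char_count < config.min_chars:
            reason = "min_chars"
        elif config.min_tokens is not None and len(doc.tokens) < config.min_tokens:
            reason = "min_tokens"
        elif (
            config.required_keyword is not None
            and config.required_keyword not in doc.raw_text
        ):
            reason = "required_keyword"
        elif (
            config.min_suitability is not None
            and doc.suitability is not None
            and doc.suitability < config.min_suitability
        ):
            reason = "min_suitability"
        if reason is None:
            retained.append(doc)
        else:
            rejected.append((doc.doc_id, reason))
    return retained, rejected


def merge_severity(judgments: Sequence[RaterJudgment]) -> tuple[float, float]:
    """Merge one case's rater judgments into (merged_severity, mean_outcome).

    Severity and difficulty are pooled and averaged together into a single
    severity indicator; outcome is averaged on its own.  Both results lie in
    [1, 7] and are invariant to rater order.
    """
    if not judgments:
        raise ValueError("merge_severity requires at least one judgment")
    sev_dif = [v for j in judgments for v in (j.severity, j.difficulty)]
    outcomes = [j.outcome for j in judgments]
    return sum(sev_dif) / len(sev_dif), sum(outcomes) / len(outcomes)


def partition_subset(
    merged_severity: float,
    mean_outcome: float,
    severity_threshold: float = 4.0,
    outcome_threshold: float = 3.5,
) -> str:
    """Map merged judgments to a subset label.

    A case is *serious* iff merged severity >= the severity threshold and
    *negative-outcome concerning* iff mean outcome >= the outcome threshold
    (both inclusive).  Crossing the two binary judgments yields A (serious,
    positive), B (serious, negative), C (not serious, positive), D (not
    serious, negative).  The default thresholds are the midpoint-style pair
    that separates typical subset means; both are configuration.
    """
    serious = merged_severity >= severity_threshold
    negative = mean_outcome >= outcome_threshold
    return {
        (True, False): "A",
        (True, True): "B",
        (False, False): "C",
        (False, True): "D",
    }[(serious, negative)]


def partition_subsets(
    cases: Sequence[TrainingCase],
    severity_threshold: float = 4.0,
    outcome_threshold: float = 3.5,
) -> list[str]:
    """Vectorized :func:`partition_subset` over cases; also relabels them."""
    labels = []
    for c in cases:
        label = partition_subset(
            c.merged_severity, c.mean_outcome, severity_threshold, outcome_threshold
        )
        c.subset = label
        labels.append(label)
    return labels


# ---------------------------------------------------------------------------
# I/O: JSONL / CSV corpora, plain-text token lists


def _judgments_from_record(case_id: str, raw: list[dict]) -> list[RaterJudgment]:
    out = []
    for i, j in enumerate(raw):
        out.append(
            RaterJudgment(
                case_id=case_id,
                rater_id=str(j.get("rater_id", i)),
                severity=int(j["severity"]),
                difficulty=int(j["difficulty"]),
                outcome=int(j["outcome"]),
                priorities=j.get("priorities"),
            )
        )
    return out


def read_corpus_jsonl(
    path: str | Path,
    tokenizer: str = "default",
    stoplist: Iterable[str] = (),
) -> tuple[list[Document], dict[str, list[RaterJudgment]]]:
    """Read a JSONL corpus: one record per line with ``id``, ``text``,
    optional ``suitability`` and optional ``judgments`` (list of rater
    records).  Returns documents and a case_id -> judgments map."""
    docs: list[Document] = []
    judgments: dict[str, list[RaterJudgment]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            doc_id = str(rec["id"])
            docs.append(
                Document.from_text(
                    doc_id,
                    rec["text"],
                    tokenizer=tokenizer,
                    stoplist=stoplist,
                    suitability=rec.get("suitability"),
                )
            )
            if rec.get("judgments"):
                judgments[doc_id] = _judgments_from_record(doc_id, rec["judgments"])
    return docs, judgments


def write_corpus_jsonl(
    path: str | Path,
    docs: Sequence[Document],
    judgments: Mapping[str, Sequence[RaterJudgment]] | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            rec: dict = {"id": doc.doc_id, "text": doc.raw_text}
            if doc.suitability is not None:
                rec["suitability"] = doc.suitability
            for j in (judgments or {}).get(doc.doc_id, ()):
                rec.setdefault("judgments", []).append(
                    {
                        "rater_id": j.rater_id,
                        "severity": j.severity,
                        "difficulty": j.difficulty,
                        "outcome": j.outcome,
                        **(
                            {"priorities": dict(j.priorities)}
                            if j.priorities is not None
                            else {}
                        ),
                    }
                )
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_corpus_csv(
    path: str | Path,
    tokenizer: str = "default",
    stoplist: Iterable[str] = (),
) -> list[Document]:
    """Read a CSV corpus with columns ``id``, ``text``, optional
    ``suitability``."""
    docs = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            suit = row.get("suitability")
            docs.append(
                Document.from_text(
                    str(row["id"]),
                    row["text"],
                    tokenizer=tokenizer,
                    stoplist=stoplist,
                    suitability=float(suit) if suit not in (None, "") else None,
                )
            )
    return docs


def read_token_list(path: str | Path) -> list[str]:
    """Read a stoplist or risk lexicon: one token per line, ``#`` comments."""
    tokens = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.append(line)
    return tokens
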