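"""Client-report rendering and the validation workflow.

Reports are deterministic renderings of an :class:`AssessmentResult` in
JSON or markdown (an optional PDF backend can wrap the markdown; content,
not styling, is the contract here).  Reports never include raw training
texts — only case identifiers — and always carry a caveat block: the
machine produces tentative, instant triage judgments meant to orient a
human counselor, not a diagnosis.

The validation workflow replays the calibration procedure: assess a set of
held-out narratives that carry reference rater judgments, then test
whether machine and reference severity/outcome judgments are statistically
indistinguishable (one-way MANOVA at a configured alpha).  Non-significance
is weak evidence of equivalence; the summary says so.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .assessor import AssessConfig, AssessmentResult, assess
from .codebook import Codebook
from .corpus import SUBSET_SEMANTICS, TrainingCase
from .errors import ConfigurationError, InsufficientEvidenceError
from .psychstats import ManovaResult, one_way_manova, pearson

__all__ = [
    "CAVEAT_TEXT",
    "render_report",
    "render_refusal",
    "config_hash",
    "ValidationSummary",
    "run_validation",
]

CAVEAT_TEXT = (
    "This report is a tentative, automatically generated triage aid based "
    "solely on the language of a single writing. It is not a diagnosis and "
    "must not replace a qualified counselor's judgment. Estimates are "
    "subset-level averages of human raters' prior judgments on similar "
    "cases; individual circumstances can differ substantially."
)


def config_hash(config: AssessConfig) -> str:
    """Short stable hash of the assessment configuration."""
    payload = json.dumps(
        {
            "tokenizer": config.tokenizer,
            "stoplist": sorted(config.stoplist),
            "w_pos": config.weights.w_pos,
            "w_risk": config.weights.w_risk,
            "min_matches": config.min_matches,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def render_report(
    result: AssessmentResult,
    codebook: Codebook | None = None,
    format: str = "json",
    case_label: str = "input",
    timestamp: str | None = None,
) -> str:
    """Render an assessment result as a client report.

    ``format`` is ``json`` or ``markdown``.  Rendering is deterministic:
    two renders of the same result are byte-identical (pass ``timestamp``
    explicitly if a generation time should appear).
    """
    if format not in ("json", "markdown"):
        raise ConfigurationError(f"unknown report format {format!r}")
    summary = codebook.subsets[result.predicted_subset] if codebook else None
    payload = {
        "case": case_label,
        "assessment": result.to_dict(),
        "subset_sd": {
            "severity": summary.sd_severity if summary else None,
            "outcome": summary.sd_outcome if summary else None,
        },
        "caveat": CAVEAT_TEXT,
        "config_hash": config_hash(result.config),
    }
    if timestamp is not None:
        payload["generated_at"] = timestamp
    if format == "json":
        return json.dumps(payload, sort_keys=True, ensure_ascii=False, indent=1)

    r = result
    sd_sev = f" (subset SD {summary.sd_severity:.2f})" if summary else ""
    sd_out = f" (subset SD {summary.sd_outcome:.2f})" if summary else ""
    lines = [
        f"# Assessment report — {case_label}",
        "",
        "## Assessment summary",
        f"- Predicted subset: **{r.predicted_subset}** — "
        f"{SUBSET_SEMANTICS[r.predicted_subset]}",
        f"- Case severity estimate (1–7): **{r.severity_estimate:.2f}**{sd_sev}",
        f"- Expected negative treatment outcome (1–7): "
        f"**{r.outcome_estimate:.2f}**{sd_out}",
        "",
        "## Topic profile",
        "| topic | value |",
        "| --- | --- |",
    ]
    for title, v in r.input_profile.items():
        lines.append(f"| {title} | {v} |")
    lines += ["", "## Intervention priorities",
              f"(from best-matched case {r.matched_case_id}, "
              f"similarity {r.case_similarity:.3f})"]
    if r.priority_ranking:
        for d, rank in sorted(r.priority_ranking.items(), key=lambda kv: kv[1]):
            lines.append(f"{rank}. {d}")
    else:
        lines.append("(no priority ranking recorded for the matched case)")
    lines += ["", "## Matched tokens (audit trail)"]
    for s, sc in sorted(r.subset_scores.items()):
        toks = ", ".join(e.token for e in sc.match_events) or "—"
        lines.append(
            f"- {s}: score {sc.probability_score:.3f}, "
            f"{sc.match_count} match(es): {toks}"
        )
    lines += ["", "## Caveats", CAVEAT_TEXT, "",
              f"config hash: `{config_hash(r.config)}`"]
    if timestamp is not None:
        lines.append(f"generated at: {timestamp}")
    return "\n".join(lines) + "\n"


def render_refusal(
    error: InsufficientEvidenceError,
    format: str = "json",
    case_label: str = "input",
) -> str:
    """Structured notice replacing the report when evidence is insufficient."""
    payload = {
        "case": case_label,
        "status": "insufficient_evidence",
        "n_matches": error.n_matches,
        "min_matches": error.min_matches,
        "message": (
            "The number of recognizable tokens in this writing is "
            "insufficient to make a reliable inference; no assessment is "
            "reported."
        ),
    }
    if format == "json":
        return json.dumps(payload, sort_keys=True, ensure_ascii=False, indent=1)
    if format == "markdown":
        return (
            f"# Assessment report — {case_label}\n\n"
            f"**No assessment: insufficient evidence.**\n\n"
            f"{payload['message']}\n\n"
            f"(distinct matched tokens: {error.n_matches}, "
            f"required: {error.min_matches})\n"
        )
    raise ConfigurationError(f"unknown report format {format!r}")


@dataclass
class ValidationSummary:
    """Machine-vs-reference comparison over held-out judged cases."""

    n_input: int
    n_assessed: int
    excluded: list[str]
    per_case: dict[str, dict]
    manova: ManovaResult | None
    severity_correlation: tuple[float, float] | None
    outcome_correlation: tuple[float, float] | None
    passed: bool
    alpha: float
    note: str = (
        "pass = machine and reference judgments are statistically "
        "indistinguishable (MANOVA p > alpha); non-significance is weak "
        "evidence of equivalence."
    )


def run_validation(
    codebook: Codebook,
    heldout: Sequence[TrainingCase],
    config: AssessConfig = AssessConfig(),
    alpha: float = 0.05,
) -> ValidationSummary:
    """Assess held-out judged cases and compare machine with reference.

    Cases failing assessment (insufficient evidence) are logged and
    excluded.  The equivalence criterion defaults to a non-significant
    one-way MANOVA (group = machine vs reference; DVs = severity, outcome)
    at ``alpha``.
    """
    per_case: dict[str, dict] = {}
    excluded: list[str] = []
    machine_rows, reference_rows = [], []
    for case in heldout:
        try:
            res = assess(case.document.raw_text, codebook, config)
        except InsufficientEvidenceError as e:
            excluded.append(case.case_id)
            per_case[case.case_id] = {"status": "excluded", "n_matches": e.n_matches}
            continue
        per_case[case.case_id] = {
            "status": "assessed",
            "machine": {"severity": res.severity_estimate,
                        "outcome": res.outcome_estimate,
                        "subset": res.predicted_subset},
            "reference": {"severity": case.merged_severity,
                          "outcome": case.mean_outcome,
                          "subset": case.subset},
        }
        machine_rows.append([res.severity_estimate, res.outcome_estimate])
        reference_rows.append([case.merged_severity, case.mean_outcome])

    manova = None
    sev_corr = out_corr = None
    passed = False
    if len(machine_rows) >= 2:
        m = np.asarray(machine_rows)
        r = np.asarray(reference_rows)
        dv = np.vstack([m, r])
        labels = ["machine"] * len(m) + ["reference"] * len(r)
        try:
            manova = one_way_manova(labels, dv, dv_names=["severity", "outcome"])
            passed = manova.p > alpha
        except Exception:
            # degenerate (e.g. identical rows): indistinguishable by construction
            if np.allclose(m.mean(axis=0), r.mean(axis=0)):
                passed = True
        try:
            sev_corr = pearson(m[:, 0], r[:, 0])
            out_corr = pearson(m[:, 1], r[:, 1])
        except Exception:
            pass
    return ValidationSummary(
        n_input=len(heldout),
        n_assessed=len(machine_rows),
        excluded=excluded,
        per_case=per_case,
        manova=manova,
        severity_correlation=sev_corr,
        outcome_correlation=out_corr,
        passed=passed,
        alpha=alpha,
    )
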