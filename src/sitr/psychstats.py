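"""Psychometric statistics used to calibrate and validate the machine.

Inter-rater agreement (Cohen's kappa with Landis-Koch bands), two-way
random-effects reliability (Shrout-Fleiss ICC(2,k), absolute agreement,
average measures), Pearson correlation, one-way MANOVA (Wilks' lambda with
Rao's F approximation plus univariate follow-ups), hierarchical multiple
regression with R-squared-change F tests, and the normality /
variance-homogeneity assumption checks run before regression.

These are textbook procedures; they are implemented here directly from the
ANOVA / normal-equation decompositions so every returned quantity is
traceable, with scipy supplying distributions and the Shapiro-Wilk and
Levene tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError

__all__ = [
    "AgreementResult",
    "RegressionStep",
    "ManovaResult",
    "AssumptionReport",
    "landis_koch_band",
    "cohens_kappa",
    "icc_2k",
    "pearson",
    "one_way_manova",
    "hierarchical_regression",
    "assumption_checks",
]


def landis_koch_band(kappa: float) -> str:
    """Landis & Koch qualitative band for a kappa value."""
    if kappa < 0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


@dataclass(frozen=True)
class AgreementResult:
    statistic: str
    value: float
    band: str | None = None
    F: float | None = None
    df1: float | None = None
    df2: float | None = None
    p: float | None = None


def cohens_kappa(
    ratings_a: Sequence,
    ratings_b: Sequence,
    weighting: str = "none",
) -> AgreementResult:
    """Cohen's kappa between two raters' paired categorical ratings.

    kappa = (p_o - p_e) / (1 - p_e) with the selected disagreement-weight
    matrix (``none`` | ``linear`` | ``quadratic``); 7-point Likert
    judgments default to unweighted agreement.  Raises
    :class:`DegenerateDataError` when chance agreement is 1 (both raters
    constant and identical), where kappa is undefined.
    """
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b) or not a:
        raise ValueError("ratings must be equal-length and non-empty")
    cats = sorted(set(a) | set(b))
    idx = {c: i for i, c in enumerate(cats)}
    q = len(cats)
    counts = np.zeros((q, q))
    for x, y in zip(a, b):
        counts[idx[x], idx[y]] += 1
    p = counts / counts.sum()
    if weighting == "none":
        w = 1.0 - np.eye(q)
    elif weighting == "linear":
        w = np.abs(np.subtract.outer(np.arange(q), np.arange(q))) / max(q - 1, 1)
    elif weighting == "quadratic":
        w = (np.subtract.outer(np.arange(q), np.arange(q)) / max(q - 1, 1)) ** 2
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    d_o = float((w * p).sum())
    d_e = float((w * np.outer(row, col)).sum())
    if d_e == 0.0:
        raise DegenerateDataError(
            "kappa undefined: expected agreement is 1 (constant identical ratings)"
        )
    kappa = 1.0 - d_o / d_e
    return AgreementResult("kappa", kappa, band=landis_koch_band(kappa))


def icc_2k(ratings: np.ndarray) -> AgreementResult:
    """Shrout-Fleiss ICC(2,k): two-way random effects, absolute agreement,
    average of k raters' measures.

    ``ratings`` is a complete targets x raters matrix.  From the two-way
    ANOVA mean squares (rows = targets, columns = raters):

        ICC(2,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n)

    with F = MS_R / MS_E on (n-1, (n-1)(k-1)) degrees of freedom.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a complete matrix with >=2 targets and >=2 raters")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (ms_c - ms_e) / n
    if denom == 0.0:
        raise DegenerateDataError(
            "ICC undefined: no between-target variance and no error variance"
        )
    icc = (ms_r - ms_e) / denom
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if ms_e == 0.0:
        f, p = float("inf"), 0.0
    else:
        f = ms_r / ms_e
        p = float(stats.f.sf(f, df1, df2))
    return AgreementResult("ICC(2,k)", icc, F=f, df1=df1, df2=df2, p=p)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment r with its two-sided t-test p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise DegenerateDataError("Pearson r undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    F: float
    df1: float
    df2: float
    p: float
    univariate: dict[str, tuple[float, float, float, float]]  # dv -> F, df1, df2, p
    group_means: dict[str, np.ndarray]
    mean_differences: dict[tuple[str, str], np.ndarray]


def one_way_manova(
    group_labels: Sequence,
    dv_matrix: np.ndarray,
    dv_names: Sequence[str] | None = None,
) -> ManovaResult:
    """One-way MANOVA: Wilks' lambda with Rao's F approximation.

    ``dv_matrix`` is observations x DVs.  Lambda = det(E) / det(E + H) with
    E the within-group and H the between-group SSCP matrices.  Univariate
    one-way F tests per DV are reported as follow-ups, and pairwise group
    mean differences (I - J) per DV accompany the test.
    """
    y = np.asarray(dv_matrix, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    labels = np.asarray(group_labels)
    if y.shape[0] != labels.shape[0]:
        raise ValueError("dv_matrix must have one row per observation")
    n, p = y.shape
    groups = sorted(set(labels.tolist()))
    g = len(groups)
    if g < 2:
        raise ValueError("need >= 2 groups")
    names = list(dv_names) if dv_names is not None else [f"dv{j}" for j in range(p)]
    grand = y.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    means: dict[str, np.ndarray] = {}
    for grp in groups:
        yg = y[labels == grp]
        mg = yg.mean(axis=0)
        means[str(grp)] = mg
        H += len(yg) * np.outer(mg - grand, mg - grand)
        E += (yg - mg).T @ (yg - mg)
    det_e = np.linalg.det(E)
    det_eh = np.linalg.det(E + H)
    if det_eh <= 0 or not np.isfinite(det_e):
        raise DegenerateDataError("singular pooled covariance; MANOVA undefined")
    lam = float(det_e / det_eh)
    # Rao's F approximation
    q = g - 1
    t_df = n - 1 - (p + g) / 2.0
    s = (
        np.sqrt((p**2 * q**2 - 4.0) / (p**2 + q**2 - 5.0))
        if (p**2 + q**2 - 5.0) > 0
        else 1.0
    )
    df1 = p * q
    df2 = t_df * s - (p * q) / 2.0 + 1.0
    lam_s = lam ** (1.0 / s)
    if lam_s == 0.0:
        f = float("inf")
    else:
        f = ((1.0 - lam_s) / lam_s) * (df2 / df1)
    pval = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    uni: dict[str, tuple[float, float, float, float]] = {}
    for j, name in enumerate(names):
        samples = [y[labels == grp, j] for grp in groups]
        fj, pj = stats.f_oneway(*samples)
        uni[name] = (float(fj), float(g - 1), float(n - g), float(pj))
    diffs: dict[tuple[str, str], np.ndarray] = {}
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            diffs[(str(gi), str(gj))] = means[str(gi)] - means[str(gj)]
    return ManovaResult(lam, float(f), float(df1), float(df2), pval, uni, means, diffs)


@dataclass(frozen=True)
class RegressionStep:
    predictors: tuple[str, ...]
    B: dict[str, float]
    SE: dict[str, float]
    beta: dict[str, float]
    t: dict[str, float]
    F: float
    p: float
    r_squared: float
    delta_r_squared: float
    F_change: float
    p_change: float


def hierarchical_regression(
    y: Sequence[float],
    blocks: Sequence[Mapping[str, Sequence[float]]],
) -> list[RegressionStep]:
    """OLS over cumulative predictor blocks, with incremental-validity stats.

    Each block maps predictor names to columns.  Step s regresses y on the
    union of blocks 1..s (with intercept) and reports per-predictor B, SE,
    standardized beta and t, the model F, R-squared, the R-squared change
    over the previous step, and its F test

        F_change = (dR2 / q) / ((1 - R2_full) / (n - p_full - 1)),

    where q is the number of predictors added at the step.
    """
    yv = np.asarray(y, dtype=float)
    n = yv.size
    steps: list[RegressionStep] = []
    names: list[str] = []
    cols: list[np.ndarray] = []
    prev_r2 = 0.0
    sst = float(((yv - yv.mean()) ** 2).sum())
    if sst == 0.0:
        raise DegenerateDataError("outcome has zero variance")
    for block in blocks:
        q = len(block)
        for name, col in block.items():
            names.append(name)
            cols.append(np.asarray(col, dtype=float))
        X = np.column_stack([np.ones(n)] + cols)
        p_full = X.shape[1] - 1
        if n <= p_full + 1:
            raise ValueError("need n > number of predictors + 1")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DegenerateDataError("design matrix is rank deficient")
        coef, *_ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ coef
        sse = float(resid @ resid)
        r2 = 1.0 - sse / sst
        df_resid = n - p_full - 1
        mse = sse / df_resid
        cov = mse * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        sd_y = yv.std(ddof=1)
        B = {nm: float(coef[i + 1]) for i, nm in enumerate(names)}
        SE = {nm: float(se[i + 1]) for i, nm in enumerate(names)}
        beta = {
            nm: float(coef[i + 1] * cols[i].std(ddof=1) / sd_y)
            for i, nm in enumerate(names)
        }
        tvals = {nm: B[nm] / SE[nm] for nm in names}
        f_model = (r2 / p_full) / ((1.0 - r2) / df_resid) if r2 < 1.0 else float("inf")
        p_model = (
            float(stats.f.sf(f_model, p_full, df_resid))
            if np.isfinite(f_model)
            else 0.0
        )
        dr2 = r2 - prev_r2
        if r2 < 1.0:
            f_change = (dr2 / q) / ((1.0 - r2) / df_resid)
            p_change = float(stats.f.sf(f_change, q, df_resid))
        else:
            f_change, p_change = float("inf"), 0.0
        steps.append(
            RegressionStep(
                predictors=tuple(names),
                B=B, SE=SE, beta=beta, t=tvals,
                F=float(f_model), p=p_model,
                r_squared=r2, delta_r_squared=dr2,
                F_change=float(f_change), p_change=p_change,
            )
        )
        prev_r2 = r2
    return steps


@dataclass(frozen=True)
class AssumptionReport:
    shapiro: dict[str, tuple[float, float]]  # group -> (W, p)
    levene: tuple[float, float] | None  # (W, p), None without groups
    normality_violated: bool
    homogeneity_violated: bool
    alpha: float


def assumption_checks(
    y: Sequence[float],
    groups: Sequence | None = None,
    alpha: float = 0.05,
) -> AssumptionReport:
    """Shapiro-Wilk normality per group (or pooled) and median-centered
    Levene variance-homogeneity across groups, flagged at ``alpha``."""
    yv = np.asarray(y, dtype=float)
    shapiro: dict[str, tuple[float, float]] = {}
    if groups is None:
        samples = {"all": yv}
    else:
        labels = np.asarray(groups)
        samples = {str(g): yv[labels == g] for g in sorted(set(labels.tolist()))}
    for name, sample in samples.items():
        if sample.size < 3:
            raise DegenerateDataError(
                f"Shapiro-Wilk needs n >= 3 per group (group {name!r})"
            )
        if np.ptp(sample) == 0.0:
            raise DegenerateDataError(
                f"Shapiro-Wilk undefined for constant data (group {name!r})"
            )
        w, p = stats.shapiro(sample)
        shapiro[name] = (float(w), float(p))
    levene = None
    if groups is not None and len(samples) >= 2:
        w, p = stats.levene(*samples.values(), center="median")
        levene = (float(w), float(p))
    return AssumptionReport(
        shapiro=shapiro,
        levene=levene,
        normality_violated=any(p < alpha for _, p in shapiro.values()),
        homogeneity_violated=levene is not None and levene[1] < alpha,
        alpha=alpha,
    )
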