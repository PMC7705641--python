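"""Random-effects meta-analysis of study-level pressure summaries.

Built for pooling zero-flow pressure (P_zf) and mean circulatory filling
pressure (MCFP) measurements across animal and human studies, where large
between-study heterogeneity is the norm, but fully generic: each
:class:`StudyRecord` carries an effect mean, its standard error, and
optional covariates/subgroups/second arm.

Estimators (all moment-based, fully formula-specified):

* :func:`pool_random_effects` — DerSimonian–Laird between-study variance τ²
  with inverse-variance random-effects weights and normal-approximation
  95% CI; heterogeneity reported as Cochran's Q and I².
* :func:`prediction_interval` — Higgins–Thompson–Spiegelhalter interval
  pooled ± t_{0.975, k−2}·√(τ² + SE²), the range a *new* study's true
  effect is expected to fall in.
* :func:`pool_difference` — paired two-arm differences (e.g. P_zf − MCFP
  within the same study) pooled with within-study independence assumed.
* :func:`egger_test` — small-study (funnel asymmetry) regression of the
  standardized effect on precision.
* :func:`meta_regression` — method-of-moments random-effects regression on
  a study-level covariate (e.g. duration of flow cessation).
* :func:`subgroup_heterogeneity` — between-subgroup Q test (e.g. species).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaError",
    "StudyRecord",
    "MetaResult",
    "pool_random_effects",
    "prediction_interval",
    "pool_difference",
    "egger_test",
    "meta_regression",
    "subgroup_heterogeneity",
    "read_studies",
    "forest_table",
]

SPECIES = ("dog", "rat", "pig", "human", "other")


class MetaError(ValueError):
    """Raised for unusable study sets."""


@dataclass(frozen=True)
class StudyRecord:
    """One study's summary: effect mean y (mmHg) and its standard error.

    ``y2``/``se2`` optionally carry a second effect measured in the same
    animals (MCFP alongside P_zf) for paired-difference pooling;
    ``duration_zero_flow`` (s) and ``subgroup`` are optional covariates.
    """

    label: str
    y: float
    se: float
    n: int = 1
    species: str = "other"
    duration_zero_flow: float | None = None
    subgroup: str | None = None
    y2: float | None = None
    se2: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise MetaError(f"{self.label}: n must be >= 1")
        if not self.se > 0:
            raise MetaError(f"{self.label}: se must be positive")
        if (self.y2 is None) != (self.se2 is None):
            raise MetaError(f"{self.label}: y2 and se2 must be given together")
        if self.se2 is not None and not self.se2 > 0:
            raise MetaError(f"{self.label}: se2 must be positive")


@dataclass(frozen=True)
class MetaResult:
    """Pooled random-effects summary."""

    k: int
    pooled: float
    se_pooled: float
    ci95: tuple[float, float]
    tau2: float
    Q: float
    df: int
    I2: float
    weights: np.ndarray = field(repr=False)  # normalized, sum to 1
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.I2 <= 100):
            raise ValueError("I2 must lie in [0, 100]")
        if self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative")
        if not (self.ci95[0] <= self.pooled <= self.ci95[1]):
            raise ValueError("ci95 must contain the pooled estimate")


def _arrays(studies: Sequence[StudyRecord]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([s.y for s in studies], dtype=float)
    se = np.array([s.se for s in studies], dtype=float)
    return y, se


def _dl_pool(y: np.ndarray, se: np.ndarray, labels: tuple[str, ...]) -> MetaResult:
    k = y.size
    w = 1.0 / se**2
    ybar = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - ybar) ** 2))
    df = k - 1
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
    wstar = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(wstar * y) / np.sum(wstar))
    se_pooled = float(np.sum(wstar) ** -0.5)
    z = stats.norm.ppf(0.975)
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return MetaResult(
        k=k,
        pooled=pooled,
        se_pooled=se_pooled,
        ci95=(pooled - z * se_pooled, pooled + z * se_pooled),
        tau2=tau2,
        Q=Q,
        df=df,
        I2=I2,
        weights=wstar / np.sum(wstar),
        labels=labels,
    )


def pool_random_effects(studies: Sequence[StudyRecord]) -> MetaResult:
    """DerSimonian–Laird random-effects pooling.

    Fixed weights w_i = 1/se_i² give Cochran's Q; the moment estimator
    τ² = max(0, (Q − df)/(Σw − Σw²/Σw)) inflates the weights to
    w*_i = 1/(se_i² + τ²); the pooled mean, its SE and a z-based 95% CI
    follow.  I² = max(0, (Q − df)/Q)·100 expresses the share of total
    variability due to between-study heterogeneity.

    A single study is returned as-is (degenerate pooling, τ² = 0).
    """
    if len(studies) < 1:
        raise MetaError("insufficient studies: need at least 1")
    labels = tuple(s.label for s in studies)
    y, se = _arrays(studies)
    if y.size == 1:
        z = stats.norm.ppf(0.975)
        return MetaResult(
            k=1, pooled=float(y[0]), se_pooled=float(se[0]),
            ci95=(float(y[0] - z * se[0]), float(y[0] + z * se[0])),
            tau2=0.0, Q=0.0, df=0, I2=0.0, weights=np.ones(1), labels=labels,
        )
    return _dl_pool(y, se, labels)


def prediction_interval(res: MetaResult) -> tuple[float, float]:
    """95% prediction interval for the true effect of a new study.

    pooled ± t_{0.975, k−2}·√(τ² + SE_pooled²); undefined below 3 studies.
    """
    if res.k < 3:
        raise MetaError("prediction interval undefined for fewer than 3 studies")
    t = stats.t.ppf(0.975, res.k - 2)
    half = t * float(np.sqrt(res.tau2 + res.se_pooled**2))
    return (res.pooled - half, res.pooled + half)


def pool_difference(studies: Sequence[StudyRecord]) -> MetaResult:
    """Pool within-study differences y − y2 (e.g. P_zf − MCFP).

    The difference SE assumes the two arms are independent within a study,
    se_d = √(se² + se2²) — conservative when the arms are positively
    correlated, as repeated measurements in the same animals usually are.
    """
    for s in studies:
        if s.y2 is None or s.se2 is None:
            raise MetaError(f"{s.label}: not a paired record (missing y2/se2)")
    warnings.warn(
        "paired differences assume within-study independence of the two arms",
        RuntimeWarning,
        stacklevel=2,
    )
    diffs = [
        StudyRecord(
            label=s.label,
            y=s.y - s.y2,  # type: ignore[operator]
            se=float(np.hypot(s.se, s.se2)),  # type: ignore[arg-type]
            n=s.n,
            species=s.species,
            subgroup=s.subgroup,
        )
        for s in studies
    ]
    return pool_random_effects(diffs)


def egger_test(studies: Sequence[StudyRecord]) -> dict[str, float]:
    """Egger regression test for small-study (funnel-plot) asymmetry.

    Ordinary least squares of the standardized effect y_i/se_i on the
    precision 1/se_i; the intercept estimates the asymmetry, tested
    two-sided against t with k − 2 df.  A degenerate design (all
    precisions equal, or residual variance zero) is flagged with
    ``degenerate`` = 1 and p = NaN.
    """
    k = len(studies)
    if k < 3:
        raise MetaError("underdetermined: Egger test needs at least 3 studies")
    y, se = _arrays(studies)
    ystar = y / se
    prec = 1.0 / se
    X = np.column_stack([np.ones(k), prec])
    if np.ptp(prec) < 1e-12 * np.max(prec):
        return {"intercept": np.nan, "se_intercept": np.nan, "p": np.nan,
                "slope": np.nan, "degenerate": 1.0}
    beta, *_ = np.linalg.lstsq(X, ystar, rcond=None)
    resid = ystar - X @ beta
    dof = k - 2
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se_int = float(np.sqrt(cov[0, 0]))
    if s2 < 1e-24 or se_int == 0.0:
        return {"intercept": float(beta[0]), "se_intercept": 0.0, "p": np.nan,
                "slope": float(beta[1]), "degenerate": 1.0}
    tval = beta[0] / se_int
    p = 2.0 * stats.t.sf(abs(tval), dof)
    return {"intercept": float(beta[0]), "se_intercept": se_int, "p": float(p),
            "slope": float(beta[1]), "degenerate": 0.0}


def meta_regression(
    studies: Sequence[StudyRecord], covariate: Sequence[float]
) -> dict[str, float]:
    """Method-of-moments random-effects meta-regression on one covariate.

    A fixed-effects WLS fit (weights 1/se²) yields the residual Q_E; the
    residual between-study variance solves the moment equation
    τ²_res = max(0, (Q_E − (k−2))/(Σw − tr[(XᵀWX)⁻¹XᵀW²X])).  The model is
    then refit with weights 1/(se² + τ²_res) and the slope tested two-sided
    against t with k − 2 df.
    """
    k = len(studies)
    if k < 4:
        raise MetaError("meta-regression needs at least 4 studies")
    x = np.asarray(covariate, dtype=float)
    if x.size != k:
        raise MetaError("covariate length must match the number of studies")
    if np.ptp(x) < 1e-12 * max(1.0, float(np.max(np.abs(x)))):
        raise MetaError("covariate constant: zero variance")
    y, se = _arrays(studies)
    X = np.column_stack([np.ones(k), x])

    def wls(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        W = np.diag(weights)
        XtWX_inv = np.linalg.inv(X.T @ W @ X)
        beta = XtWX_inv @ X.T @ W @ y
        return beta, XtWX_inv

    w = 1.0 / se**2
    beta_fe, XtWX_inv = wls(w)
    resid = y - X @ beta_fe
    Q_E = float(np.sum(w * resid**2))
    trace = float(np.trace(XtWX_inv @ (X.T @ np.diag(w**2) @ X)))
    denom = float(np.sum(w)) - trace
    tau2 = max(0.0, (Q_E - (k - 2)) / denom) if denom > 0 else 0.0

    wstar = 1.0 / (se**2 + tau2)
    beta, cov_unscaled = wls(wstar)
    se_slope = float(np.sqrt(cov_unscaled[1, 1]))
    tval = beta[1] / se_slope
    p = 2.0 * stats.t.sf(abs(tval), k - 2)
    return {
        "intercept": float(beta[0]),
        "slope": float(beta[1]),
        "se_slope": se_slope,
        "p": float(p),
        "tau2_residual": tau2,
        "Q_E": Q_E,
    }


def subgroup_heterogeneity(
    studies: Sequence[StudyRecord], by: str = "subgroup"
) -> dict[str, float]:
    """Test for heterogeneity between subgroup pooled effects.

    Each subgroup (``by`` = "subgroup" or "species") with at least two
    studies is pooled by DerSimonian–Laird; subgroups smaller than two are
    excluded with a warning.  Q_between = Σ_g w_g·(pooled_g − grand)², with
    w_g = 1/SE_g² and the grand mean the w_g-weighted average, is referred
    to chi-square with (groups − 1) df.
    """
    groups: dict[str, list[StudyRecord]] = {}
    for s in studies:
        key = getattr(s, by) if by != "subgroup" else s.subgroup
        if key is None:
            key = "(none)"
        groups.setdefault(str(key), []).append(s)
    kept = {g: ss for g, ss in groups.items() if len(ss) >= 2}
    dropped = sorted(set(groups) - set(kept))
    if dropped:
        warnings.warn(
            f"subgroups excluded with fewer than 2 studies: {dropped}",
            RuntimeWarning,
            stacklevel=2,
        )
    if len(kept) < 2:
        raise MetaError("need at least 2 subgroups with >= 2 studies each")
    pooled = {g: pool_random_effects(ss) for g, ss in kept.items()}
    wg = np.array([1.0 / r.se_pooled**2 for r in pooled.values()])
    mg = np.array([r.pooled for r in pooled.values()])
    grand = float(np.sum(wg * mg) / np.sum(wg))
    Q_between = float(np.sum(wg * (mg - grand) ** 2))
    df = len(kept) - 1
    p = float(stats.chi2.sf(Q_between, df))
    return {"Q_between": Q_between, "df": float(df), "p": p,
            "n_groups": float(len(kept))}


# ---------------------------------------------------------------------------
# I/O


def read_studies(path) -> list[StudyRecord]:
    """Read study summaries from CSV.

    Required columns: label, y, and either se or (sd and n); optional:
    n, species, y2, se2 (or sd2 with n), duration_s, subgroup.  SD columns
    are converted at ingest via se = sd/√n.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "label" not in df or "y" not in df:
        raise MetaError("CSV needs at least 'label' and 'y' columns")
    records: list[StudyRecord] = []
    for _, row in df.iterrows():
        n = int(row["n"]) if "n" in df and pd.notna(row.get("n")) else 1
        if "se" in df and pd.notna(row.get("se")):
            se = float(row["se"])
        elif "sd" in df and pd.notna(row.get("sd")):
            se = float(row["sd"]) / np.sqrt(n)
        else:
            raise MetaError(f"{row['label']}: need se, or sd with n")
        y2 = se2 = None
        if "y2" in df and pd.notna(row.get("y2")):
            y2 = float(row["y2"])
            if "se2" in df and pd.notna(row.get("se2")):
                se2 = float(row["se2"])
            elif "sd2" in df and pd.notna(row.get("sd2")):
                se2 = float(row["sd2"]) / np.sqrt(n)
            else:
                raise MetaError(f"{row['label']}: y2 needs se2 or sd2")
        records.append(
            StudyRecord(
                label=str(row["label"]),
                y=float(row["y"]),
                se=se,
                n=n,
                species=str(row["species"]) if "species" in df and pd.notna(row.get("species")) else "other",
                duration_zero_flow=float(row["duration_s"]) if "duration_s" in df and pd.notna(row.get("duration_s")) else None,
                subgroup=str(row["subgroup"]) if "subgroup" in df and pd.notna(row.get("subgroup")) else None,
                y2=y2,
                se2=se2,
            )
        )
    return records


def forest_table(studies: Sequence[StudyRecord], res: MetaResult) -> pd.DataFrame:
    """Forest-plot-ready table: per-study effect, 95% CI and RE weight."""
    z = stats.norm.ppf(0.975)
    rows = [
        {
            "label": s.label,
            "effect": s.y,
            "ci_lo": s.y - z * s.se,
            "ci_hi": s.y + z * s.se,
            "weight_pct": 100.0 * float(wi),
        }
        for s, wi in zip(studies, res.weights)
    ]
    rows.append(
        {
            "label": "RE pooled",
            "effect": res.pooled,
            "ci_lo": res.ci95[0],
            "ci_hi": res.ci95[1],
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)
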