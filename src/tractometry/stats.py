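"""Point-wise along-tract group statistics.

At every sample point of every fiber slot, the scalar metric is regressed
on a disease indicator (disease = 1, reference = 0) with age, sex and
brain volume as covariates, by ordinary least squares.  The two-sided
p-values of the disease coefficient are pooled across *all* bundles,
fiber slots and points for one metric and comparison, and corrected with
the Benjamini-Hochberg step-up procedure at level q.  The "critical P" is
the largest p-value declared significant.

Effect sizes use the correlation-scale transform r = sqrt(t^2/(t^2+df))
with df defined as the number of subjects in the comparison minus 2.
Per-bundle summaries report the percentage of tested points that are
FDR-significant *and* in the hypothesized direction (FA decreased, MD/RD/
AX increased in disease), and metrics/tracts are ranked by mean percent
affected (tracts by the MD/RD average).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .extraction import SubjectTractProfile
from .tensor import METRICS

__all__ = [
    "PointwiseResultMap",
    "RankingTable",
    "GROUPS",
    "load_design",
    "validate_design",
    "pointwise_regression",
    "mmse_association",
    "bh_fdr",
    "effect_size",
    "expected_direction",
    "percent_tract_affected",
    "summarize",
    "rank_from_summary",
    "summarize_and_rank",
]

GROUPS = ("control", "bvFTD", "EOAD")

#: Hypothesized direction of disease effects per metric: anisotropy falls,
#: diffusivities rise.
_DIRECTION = {"FA": -1, "MD": +1, "RD": +1, "AX": +1}


@dataclass
class PointwiseResultMap:
    """Per-point regression results for one metric and one comparison."""

    metric: str
    comparison: tuple[str, str]  # (coded 1, coded 0)
    bundle: np.ndarray  # bundle abbreviation per tested point
    slot: np.ndarray  # fiber slot index per tested point
    point: np.ndarray  # 0-based sample point index per tested point
    coef: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r: np.ndarray
    significant: np.ndarray = field(default=None)  # set by apply_fdr
    critical_p: float = 0.0
    n_subjects: int = 0
    df: int = 0  # n_subjects - 2, the effect-size degrees of freedom

    @property
    def n_points(self) -> int:
        return self.p.size

    def apply_fdr(self, q: float = 0.05) -> "PointwiseResultMap":
        self.significant, self.critical_p = bh_fdr(self.p, q)
        return self


@dataclass
class RankingTable:
    """Metric and tract rankings for one comparison."""

    comparison: str
    mean_percent_tract: dict[str, float]  # metric -> mean over bundles
    mean_r: dict[str, float]  # metric -> mean over bundles
    metric_ranking: list[str]  # descending mean percent tract
    tract_ranking: list[str]  # descending (MD + RD)/2 percent tract


# ---------------------------------------------------------------------------
# Cohort design table


def load_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path)
    validate_design(design)
    return design


def validate_design(design: pd.DataFrame) -> None:
    required = {"id", "group", "age", "sex", "brain_volume"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns {sorted(missing)}")
    if design["id"].duplicated().any():
        raise ValueError("duplicate subject ids in design table")
    unknown = set(design["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown groups {sorted(unknown)}; expected {GROUPS}")
    bad_sex = set(design["sex"]) - {"M", "F"}
    if bad_sex:
        raise ValueError(f"sex must be 'M' or 'F', found {sorted(bad_sex)}")


# ---------------------------------------------------------------------------
# Vectorized per-point OLS


def _check_collinearity(x: np.ndarray, names: list[str]) -> None:
    n, k = x.shape
    if n <= k:
        raise ValueError(
            f"need more subjects ({n}) than regressors ({k}) for OLS"
        )
    if np.linalg.matrix_rank(x) == k:
        return
    offending = []
    for j in range(k):
        others = np.delete(x, j, axis=1)
        _, res, *_ = np.linalg.lstsq(others, x[:, j], rcond=None)
        ssr = res[0] if res.size else np.sum(
            (x[:, j] - others @ np.linalg.lstsq(others, x[:, j], rcond=None)[0]) ** 2
        )
        if ssr < 1e-10 * max(1.0, np.sum(x[:, j] ** 2)):
            offending.append(names[j])
    raise ValueError(f"design matrix is collinear; offending columns: {offending}")


def _pointwise_ols(
    y: np.ndarray, x: np.ndarray, predictor: int, names: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of each column of ``y`` (n_subjects, n_points) on ``x``.

    Returns (coefficient, t, two-sided p) for the ``predictor`` column.
    All points share the design matrix, so the fit is two matrix
    products: beta = pinv(X) Y and the residual sum of squares.
    """
    _check_collinearity(x, names)
    n, k = x.shape
    pinv = np.linalg.pinv(x)
    beta = pinv @ y  # (k, n_points)
    resid = y - x @ beta
    dof = n - k
    sigma2 = np.sum(resid**2, axis=0) / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(sigma2 * xtx_inv[predictor, predictor])
    coef = beta[predictor]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    # A point where the response is (numerically) constant has no signal:
    # both the coefficient and its SE are at rounding level, so their ratio
    # is noise.  Report t = 0, p = 1 there.
    y_rms = np.sqrt(np.mean(y**2, axis=0)) + 1e-300
    degenerate = (np.abs(coef) < 1e-8 * y_rms) & (se < 1e-8 * y_rms)
    t = np.where(degenerate, 0.0, t)
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    return coef, t, p


def _stack_profiles(
    profiles: dict[str, SubjectTractProfile],
    subject_ids: list[str],
    metric: str,
    bundle_order: list[str] | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pool one metric into Y (n_subjects, n_points) plus point labels."""
    metric_idx = METRICS.index(metric)
    first = profiles[subject_ids[0]]
    order = bundle_order if bundle_order is not None else list(first.values.keys())
    bundles, slots, points = [], [], []
    for name in order:
        n_slots, k, _ = first.values[name].shape
        bundles.append(np.repeat(name, n_slots * k))
        slots.append(np.repeat(np.arange(n_slots), k))
        points.append(np.tile(np.arange(k), n_slots))
    bundle_lab = np.concatenate(bundles)
    slot_lab = np.concatenate(slots)
    point_lab = np.concatenate(points)
    y = np.empty((len(subject_ids), bundle_lab.size))
    for i, sid in enumerate(subject_ids):
        prof = profiles[sid]
        y[i] = np.concatenate(
            [prof.values[name][:, :, metric_idx].ravel() for name in order]
        )
    return y, bundle_lab, slot_lab, point_lab


def _covariate_matrix(rows: pd.DataFrame) -> np.ndarray:
    return np.column_stack(
        [
            rows["age"].to_numpy(float),
            (rows["sex"] == "M").to_numpy(float),
            rows["brain_volume"].to_numpy(float),
        ]
    )


def pointwise_regression(
    profiles: dict[str, SubjectTractProfile],
    design: pd.DataFrame,
    metric: str,
    comparison: tuple[str, str],
    bundle_order: list[str] | None = None,
    q: float | None = 0.05,
) -> PointwiseResultMap:
    """Disease-versus-reference OLS at every tested point of one metric.

    ``comparison`` is (group coded 1, group coded 0); positive t means the
    metric is higher in the coded-1 group.  With ``q`` set, BH-FDR is
    applied across the pooled points and the significance flags and
    critical P attached.
    """
    validate_design(design)
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    disease, reference = comparison
    rows = design[design["group"].isin(comparison)].reset_index(drop=True)
    for g in comparison:
        if not (rows["group"] == g).any():
            raise ValueError(f"comparison group {g!r} has no subjects")
    missing = [sid for sid in rows["id"] if sid not in profiles]
    if missing:
        raise ValueError(f"subjects without profiles: {missing}")
    ids = rows["id"].tolist()
    y, bundle_lab, slot_lab, point_lab = _stack_profiles(
        profiles, ids, metric, bundle_order
    )
    indicator = (rows["group"] == disease).to_numpy(float)
    x = np.column_stack(
        [np.ones(len(rows)), indicator, _covariate_matrix(rows)]
    )
    names = ["intercept", "disease", "age", "sex", "brain_volume"]
    coef, t, p = _pointwise_ols(y, x, predictor=1, names=names)
    n = len(rows)
    result = PointwiseResultMap(
        metric=metric,
        comparison=comparison,
        bundle=bundle_lab,
        slot=slot_lab,
        point=point_lab,
        coef=coef,
        t=t,
        p=p,
        r=effect_size(t, n - 2),
        n_subjects=n,
        df=n - 2,
    )
    if q is not None:
        result.apply_fdr(q)
    return result


def mmse_association(
    profiles: dict[str, SubjectTractProfile],
    design: pd.DataFrame,
    metric: str,
    bundle_order: list[str] | None = None,
    include_covariates: bool = True,
    q: float | None = 0.05,
) -> PointwiseResultMap:
    """Point-wise association of a metric with MMSE across all subjects.

    By default age, sex and brain volume are included as covariates; the
    MMSE slope's t, p and effect size are reported per point.
    """
    validate_design(design)
    if "mmse" not in design.columns:
        raise ValueError("design table has no 'mmse' column")
    missing_mmse = design.loc[design["mmse"].isna(), "id"].tolist()
    if missing_mmse:
        raise ValueError(f"subjects missing MMSE: {missing_mmse}")
    rows = design.reset_index(drop=True)
    ids = rows["id"].tolist()
    y, bundle_lab, slot_lab, point_lab = _stack_profiles(
        profiles, ids, metric, bundle_order
    )
    mmse = rows["mmse"].to_numpy(float)
    if include_covariates:
        x = np.column_stack([np.ones(len(rows)), mmse, _covariate_matrix(rows)])
        names = ["intercept", "mmse", "age", "sex", "brain_volume"]
    else:
        x = np.column_stack([np.ones(len(rows)), mmse])
        names = ["intercept", "mmse"]
    coef, t, p = _pointwise_ols(y, x, predictor=1, names=names)
    n = len(rows)
    result = PointwiseResultMap(
        metric=metric,
        comparison=("mmse", "all"),
        bundle=bundle_lab,
        slot=slot_lab,
        point=point_lab,
        coef=coef,
        t=t,
        p=p,
        r=effect_size(t, n - 2),
        n_subjects=n,
        df=n - 2,
    )
    if q is not None:
        result.apply_fdr(q)
    return result


# ---------------------------------------------------------------------------
# Multiple testing, effect sizes, summaries


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over a pooled p-value vector.

    Returns ``(flags, critical_p)`` where ``critical_p`` is the largest
    p-value declared significant (0.0 when nothing is rejected).
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    critical_p = float(p[reject].max()) if reject.any() else 0.0
    return reject, critical_p


def effect_size(t: np.ndarray | float, df: int | np.ndarray) -> np.ndarray | float:
    """r = sqrt(t^2 / (t^2 + df)); sign-free, in [0, 1)."""
    df_arr = np.asarray(df, dtype=float)
    if np.any(df_arr < 1):
        raise ValueError("df must be >= 1")
    t_arr = np.asarray(t, dtype=float)
    r = np.sqrt(t_arr**2 / (t_arr**2 + df_arr))
    return float(r) if r.ndim == 0 else r


def expected_direction(metric: str) -> int:
    """+1 if the metric is hypothesized to increase in disease, -1 if to fall."""
    try:
        return _DIRECTION[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}") from None


def percent_tract_affected(
    significant: np.ndarray,
    coef: np.ndarray,
    direction: int,
    slots: np.ndarray | None = None,
    unit: str = "points",
) -> float:
    """Percent of a bundle's tested points that are FDR-significant in the
    hypothesized direction.

    ``unit="fibers"`` instead counts a fiber slot as affected when at
    least half of its points qualify.
    """
    sig = np.asarray(significant, dtype=bool)
    if sig.size == 0:
        raise ValueError("empty bundle")
    hit = sig & (np.sign(np.asarray(coef)) == direction)
    if unit == "points":
        return 100.0 * hit.mean()
    if unit == "fibers":
        if slots is None:
            raise ValueError("fiber-level percentages require slot labels")
        frame = pd.DataFrame({"slot": slots, "hit": hit})
        per_fiber = frame.groupby("slot")["hit"].mean() >= 0.5
        return 100.0 * per_fiber.mean()
    raise ValueError(f"unknown unit {unit!r}")


def summarize(
    results: dict[str, PointwiseResultMap],
    bundle_order: list[str] | None = None,
    unit: str = "points",
    tract_r: str = "mean_point_r",
) -> pd.DataFrame:
    """Per-bundle summary table across metrics for one comparison.

    ``tract_r`` selects the bundle-level effect size: the mean of
    point-wise r (default) or r recomputed from the bundle-mean t
    (``"from_mean_t"``).
    """
    records = []
    for metric, res in results.items():
        if res.significant is None:
            raise ValueError(f"result for {metric} has no FDR flags; call apply_fdr")
        order = (
            bundle_order
            if bundle_order is not None
            else list(dict.fromkeys(res.bundle.tolist()))
        )
        direction = expected_direction(metric)
        comparison = f"{res.comparison[0]}_vs_{res.comparison[1]}"
        for name in order:
            mask = res.bundle == name
            if not mask.any():
                raise ValueError(f"no tested points for bundle {name!r}")
            pct = percent_tract_affected(
                res.significant[mask], res.coef[mask], direction,
                slots=res.slot[mask], unit=unit,
            )
            if tract_r == "mean_point_r":
                r_val = float(res.r[mask].mean())
            elif tract_r == "from_mean_t":
                r_val = float(effect_size(res.t[mask].mean(), res.df))
            else:
                raise ValueError(f"unknown tract_r {tract_r!r}")
            records.append(
                {
                    "comparison": comparison,
                    "metric": metric,
                    "bundle": name,
                    "percent_tract": pct,
                    "mean_r": r_val,
                    "critical_p": res.critical_p,
                }
            )
    return pd.DataFrame.from_records(records)


def rank_from_summary(summary: pd.DataFrame, comparison: str | None = None) -> RankingTable:
    """Metric and tract rankings from a per-bundle summary table.

    The metric ranking orders metrics by their mean percent-tract over
    all bundles; the tract ranking orders bundles by the MD/RD-averaged
    percent-tract, high to low, ties keeping first-appearance order.
    """
    df = summary
    if comparison is not None:
        df = df[df["comparison"] == comparison]
    elif df["comparison"].nunique() == 1:
        comparison = df["comparison"].iloc[0]
    else:
        raise ValueError("summary holds several comparisons; pass one explicitly")
    metrics = [m for m in METRICS if m in set(df["metric"])]
    bundle_order = list(dict.fromkeys(df["bundle"].tolist()))
    per_metric_bundles = {m: set(df.loc[df["metric"] == m, "bundle"]) for m in metrics}
    for m in metrics:
        missing = [b for b in bundle_order if b not in per_metric_bundles[m]]
        if missing:
            raise ValueError(f"metric {m} missing bundles {missing}")
    mean_pct = {
        m: float(df.loc[df["metric"] == m, "percent_tract"].mean()) for m in metrics
    }
    mean_r = {m: float(df.loc[df["metric"] == m, "mean_r"].mean()) for m in metrics}
    metric_ranking = sorted(metrics, key=lambda m: -mean_pct[m])
    if {"MD", "RD"} <= set(metrics):
        wide = df.pivot(index="bundle", columns="metric", values="percent_tract")
        md_rd = ((wide["MD"] + wide["RD"]) / 2.0).reindex(bundle_order)
        tract_ranking = sorted(
            bundle_order, key=lambda b: (-md_rd[b], bundle_order.index(b))
        )
    else:
        tract_ranking = list(bundle_order)
    return RankingTable(
        comparison=comparison,
        mean_percent_tract=mean_pct,
        mean_r=mean_r,
        metric_ranking=metric_ranking,
        tract_ranking=tract_ranking,
    )


def summarize_and_rank(
    results: dict[str, PointwiseResultMap],
    bundle_order: list[str] | None = None,
    unit: str = "points",
) -> tuple[pd.DataFrame, RankingTable]:
    summary = summarize(results, bundle_order=bundle_order, unit=unit)
    return summary, rank_from_summary(summary)
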