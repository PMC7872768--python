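"""Group inference: AUC summaries, label permutation, FDR, partial correlation.

Because each group yields a single covariance network, group differences in
a graph metric cannot be tested subject-wise. Instead each metric's curve
over the sparsity range is reduced to its area under the curve (AUC,
trapezoid rule), and the observed AUC difference is referred to a
permutation distribution: in every cycle the confound-adjusted regional
volume rows are reshuffled between the two groups (original sizes kept),
both networks are rebuilt from scratch, and the metric AUCs recomputed.
The two-tailed p-value uses the add-one convention
p = (#{|null| >= |observed|} + 1) / (R + 1), so p is never exactly zero.

Nodal metrics produce one test per region; their p-values are adjusted by
Benjamini-Hochberg FDR within each metric (one family of N nodes per
metric). Global metrics are reported unadjusted.

Clinical association uses the partial correlation: Pearson correlation of
the residuals of the two variables after regressing each on the covariates
(age, gender), with t = r * sqrt(df / (1 - r^2)) on df = n - 2 - k.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import graphmetrics, scn
from .data_io import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MetricCurve",
    "PermutationResult",
    "PartialCorrelationResult",
    "auc_trapezoid",
    "metric_curve_extractor",
    "permutation_test",
    "bh_fdr",
    "partial_correlation",
    "clinical_partial_correlations",
]


@dataclasses.dataclass
class MetricCurve:
    """One metric's values over the sparsity grid, for one group."""

    metric: str
    group: str
    sparsities: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != len(self.sparsities):
            raise ValidationError("curve length does not match sparsity grid")

    @property
    def auc(self) -> float:
        return auc_trapezoid(self.values, self.sparsities)


@dataclasses.dataclass
class PermutationResult:
    """AUC permutation test outcome for one metric (global or per-node).

    For a global metric the AUC fields are scalars and ``q`` is None; for a
    nodal metric they are arrays over nodes and ``q`` holds BH-FDR adjusted
    p-values across the node family.
    """

    metric: str
    sparsities: np.ndarray
    auc_group1: np.ndarray | float
    auc_group2: np.ndarray | float
    observed_diff: np.ndarray | float
    null_diffs: np.ndarray
    p: np.ndarray | float
    q: np.ndarray | None
    n_perm: int
    labels: list[str] | None = None

    @property
    def nodal(self) -> bool:
        return np.ndim(self.observed_diff) == 1

    def to_frame(self) -> pd.DataFrame:
        if not self.nodal:
            return pd.DataFrame(
                [{
                    "metric": self.metric,
                    "auc_group1": self.auc_group1,
                    "auc_group2": self.auc_group2,
                    "diff": self.observed_diff,
                    "p": self.p,
                }]
            )
        labels = self.labels or [f"node{k}" for k in range(len(self.observed_diff))]
        return pd.DataFrame(
            {
                "metric": self.metric,
                "node": labels,
                "auc_group1": self.auc_group1,
                "auc_group2": self.auc_group2,
                "diff": self.observed_diff,
                "p": self.p,
                "q": self.q,
            }
        )


@dataclasses.dataclass
class PartialCorrelationResult:
    roi: str
    variable: str
    r: float
    p: float
    df: int
    n: int


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


def auc_trapezoid(values, sparsities) -> float | np.ndarray:
    """Trapezoidal area under a metric curve over the sparsity axis.

    ``values`` may be (L,) for a global metric or (L, N) for nodal curves
    (integrated column-wise).
    """
    values = np.asarray(values, dtype=float)
    s = np.asarray(sparsities, dtype=float)
    if len(s) < 2:
        raise ValidationError("need at least 2 sparsity points")
    if np.any(np.diff(s) <= 0):
        raise ValidationError("sparsities must be strictly increasing")
    if values.shape[0] != len(s):
        raise ValidationError(
            f"curve has {values.shape[0]} points for {len(s)} sparsities"
        )
    out = np.trapezoid(values, s, axis=0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Metric curve extractors (residuals -> curve), shared by pipeline and tests
# ---------------------------------------------------------------------------


def _check_no_constant(residuals: np.ndarray) -> None:
    if np.any(residuals.std(axis=0) == 0):
        raise ValidationError("constant ROI column in group")


def _degree_curves(residuals: np.ndarray, sparsities: np.ndarray, rule: str) -> np.ndarray:
    """(L, N) degree curves straight from the edge ranking (no graph stack)."""
    _check_no_constant(residuals)
    r = np.corrcoef(residuals.T)
    n = r.shape[0]
    L = len(sparsities)
    ei, ej, levels, _ = scn.first_inclusion_levels(r, sparsities, rule)
    keep = levels < L
    deg = np.zeros((L, n))
    np.add.at(deg, (levels[keep], ei[keep]), 1.0)
    np.add.at(deg, (levels[keep], ej[keep]), 1.0)
    return np.cumsum(deg, axis=0)


def _stack_for(residuals: np.ndarray, sparsities: np.ndarray, rule: str) -> np.ndarray:
    _check_no_constant(residuals)
    r = np.corrcoef(residuals.T)
    return scn.adjacency_stack(r, sparsities, rule)


def metric_curve_extractor(
    metric: str,
    sparsities: Sequence[float],
    rule: str = "round",
    bc_normalized: bool = False,
    small_world_nulls: int = 100,
) -> Callable:
    """Build ``f(residuals, rng=None) -> curve`` for one metric.

    Global metrics return an (L,) curve, nodal metrics (L, N). The callable
    recomputes the group correlation network and the whole thresholded
    series on every call — exactly what each permutation cycle needs.
    """
    s = np.asarray(sparsities, dtype=float)
    L = len(s)

    def extract(residuals: np.ndarray, rng=None) -> np.ndarray:
        if metric == "degree":
            return _degree_curves(residuals, s, rule)
        stack = _stack_for(residuals, s, rule)
        n = stack.shape[1]
        if metric == "clustering":
            return graphmetrics._stack_clustering(stack).mean(axis=1)
        if metric in ("path_length", "global_efficiency", "nodal_efficiency"):
            dist = graphmetrics._stack_distances(stack)
            with np.errstate(divide="ignore"):
                inv = 1.0 / dist
            inv[:, np.arange(n), np.arange(n)] = 0.0
            inv[~np.isfinite(inv)] = 0.0
            if metric == "global_efficiency":
                return inv.sum(axis=(1, 2)) / (n * (n - 1))
            if metric == "nodal_efficiency":
                return inv.sum(axis=2) / (n - 1)
            off = ~np.eye(n, dtype=bool)
            finite = np.isfinite(dist) & off
            return np.array(
                [dist[k][finite[k]].mean() if finite[k].any() else np.nan for k in range(L)]
            )
        if metric == "local_efficiency":
            return np.array(
                [graphmetrics.local_efficiency(stack[k])[1] for k in range(L)]
            )
        if metric == "betweenness":
            return np.array(
                [graphmetrics.betweenness_centrality(stack[k], normalized=bc_normalized)
                 for k in range(L)]
            )
        if metric == "small_world":
            rng = np.random.default_rng(rng)
            return np.array(
                [graphmetrics.small_worldness(stack[k], n_null=small_world_nulls, rng=rng)
                 for k in range(L)]
            )
        raise ValueError(f"unknown metric {metric!r}")

    extract.metric = metric
    extract.sparsities = s
    return extract


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------


def permutation_test(
    residuals_group1: np.ndarray,
    residuals_group2: np.ndarray,
    extractor: Callable,
    sparsities: Sequence[float],
    n_perm: int = 5000,
    rng=None,
    labels: Sequence[str] | None = None,
    metric: str | None = None,
    exact: bool = False,
    max_resample: int = 100,
) -> PermutationResult:
    """Two-tailed AUC permutation test between two groups of residual rows.

    Each cycle reassigns subjects' adjusted regional volumes to two new
    groups of the original sizes, rebuilds both covariance networks and the
    thresholded series, and recomputes the metric AUC difference
    (group1 - group2). ``exact=True`` enumerates every distinct assignment
    instead of sampling (feasible only for tiny cohorts); p is then the
    add-one-corrected tail fraction over the enumerated assignments.

    Permutations that produce a constant ROI within a permuted group are
    resampled (logged); with continuous data this is measure-zero.
    """
    res1 = np.asarray(residuals_group1, dtype=float)
    res2 = np.asarray(residuals_group2, dtype=float)
    if res1.shape[0] < 3 or res2.shape[0] < 3:
        raise ValidationError("each group needs at least 3 subjects")
    if not exact and n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    s = np.asarray(sparsities, dtype=float)
    rng = np.random.default_rng(rng)
    name = metric or getattr(extractor, "metric", "metric")

    c1 = extractor(res1, rng=rng)
    c2 = extractor(res2, rng=rng)
    auc1 = auc_trapezoid(c1, s)
    auc2 = auc_trapezoid(c2, s)
    observed = auc1 - auc2

    pooled = np.vstack([res1, res2])
    n = pooled.shape[0]
    n1 = res1.shape[0]

    if exact:
        assignments = itertools.combinations(range(n), n1)
        null = []
        for idx1 in assignments:
            m = np.zeros(n, dtype=bool)
            m[list(idx1)] = True
            d = auc_trapezoid(extractor(pooled[m], rng=rng), s) - auc_trapezoid(
                extractor(pooled[~m], rng=rng), s
            )
            null.append(d)
        null = np.asarray(null)
    else:
        null = []
        for _ in range(n_perm):
            for _retry in range(max_resample):
                perm = rng.permutation(n)
                try:
                    d = auc_trapezoid(
                        extractor(pooled[perm[:n1]], rng=rng), s
                    ) - auc_trapezoid(extractor(pooled[perm[n1:]], rng=rng), s)
                except ValidationError:
                    logger.info("degenerate permutation resampled (constant ROI)")
                    continue
                null.append(d)
                break
            else:
                raise ValidationError("could not draw a non-degenerate permutation")
        null = np.asarray(null)

    R = null.shape[0]
    exceed = (np.abs(null) >= np.abs(observed)).sum(axis=0)
    p = (exceed + 1) / (R + 1)
    q = None
    if np.ndim(observed) == 1:
        q = bh_fdr(p)
    return PermutationResult(
        metric=name,
        sparsities=s,
        auc_group1=auc1,
        auc_group2=auc2,
        observed_diff=observed,
        null_diffs=null,
        p=p if np.ndim(p) else float(p),
        q=q,
        n_perm=R,
        labels=list(labels) if labels is not None else None,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Partial correlation
# ---------------------------------------------------------------------------


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_correlation(
    x,
    y,
    covariates=None,
    roi: str = "x",
    variable: str = "y",
) -> PartialCorrelationResult:
    """Pearson correlation of x and y after removing covariates from both.

    With no covariates this reduces to the plain Pearson correlation with
    df = n - 2. Rows with missing values in any input are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        Zc = np.empty((len(x), 0))
    else:
        Zc = np.asarray(covariates, dtype=float)
        if Zc.ndim == 1:
            Zc = Zc[:, None]
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(Zc).all(axis=1)
    x, y, Zc = x[ok], y[ok], Zc[ok]
    n = len(x)
    k = Zc.shape[1]
    if n <= k + 2:
        raise ValidationError(f"need n > {k + 2} complete observations, got {n}")
    Z = np.column_stack([np.ones(n), Zc])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValidationError("covariate matrix is rank deficient")
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValidationError("zero variance after residualization")
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(roi=roi, variable=variable, r=r, p=p, df=df, n=n)


def clinical_partial_correlations(
    volumes,
    cohort,
    rois: Sequence[str],
    variables: Sequence[str],
    covariates: Sequence[str] = ("age", "gender"),
    group=None,
) -> pd.DataFrame:
    """ROI-by-variable grid of covariate-adjusted correlations (one group).

    ``volumes`` is a RegionalVolumeTable aligned with ``cohort``; rows are
    restricted to ``group`` (default: first group level). P-values are
    reported unadjusted across the grid.
    """
    cohort = cohort.aligned_to(volumes)
    level = group if group is not None else cohort.group_levels[0]
    mask = cohort.subjects_in_group(level)
    Z = np.column_stack([cohort.data[c].to_numpy(dtype=float)[mask] for c in covariates])
    rows = []
    for roi in rois:
        j = volumes.roi_labels.index(roi)
        x = volumes.volumes[mask, j]
        for var in variables:
            y = cohort.data[var].to_numpy(dtype=float)[mask]
            res = partial_correlation(x, y, Z, roi=roi, variable=var)
            rows.append(dataclasses.asdict(res))
    return pd.DataFrame(rows)
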