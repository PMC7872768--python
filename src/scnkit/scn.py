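"""Structural covariance networks and sparsity-thresholded binary graphs.

Each group's network has one node per atlas region; the edge weight between
regions is the Pearson correlation of their confound-adjusted volumes across
the subjects of that group. To compare groups at equal edge count, the
absolute correlation matrix is proportionally thresholded over a sparsity
range (default 0.05 to 0.50 in steps of 0.01, 46 levels): at sparsity S the
K = round(S * N(N-1)/2) strongest |r| edges are kept and binarized. Ties in
|r| are broken by ascending (i, j) node-pair order so a run is reproducible
bit-for-bit; because the edge ranking is fixed once per network, the graph
series is nested (every edge present at a smaller sparsity is present at
every larger one).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ValidationError

__all__ = [
    "CovarianceNetwork",
    "BinaryGraphSeries",
    "build_covariance_network",
    "edge_count_for_sparsity",
    "threshold_by_sparsity",
    "default_sparsities",
    "build_graph_series",
    "ranked_edges",
    "first_inclusion_levels",
    "edge_list_frame",
]


@dataclasses.dataclass
class CovarianceNetwork:
    """Per-group ROI x ROI Pearson correlation matrix (diagonal zeroed)."""

    group: str
    r_matrix: np.ndarray
    n_subjects: int
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.r_matrix, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValidationError("correlation matrix must be square")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValidationError("correlation matrix must be symmetric")
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0.0)
        if np.nanmax(np.abs(r)) > 1 + 1e-12:
            raise ValidationError("off-diagonal correlations must lie in [-1, 1]")
        self.r_matrix = r

    @property
    def n_roi(self) -> int:
        return self.r_matrix.shape[0]


@dataclasses.dataclass
class BinaryGraphSeries:
    """Stack of undirected unweighted graphs, one per sparsity level.

    ``adjacencies`` has shape (n_levels, N, N), dtype uint8, symmetric with
    zero diagonal; ``edge_counts[s] == adjacencies[s].sum() / 2``.
    """

    sparsities: np.ndarray
    adjacencies: np.ndarray
    edge_counts: np.ndarray
    group: str = ""
    roi_labels: list[str] | None = None

    def __len__(self) -> int:
        return len(self.sparsities)

    def graph(self, idx: int) -> np.ndarray:
        return self.adjacencies[idx]


def build_covariance_network(
    residuals: np.ndarray,
    group: str = "",
    roi_labels: Sequence[str] | None = None,
) -> CovarianceNetwork:
    """Pearson correlation across subjects of one group's residual volumes.

    ``residuals`` is subjects x ROI; at least 3 subjects are required and no
    ROI column may be constant (its correlation is undefined).
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim != 2 or residuals.shape[0] < 3:
        raise ValidationError("need at least 3 subjects to correlate")
    sd = residuals.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        label = roi_labels[j] if roi_labels is not None else f"column {j}"
        raise ValidationError(f"ROI {label} is constant within group {group!r}")
    r = np.corrcoef(residuals.T)
    np.fill_diagonal(r, 0.0)
    return CovarianceNetwork(
        group=group,
        r_matrix=r,
        n_subjects=residuals.shape[0],
        roi_labels=list(roi_labels) if roi_labels is not None else None,
    )


def edge_count_for_sparsity(sparsity: float, n_nodes: int, rule: str = "round") -> int:
    """K = round(S * N(N-1)/2); ``rule='floor'`` truncates instead.

    ``round`` is conventional half-up rounding (not banker's) so the edge
    count is a deterministic function of the printed sparsity value.
    """
    n_pairs = n_nodes * (n_nodes - 1) // 2
    x = sparsity * n_pairs
    if rule == "round":
        k = int(np.floor(x + 0.5))
    elif rule == "floor":
        k = int(np.floor(x))
    else:
        raise ValueError(f"unknown rounding rule {rule!r}")
    return k


def ranked_edges(r_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs ordered by (|r| descending, pair ascending).

    Returns (i_idx, j_idx) arrays of length N(N-1)/2 in selection order.
    """
    r = np.asarray(r_matrix, dtype=float)
    n = r.shape[0]
    iu, ju = np.triu_indices(n, 1)
    a = np.abs(r[iu, ju])
    order = np.lexsort((ju, iu, -a))
    return iu[order], ju[order]


def threshold_by_sparsity(
    network: CovarianceNetwork | np.ndarray,
    sparsity: float,
    rule: str = "round",
) -> np.ndarray:
    """Binary adjacency keeping the K strongest-|r| edges at one sparsity."""
    r = network.r_matrix if isinstance(network, CovarianceNetwork) else np.asarray(network)
    n = r.shape[0]
    if sparsity > 1:
        raise ValidationError(f"sparsity {sparsity} exceeds 1")
    k = edge_count_for_sparsity(sparsity, n, rule)
    if k < 1:
        raise ValidationError(f"sparsity {sparsity} keeps no edges for N={n}")
    ei, ej = ranked_edges(r)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[ei[:k], ej[:k]] = 1
    adj[ej[:k], ei[:k]] = 1
    return adj


def default_sparsities() -> np.ndarray:
    """The standard thresholding grid: 0.05 to 0.50 in steps of 0.01."""
    return np.arange(5, 51) / 100.0


def sparsity_grid(s_min: float, s_max: float, step: float) -> np.ndarray:
    if not (s_min < s_max) or step <= 0:
        raise ValidationError("need s_min < s_max and step > 0")
    n = int(np.floor((s_max - s_min) / step + 0.5)) + 1
    grid = s_min + step * np.arange(n)
    return np.round(grid[grid <= s_max + 1e-12], 12)


def first_inclusion_levels(
    r_matrix: np.ndarray, sparsities: np.ndarray, rule: str = "round"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """For each ranked edge, the first sparsity-level index that includes it.

    Returns (i_idx, j_idx, level_idx, K array); edges never included get
    level_idx == len(sparsities). This single ranking is what makes the
    graph series nested and is the substrate of the fast batched metrics.
    """
    n = r_matrix.shape[0]
    K = np.array([edge_count_for_sparsity(s, n, rule) for s in sparsities])
    if np.any(np.diff(K) < 0):
        raise ValidationError("sparsities must be increasing")
    ei, ej = ranked_edges(r_matrix)
    ranks = np.arange(ei.size)
    levels = np.searchsorted(K, ranks + 1)
    return ei, ej, levels, K


def adjacency_stack(
    r_matrix: np.ndarray, sparsities: np.ndarray, rule: str = "round"
) -> np.ndarray:
    """(n_levels, N, N) uint8 stack of nested thresholded graphs."""
    n = r_matrix.shape[0]
    L = len(sparsities)
    ei, ej, levels, _ = first_inclusion_levels(r_matrix, sparsities, rule)
    keep = levels < L
    stack = np.zeros((L, n, n), dtype=np.uint8)
    stack[levels[keep], ei[keep], ej[keep]] = 1
    stack[levels[keep], ej[keep], ei[keep]] = 1
    np.cumsum(stack, axis=0, out=stack)
    return stack


def build_graph_series(
    network: CovarianceNetwork,
    sparsities: Sequence[float] | None = None,
    rule: str = "round",
) -> BinaryGraphSeries:
    """Threshold a covariance network over a sparsity grid (default 46 levels)."""
    s = np.asarray(sparsities, dtype=float) if sparsities is not None else default_sparsities()
    if s.size == 0:
        raise ValidationError("empty sparsity range")
    if np.any(np.diff(s) <= 0):
        raise ValidationError("sparsities must be strictly increasing")
    if edge_count_for_sparsity(s[0], network.n_roi, rule) < 1:
        raise ValidationError(f"smallest sparsity {s[0]} keeps no edges")
    stack = adjacency_stack(network.r_matrix, s, rule)
    counts = stack.sum(axis=(1, 2)) // 2
    return BinaryGraphSeries(
        sparsities=s,
        adjacencies=stack,
        edge_counts=counts.astype(int),
        group=network.group,
        roi_labels=network.roi_labels,
    )


def edge_list_frame(series: BinaryGraphSeries, r_matrix: np.ndarray) -> pd.DataFrame:
    """Edges with the sparsity at which each first enters the series (TSV-ready)."""
    ei, ej, levels, _ = first_inclusion_levels(r_matrix, series.sparsities)
    keep = levels < len(series.sparsities)
    labels = series.roi_labels or [f"node{k}" for k in range(r_matrix.shape[0])]
    return pd.DataFrame(
        {
            "node_i": [labels[i] for i in ei[keep]],
            "node_j": [labels[j] for j in ej[keep]],
            "r": r_matrix[ei[keep], ej[keep]],
            "sparsity_of_first_inclusion": series.sparsities[levels[keep]],
        }
    )
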