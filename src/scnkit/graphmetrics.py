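"""Graph-theoretic measures on undirected, unweighted binary graphs.

Global measures per graph: mean clustering coefficient Cp (Watts-Strogatz
nodal definition averaged over nodes), characteristic path length Lp (mean
shortest-path hop count over *reachable* ordered pairs, with a logged flag
when the graph is disconnected — inevitable at the sparsest thresholds),
global efficiency Eglob and network local efficiency Eloc
(Latora-Marchiori), and the small-world index
sigma = (Cp/<Cp_null>) / (Lp/<Lp_null>) against degree-preserving
(Maslov-Sneppen double-edge-swap) random nulls.

Nodal measures: degree D, nodal efficiency Enod (mean inverse distance to
every other node) and betweenness centrality BC (Brandes accumulation,
each unordered pair counted once; unnormalized by default).

Everything is implemented directly on dense numpy adjacency matrices —
shortest paths by level-synchronous breadth-first search expressed as
matrix products — because the permutation machinery needs thousands of
evaluations per run; `_stack_*` helpers evaluate a whole nested sparsity
series (L, N, N) in one shot. An independent graph library is used only as
a cross-check in the test suite, never here.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .data_io import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GlobalMetricSet",
    "NodalMetricSet",
    "degree_sequence",
    "bfs_distances",
    "characteristic_path_length",
    "is_connected",
    "global_efficiency",
    "nodal_efficiency",
    "clustering_coefficients",
    "local_efficiency",
    "betweenness_centrality",
    "degree_preserving_rewire",
    "small_worldness",
    "global_metric_series",
    "nodal_metric_series",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
]

GLOBAL_METRICS = ("clustering", "path_length", "global_efficiency", "local_efficiency")
NODAL_METRICS = ("degree", "nodal_efficiency", "betweenness")


def _validate_adjacency(adj) -> np.ndarray:
    a = np.asarray(adj)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.array_equal(a, a.T):
        raise ValidationError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValidationError("adjacency must have zero diagonal")
    if not np.isin(a, (0, 1)).all():
        raise ValidationError("adjacency must be binary 0/1")
    return a.astype(np.uint8)


# ---------------------------------------------------------------------------
# Nodal primitives
# ---------------------------------------------------------------------------


def degree_sequence(adj) -> np.ndarray:
    """Per-node degree: number of direct connections (row sums)."""
    a = _validate_adjacency(adj)
    return a.sum(axis=1).astype(int)


def bfs_distances(adj) -> np.ndarray:
    """All-pairs shortest-path hop counts; unreachable pairs are ``inf``.

    Level-synchronous BFS from all sources at once: the frontier indicator
    matrix is expanded by one multiplication with the adjacency per hop.
    """
    a = _validate_adjacency(adj)
    return _stack_distances(a[None])[0]


def _stack_distances(stack: np.ndarray) -> np.ndarray:
    """Batched all-pairs BFS over an (L, N, N) stack of adjacencies."""
    L, n, _ = stack.shape
    af = stack.astype(np.float32)  # frontier counts are small ints: exact
    dist = np.full((L, n, n), np.inf, dtype=np.float64)
    eye = np.broadcast_to(np.eye(n, dtype=bool), (L, n, n))
    dist[eye] = 0.0
    reached = eye.copy()
    frontier = eye.copy()
    d = 0
    while frontier.any():
        d += 1
        new = (np.matmul(frontier.astype(np.float32), af) > 0) & ~reached
        if not new.any():
            break
        dist[new] = d
        reached |= new
        frontier = new
    return dist


def is_connected(adj) -> bool:
    a = _validate_adjacency(adj)
    return bool(np.isfinite(_stack_distances(a[None])[0]).all())


def characteristic_path_length(adj, distances: np.ndarray | None = None) -> float:
    """Mean hop distance over reachable ordered pairs i != j.

    Disconnected graphs are averaged over the finite entries only; a flag is
    logged so the caller knows the value is conditional on reachability.
    """
    a = _validate_adjacency(adj)
    if a.sum() == 0:
        raise ValidationError("path length undefined on an edgeless graph")
    d = distances if distances is not None else bfs_distances(a)
    off = ~np.eye(a.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    if finite.sum() < off.sum():
        logger.warning(
            "graph disconnected: path length averaged over %d of %d pairs",
            int(finite.sum()), int(off.sum()),
        )
    return float(d[finite].mean())


def global_efficiency(adj, distances: np.ndarray | None = None) -> float:
    """Mean inverse shortest-path length over ordered pairs (unreachable -> 0)."""
    a = _validate_adjacency(adj)
    n = a.shape[0]
    if n < 2:
        return 0.0
    d = distances if distances is not None else bfs_distances(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(adj, distances: np.ndarray | None = None) -> np.ndarray:
    """Enod(i): mean inverse distance from node i to every other node."""
    a = _validate_adjacency(adj)
    n = a.shape[0]
    d = distances if distances is not None else bfs_distances(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return inv.sum(axis=1) / (n - 1)


def clustering_coefficients(adj) -> tuple[np.ndarray, float]:
    """Watts-Strogatz nodal clustering and its unweighted mean Cp.

    C(i) = 2 T(i) / (D(i)(D(i)-1)) with T(i) the triangles through i;
    nodes of degree < 2 contribute C(i) = 0.
    """
    a = _validate_adjacency(adj)
    c = _stack_clustering(a[None])[0]
    return c, float(c.mean())


def _stack_clustering(stack: np.ndarray) -> np.ndarray:
    """Batched per-node clustering over an (L, N, N) stack."""
    af = stack.astype(np.float32)
    # diag(A^3)_i = 2 * triangles through i; float32 products of small
    # integer counts are exact, reductions promoted to float64
    tri2 = (np.matmul(af, af) * af).sum(axis=2, dtype=np.float64)
    deg = stack.sum(axis=2, dtype=np.float64)
    denom = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return c


def local_efficiency(adj) -> tuple[np.ndarray, float]:
    """Latora-Marchiori local efficiency.

    Eloc(i) is the global efficiency of the subgraph induced by the
    neighbours of i (0 when fewer than two neighbours); the network value
    is the unweighted mean over nodes.
    """
    a = _validate_adjacency(adj)
    n = a.shape[0]
    eloc = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        eloc[i] = global_efficiency(sub)
    return eloc, float(eloc.mean())


def betweenness_centrality(adj, normalized: bool = False) -> np.ndarray:
    """Brandes betweenness; each unordered source-target pair counted once.

    With ``normalized=True`` values are divided by (N-1)(N-2)/2, the number
    of pairs a node could possibly mediate. Group contrasts are invariant
    to this common factor.
    """
    a = _validate_adjacency(adj)
    n = a.shape[0]
    ab = a.astype(bool)
    af = a.astype(np.float64)
    bc = np.zeros(n)
    for s in range(n):
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        frontier = np.zeros(n, dtype=bool)
        frontier[s] = True
        levels = [frontier]
        d = 0
        while True:
            reach = ab[levels[-1]].any(axis=0)
            new = reach & (dist < 0)
            if not new.any():
                break
            d += 1
            dist[new] = d
            sigma[new] = (sigma * levels[-1]) @ af[:, new]
            levels.append(new)
        delta = np.zeros(n)
        for lev in range(len(levels) - 1, 0, -1):
            w = levels[lev]
            coeff = np.zeros(n)
            coeff[w] = (1.0 + delta[w]) / sigma[w]
            prev = levels[lev - 1]
            delta[prev] += sigma[prev] * (af[np.ix_(prev.nonzero()[0], w.nonzero()[0])] @ coeff[w])
        delta[s] = 0.0
        bc += delta
    bc /= 2.0  # ordered -> unordered pairs
    if normalized:
        denom = (n - 1) * (n - 2) / 2
        bc = bc / denom if denom > 0 else bc
    return bc


# ---------------------------------------------------------------------------
# Small-world null model
# ---------------------------------------------------------------------------


def degree_preserving_rewire(adj, n_attempts: int | None = None, rng=None) -> np.ndarray:
    """Maslov-Sneppen double-edge swaps; degree sequence exactly preserved.

    Each attempt picks two edges (a,b), (c,d) and proposes (a,d), (c,b);
    attempts that would create a self-loop or duplicate edge are skipped.
    Default attempt budget is 10x the edge count.
    """
    a = _validate_adjacency(adj).copy()
    rng = np.random.default_rng(rng)
    ei, ej = np.nonzero(np.triu(a, 1))
    edges = np.column_stack([ei, ej])
    m = len(edges)
    if m < 2:
        raise ValidationError("need at least 2 edges to rewire")
    n_attempts = 10 * m if n_attempts is None else int(n_attempts)
    picks = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    for (e1, e2), flip in zip(picks, flips):
        if e1 == e2:
            continue
        x1, y1 = edges[e1]
        x2, y2 = edges[e2]
        if flip:
            x2, y2 = y2, x2
        # proposed new edges: (x1, y2), (x2, y1)
        if len({x1, y1, x2, y2}) < 4:
            continue
        if a[x1, y2] or a[x2, y1]:
            continue
        a[x1, y1] = a[y1, x1] = 0
        a[x2, y2] = a[y2, x2] = 0
        a[x1, y2] = a[y2, x1] = 1
        a[x2, y1] = a[y1, x2] = 1
        edges[e1] = sorted((x1, y2))
        edges[e2] = sorted((x2, y1))
    return a


def small_worldness(
    adj,
    n_null: int = 100,
    rng=None,
    swap_factor: int = 10,
    max_retries: int = 20,
) -> float:
    """sigma = (Cp / <Cp_null>) / (Lp / <Lp_null>) over degree-matched nulls.

    Null graphs whose path length is undefined (edgeless after a degenerate
    rewire — only possible on pathological inputs) are resampled up to
    ``max_retries`` times.
    """
    a = _validate_adjacency(adj)
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    rng = np.random.default_rng(rng)
    _, cp = clustering_coefficients(a)
    lp = characteristic_path_length(a)
    m = int(a.sum()) // 2
    cps, lps = [], []
    for _ in range(n_null):
        for _retry in range(max_retries):
            null = degree_preserving_rewire(a, n_attempts=swap_factor * m, rng=rng)
            try:
                lps.append(characteristic_path_length(null))
            except ValidationError:
                continue
            _, c = clustering_coefficients(null)
            cps.append(c)
            break
        else:
            raise ValidationError("could not draw a null graph with defined path length")
    cp_null = float(np.mean(cps))
    lp_null = float(np.mean(lps))
    if cp_null == 0:
        return np.inf if cp > 0 else np.nan
    return float((cp / cp_null) / (lp / lp_null))


# ---------------------------------------------------------------------------
# Per-sparsity-series metric curves
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GlobalMetricSet:
    """Global metric curves over a sparsity series (one value per level)."""

    sparsities: np.ndarray
    clustering: np.ndarray          # Cp
    path_length: np.ndarray         # Lp
    global_efficiency: np.ndarray   # Eglob
    local_efficiency: np.ndarray    # Eloc
    small_world: np.ndarray | None = None  # sigma, optional (costly)
    group: str = ""

    def as_dict(self) -> dict[str, np.ndarray]:
        d = {
            "clustering": self.clustering,
            "path_length": self.path_length,
            "global_efficiency": self.global_efficiency,
            "local_efficiency": self.local_efficiency,
        }
        if self.small_world is not None:
            d["small_world"] = self.small_world
        return d


@dataclasses.dataclass
class NodalMetricSet:
    """Nodal metric curves: (n_levels, N) per metric."""

    sparsities: np.ndarray
    degree: np.ndarray
    nodal_efficiency: np.ndarray
    betweenness: np.ndarray
    roi_labels: list[str] | None = None
    group: str = ""

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "degree": self.degree,
            "nodal_efficiency": self.nodal_efficiency,
            "betweenness": self.betweenness,
        }


def global_metric_series(
    series,
    include_small_world: bool = False,
    n_null: int = 100,
    rng=None,
) -> GlobalMetricSet:
    """Evaluate every global metric at every sparsity level of a graph series."""
    stack = series.adjacencies
    L, n, _ = stack.shape
    dist = _stack_distances(stack)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[:, np.arange(n), np.arange(n)] = 0.0
    inv[~np.isfinite(inv)] = 0.0
    eglob = inv.sum(axis=(1, 2)) / (n * (n - 1))
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    lp = np.array(
        [dist[s][finite[s]].mean() if finite[s].any() else np.nan for s in range(L)]
    )
    cp = _stack_clustering(stack).mean(axis=1)
    eloc = np.array([local_efficiency(stack[s])[1] for s in range(L)])
    sigma = None
    if include_small_world:
        rng = np.random.default_rng(rng)
        sigma = np.array(
            [small_worldness(stack[s], n_null=n_null, rng=rng) for s in range(L)]
        )
    return GlobalMetricSet(
        sparsities=series.sparsities,
        clustering=cp,
        path_length=lp,
        global_efficiency=eglob,
        local_efficiency=eloc,
        small_world=sigma,
        group=getattr(series, "group", ""),
    )


def nodal_metric_series(series, bc_normalized: bool = False) -> NodalMetricSet:
    """Evaluate degree, nodal efficiency and betweenness per sparsity level."""
    stack = series.adjacencies
    L, n, _ = stack.shape
    dist = _stack_distances(stack)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[:, np.arange(n), np.arange(n)] = 0.0
    inv[~np.isfinite(inv)] = 0.0
    enod = inv.sum(axis=2) / (n - 1)
    deg = stack.sum(axis=2).astype(float)
    bc = np.array([betweenness_centrality(stack[s], normalized=bc_normalized) for s in range(L)])
    return NodalMetricSet(
        sparsities=series.sparsities,
        degree=deg,
        nodal_efficiency=enod,
        betweenness=bc,
        roi_labels=getattr(series, "roi_labels", None),
        group=getattr(series, "group", ""),
    )
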