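"""Small-world graph metrics with matched randomized references.

Clustering and characteristic path length are computed directly from the
adjacency matrix (triangle counts via A^3, shortest paths via breadth-first
search).  Normalized metrics divide by the mean over degree-preserving
randomized references (batched Maslov-Sneppen double-edge swaps):

    gamma  = C / C_rand      (normalized clustering)
    lambda = L / L_rand      (normalized path length)
    sigma  = gamma / lambda  (small-world coefficient)

A network is small-world when gamma > 1, lambda ~ 1 and sigma > 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .network import BinaryNetwork

__all__ = [
    "NetworkProperties",
    "UndefinedPathLengthError",
    "DegenerateReferenceError",
    "clustering_coefficient",
    "characteristic_path_length",
    "randomize_network",
    "small_world_properties",
]


class UndefinedPathLengthError(ValueError):
    """Raised for edgeless networks, where no path exists."""


class DegenerateReferenceError(ValueError):
    """Raised when the randomized references have zero mean clustering."""


@dataclass
class NetworkProperties:
    """Per-subject small-world summary.

    ``gamma = clustering_C / C_rand``, ``lambda_ = path_length_L / L_rand``,
    ``sigma = gamma / lambda_`` (exactly, by construction).
    """

    clustering_C: float
    path_length_L: float
    C_rand: float
    L_rand: float
    gamma: float
    lambda_: float
    sigma: float
    n_random: int
    largest_component_frac: float = 1.0

    def as_dict(self) -> dict[str, float]:
        return {
            "C": self.clustering_C,
            "L": self.path_length_L,
            "C_rand": self.C_rand,
            "L_rand": self.L_rand,
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "sigma": self.sigma,
        }


def clustering_coefficient(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean over all nodes.

    For node i with degree k_i >= 2, C_i = 2 t_i / (k_i (k_i - 1)) where
    t_i counts edges among its neighbors; nodes with degree < 2 contribute
    C_i = 0 (they are kept in the mean).
    """
    a = net.adjacency.astype(np.float64)
    k = a.sum(axis=1)
    triangles = ((a @ a) * a).sum(axis=1) / 2.0
    denom = k * (k - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_node = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return per_node, float(per_node.mean())


def _largest_component(net: BinaryNetwork) -> np.ndarray:
    n_comp, labels = connected_components(csr_matrix(net.adjacency), directed=False)
    if n_comp == 1:
        return np.arange(net.n_nodes)
    sizes = np.bincount(labels)
    return np.flatnonzero(labels == sizes.argmax())


def characteristic_path_length(
    net: BinaryNetwork, method: str = "largest_component"
) -> tuple[float, int]:
    """Mean shortest-path distance over node pairs.

    ``method="largest_component"`` (default): the mean over all ordered
    pairs within the largest connected component.  ``method="harmonic"``:
    the reciprocal of the mean inverse distance over all ordered pairs of
    the whole graph (disconnected pairs contribute 0), an efficiency-style
    alternative for fragmented graphs.  Returns ``(L, component_size)``.
    """
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if net.n_edges == 0:
        raise UndefinedPathLengthError("edgeless network has no defined path length")
    comp = _largest_component(net)
    if method == "largest_component":
        sub = net.adjacency[np.ix_(comp, comp)]
        d = shortest_path(csr_matrix(sub), method="auto", unweighted=True, directed=False)
        m = len(comp)
        total = d[np.triu_indices(m, k=1)].sum()
        return float(2.0 * total / (m * (m - 1))), len(comp)
    if method == "harmonic":
        d = shortest_path(
            csr_matrix(net.adjacency), method="auto", unweighted=True, directed=False
        )
        n = net.n_nodes
        iu = np.triu_indices(n, k=1)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(d[iu]), 1.0 / d[iu], 0.0)
        mean_inv = inv.mean()
        if mean_inv == 0:
            raise UndefinedPathLengthError("no finite distances")
        return float(1.0 / mean_inv), len(comp)
    raise ValueError(f"unknown method: {method!r}")


try:  # sequential jitted kernel; the numpy batch path remains as fallback
    from numba import njit

    @njit(cache=False)
    def _swap_kernel(adj, edges, n_attempts, seed):  # pragma: no cover - jitted
        np.random.seed(seed)
        m = edges.shape[0]
        applied = 0
        for _ in range(n_attempts):
            e1 = np.random.randint(0, m)
            e2 = np.random.randint(0, m)
            a = edges[e1, 0]
            b = edges[e1, 1]
            c = edges[e2, 0]
            d = edges[e2, 1]
            if np.random.random() < 0.5:
                c, d = d, c
            if a == c or a == d or b == c or b == d:
                continue
            if adj[a, d] or adj[c, b]:
                continue
            adj[a, b] = adj[b, a] = False
            adj[c, d] = adj[d, c] = False
            adj[a, d] = adj[d, a] = True
            adj[c, b] = adj[b, c] = True
            edges[e1, 1] = d
            edges[e2, 0] = c
            edges[e2, 1] = b
            applied += 1
        return applied

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _batched_double_edge_swap(adj: np.ndarray, n_attempts: int, rng: np.random.Generator) -> int:
    """Run Maslov-Sneppen swap attempts in conflict-free numpy batches.

    Two edges (a, b) and (c, d) are drawn uniformly with random orientation
    and rewired to (a, d), (c, b) when all four endpoints are distinct and
    neither replacement edge exists.  Proposals within a batch that share a
    node are dropped (counted as rejected attempts), so applied swaps
    commute and the result is deterministic given the generator state.
    Modifies ``adj`` in place; returns the number of successful swaps.
    """
    iu = np.nonzero(np.triu(adj, 1))
    edges = np.stack(iu, axis=1)
    m = len(edges)
    n = adj.shape[0]
    done = applied = 0
    # keep batches small relative to n so within-batch node collisions stay rare
    batch = int(min(2048, max(1, n // 16)))
    while done < n_attempts:
        b = min(batch, n_attempts - done)
        e1 = rng.integers(0, m, size=b)
        e2 = rng.integers(0, m, size=b)
        a, bb = edges[e1, 0].copy(), edges[e1, 1].copy()
        c, d = edges[e2, 0].copy(), edges[e2, 1].copy()
        flip = rng.random(b) < 0.5
        c[flip], d[flip] = d[flip], c[flip].copy()
        ok = (a != c) & (a != d) & (bb != c) & (bb != d)
        ok &= ~adj[a, d] & ~adj[c, bb]
        idx = np.flatnonzero(ok)
        nodes = np.concatenate([a[idx], bb[idx], c[idx], d[idx]])
        counts = np.bincount(nodes, minlength=n)
        free = (
            (counts[a[idx]] == 1)
            & (counts[bb[idx]] == 1)
            & (counts[c[idx]] == 1)
            & (counts[d[idx]] == 1)
        )
        # conflict-dropped proposals are a batching artifact, not a
        # Maslov-Sneppen rejection; they do not consume attempt budget
        done += b - int((~free).sum())
        idx = idx[free]
        if idx.size == 0:
            continue
        ai, bi, ci, di = a[idx], bb[idx], c[idx], d[idx]
        adj[ai, bi] = adj[bi, ai] = False
        adj[ci, di] = adj[di, ci] = False
        adj[ai, di] = adj[di, ai] = True
        adj[ci, bi] = adj[bi, ci] = True
        edges[e1[idx]] = np.stack([ai, di], axis=1)
        edges[e2[idx]] = np.stack([ci, bi], axis=1)
        applied += idx.size
    return applied


def randomize_network(
    net: BinaryNetwork, n_swaps_per_edge: int = 10, seed: int = 0
) -> BinaryNetwork:
    """Degree-preserving randomization by Maslov-Sneppen double-edge swaps.

    Attempts ``n_swaps_per_edge * n_edges`` double-edge swaps; each swap
    replaces edges (a, b), (c, d) with (a, d), (c, b) when that introduces
    no self-loop or multi-edge, which preserves every node's degree
    exactly.  Deterministic given ``seed``.  Graphs too small or too dense
    to swap are returned unchanged with a warning.
    """
    m = net.n_edges
    n = net.n_nodes
    if m < 2 or n < 4:
        warnings.warn("network too small to randomize; returning input", stacklevel=2)
        return BinaryNetwork(net.adjacency.copy(), r_threshold=net.r_threshold)
    if m / (n * (n - 1) / 2) > 0.9:
        # a near-complete graph admits almost no valid swaps and is its own
        # degree-preserving randomization for practical purposes
        warnings.warn("network too dense to randomize; returning input", stacklevel=2)
        return BinaryNetwork(net.adjacency.copy(), r_threshold=net.r_threshold)
    adj = net.adjacency.copy()
    if _HAVE_NUMBA:
        iu = np.nonzero(np.triu(adj, 1))
        edges = np.ascontiguousarray(np.stack(iu, axis=1))
        applied = _swap_kernel(adj, edges, n_swaps_per_edge * m, int(seed) % (2**31))
    else:
        rng = np.random.default_rng(int(seed))
        applied = _batched_double_edge_swap(adj, n_swaps_per_edge * m, rng)
    if applied < m:
        warnings.warn(
            f"only {applied} swaps applied for {m} edges; graph may be under-mixed",
            stacklevel=2,
        )
    return BinaryNetwork(adj)


def small_world_properties(
    net: BinaryNetwork,
    n_random: int = 5,
    seed: int = 0,
    n_swaps_per_edge: int = 10,
    path_method: str = "largest_component",
) -> NetworkProperties:
    """Clustering, path length, and their normalized (small-world) versions.

    The randomized references use child seeds fanned out deterministically
    from ``seed``.  Warns when the largest connected component covers less
    than 90% of the nodes, since L is then computed on a subgraph.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    _, c = clustering_coefficient(net)
    length, comp_size = characteristic_path_length(net, method=path_method)
    frac = comp_size / net.n_nodes
    if frac < 0.9:
        warnings.warn(
            f"largest component holds only {frac:.0%} of nodes; "
            "path length refers to that component",
            stacklevel=2,
        )
    child_seeds = np.random.SeedSequence(int(seed)).generate_state(n_random) % (2**31)
    c_rands, l_rands = [], []
    for s in child_seeds:
        r = randomize_network(net, n_swaps_per_edge=n_swaps_per_edge, seed=int(s))
        _, cr = clustering_coefficient(r)
        lr, _ = characteristic_path_length(r, method=path_method)
        c_rands.append(cr)
        l_rands.append(lr)
    c_rand = float(np.mean(c_rands))
    l_rand = float(np.mean(l_rands))
    if c_rand == 0:
        raise DegenerateReferenceError("randomized references have zero clustering")
    gamma = c / c_rand
    lam = length / l_rand
    return NetworkProperties(
        clustering_C=c,
        path_length_L=length,
        C_rand=c_rand,
        L_rand=l_rand,
        gamma=gamma,
        lambda_=lam,
        sigma=gamma / lam,
        n_random=n_random,
        largest_component_frac=frac,
    )
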