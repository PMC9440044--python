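"""Random threshold networks and their percolation-theoretic properties.

A :class:`ThresholdNetwork` is an Erdős–Rényi–Gilbert graph G(n, p) with
p = z/(n-1) for a target mean degree z, a uniform-random activation
threshold per node, a designated ordered set of k seed (input) nodes, and a
boolean antagonist flag per node marking inhibitory (negated-rule) units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import brentq
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ThresholdNetwork",
    "generate_network",
    "giant_component",
    "gcc_fraction_theoretical",
    "clustering_estimate",
    "average_clustering",
    "read_edgelist",
    "write_edgelist",
]

# Smallest admissible threshold: thresholds live in the open interval (0, 1)
# so that a node with zero labelled neighbours can never satisfy the
# non-antagonist rule L(u)/deg(u) >= phi.
_PHI_MIN = np.nextafter(0.0, 1.0)


@dataclass
class ThresholdNetwork:
    """Undirected random graph with per-node thresholds and antagonist flags.

    Parameters
    ----------
    n
        Number of nodes, indexed ``0 .. n-1``.
    edges
        ``(m, 2)`` integer array of undirected edges with ``u < v`` per row,
        no self-loops, no duplicates.
    thresholds
        Per-node activation threshold ``phi`` in the open interval (0, 1).
    antagonist_flags
        Per-node boolean; ``True`` marks the negated (inhibitory) rule.
    seed_nodes
        Ordered array of ``k`` distinct input-node indices.
    mean_degree_target
        The mean degree ``z`` the graph was generated for (informational).
    edge_probability
        The edge probability ``p = z/(n-1)`` actually used (clamped to 1).
    rng_seed
        Master seed the network was generated from, or ``None`` for
        hand-built networks.
    """

    n: int
    edges: np.ndarray
    thresholds: np.ndarray
    antagonist_flags: np.ndarray
    seed_nodes: np.ndarray
    mean_degree_target: float = np.nan
    edge_probability: float = np.nan
    rng_seed: int | None = None
    _csr: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        self.antagonist_flags = np.asarray(self.antagonist_flags, dtype=bool)
        self.seed_nodes = np.asarray(self.seed_nodes, dtype=np.int64)
        self._validate()

    def _validate(self) -> None:
        n = self.n
        if self.edges.size:
            u, v = self.edges[:, 0], self.edges[:, 1]
            if np.any(u == v):
                raise ValueError("self-loops are not allowed")
            if np.any((self.edges < 0) | (self.edges >= n)):
                raise ValueError("edge endpoint out of range")
            lo, hi = np.minimum(u, v), np.maximum(u, v)
            keys = lo * n + hi
            if np.unique(keys).size != keys.size:
                raise ValueError("duplicate edges are not allowed")
            self.edges = np.column_stack([lo, hi])
        if self.thresholds.shape != (n,):
            raise ValueError("thresholds must have one entry per node")
        if np.any((self.thresholds < 0.0) | (self.thresholds > 1.0)):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.antagonist_flags.shape != (n,):
            raise ValueError("antagonist_flags must have one entry per node")
        seeds = self.seed_nodes
        if np.unique(seeds).size != seeds.size:
            raise ValueError("seed nodes must be distinct")
        if seeds.size and (seeds.min() < 0 or seeds.max() >= n):
            raise ValueError("seed node index out of range")

    # -- derived structure -------------------------------------------------

    @property
    def k(self) -> int:
        """Number of seed (input) nodes."""
        return int(self.seed_nodes.size)

    @property
    def m(self) -> int:
        """Number of edges."""
        return int(self.edges.shape[0])

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric boolean adjacency matrix in CSR form (cached)."""
        if self._csr is None:
            if self.m:
                u, v = self.edges[:, 0], self.edges[:, 1]
                row = np.concatenate([u, v])
                col = np.concatenate([v, u])
                data = np.ones(row.size, dtype=np.int8)
                self._csr = sp.csr_matrix(
                    (data, (row, col)), shape=(self.n, self.n)
                )
            else:
                self._csr = sp.csr_matrix((self.n, self.n), dtype=np.int8)
        return self._csr

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        if self.m:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def mean_degree(self) -> float:
        return 2.0 * self.m / self.n if self.n else 0.0

    def is_seed_mask(self) -> np.ndarray:
        mask = np.zeros(self.n, dtype=bool)
        mask[self.seed_nodes] = True
        return mask


# -- G(n, p) sampling ------------------------------------------------------


def _sample_gnp_edges(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Sample the edge set of G(n, p) in O(m) vectorized numpy.

    Walks the linearized upper triangle (T = n(n-1)/2 cells) with geometric
    inter-arrival skips — the standard O(n + m) G(n, p) algorithm — batched
    through numpy instead of a per-edge Python loop.
    """
    total = n * (n - 1) // 2
    if total == 0 or p <= 0.0:
        return np.empty((0, 2), dtype=np.int64)
    if p >= 1.0:
        positions = np.arange(total, dtype=np.int64)
    else:
        chunks: list[np.ndarray] = []
        pos = -1  # last occupied cell
        batch = max(1024, int(total * p * 1.1) + 16)
        while pos < total - 1:
            skips = rng.geometric(p, size=batch).astype(np.int64)
            cells = pos + np.cumsum(skips)
            chunks.append(cells)
            pos = int(cells[-1])
        positions = np.concatenate(chunks)
        positions = positions[positions < total]
    # linear cell index -> (i, j), i < j, row-major upper triangle
    i_arr = np.arange(n, dtype=np.int64)
    row_start = i_arr * (n - 1) - i_arr * (i_arr - 1) // 2
    rows = np.searchsorted(row_start, positions, side="right") - 1
    cols = positions - row_start[rows] + rows + 1
    return np.column_stack([rows, cols])


def generate_network(
    n: int,
    z: float,
    k: int,
    theta: float = 0.0,
    rng_seed: int = 0,
) -> ThresholdNetwork:
    """Generate a random threshold network.

    Each of the n(n-1)/2 node pairs is an edge independently with probability
    ``p = z/(n-1)`` (clamped to 1 when z >= n-1, so z = n yields the complete
    graph). Thresholds are i.i.d. uniform on (0, 1); ``k`` distinct seed
    nodes are chosen uniformly; ``round(theta * (n - k))`` uniformly chosen
    non-seed nodes are flagged antagonistic (seeds, being clamped inputs,
    are never antagonistic).

    The single integer ``rng_seed`` is expanded into independent streams for
    topology, thresholds, seed choice and antagonist choice, so a network is
    fully reproducible from ``(n, z, k, theta, rng_seed)``.
    """
    if k < 1 or k > n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    if z < 0 or z > n:
        raise ValueError(f"need 0 <= z <= n, got z={z}")
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must lie in [0, 1], got {theta}")

    ss = np.random.SeedSequence(rng_seed)
    s_topo, s_phi, s_seed, s_antag = ss.spawn(4)
    p = 1.0 if n <= 1 else min(1.0, z / (n - 1))

    edges = _sample_gnp_edges(n, p, np.random.default_rng(s_topo))
    thresholds = np.random.default_rng(s_phi).uniform(_PHI_MIN, 1.0, size=n)
    seed_nodes = np.random.default_rng(s_seed).choice(n, size=k, replace=False)

    flags = np.zeros(n, dtype=bool)
    n_antag = int(round(theta * (n - k)))
    if n_antag:
        non_seed = np.setdiff1d(np.arange(n), seed_nodes)
        chosen = np.random.default_rng(s_antag).choice(
            non_seed, size=n_antag, replace=False
        )
        flags[chosen] = True

    return ThresholdNetwork(
        n=n,
        edges=edges,
        thresholds=thresholds,
        antagonist_flags=flags,
        seed_nodes=seed_nodes,
        mean_degree_target=float(z),
        edge_probability=p,
        rng_seed=rng_seed,
    )


# -- percolation -----------------------------------------------------------


def giant_component(net: ThresholdNetwork) -> set[int]:
    """Largest connected component by node count.

    Ties are broken deterministically in favour of the component containing
    the smallest node index.
    """
    n_comp, labels = connected_components(net.adjacency(), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    best = sizes.max()
    # among maximal components, the one whose smallest member is smallest;
    # labels are assigned in order of first occurrence, so the first maximal
    # label wins.
    winner = int(np.flatnonzero(sizes == best)[0])
    return set(np.flatnonzero(labels == winner).tolist())


def gcc_fraction_theoretical(z: float) -> float:
    """Giant-component node fraction v from the self-consistency v = 1 - e^{-zv}.

    Returns the largest root in [0, 1]; below (and at) the critical mean
    degree z_c = 1 the only root is v = 0.
    """
    if z < 0:
        raise ValueError(f"mean degree must be nonnegative, got {z}")
    if z <= 1.0:
        return 0.0

    def f(v: float) -> float:
        return v - 1.0 + np.exp(-z * v)

    # f(eps) < 0 above criticality, f(1) = e^{-z} > 0: root bracketed.
    v = brentq(f, 1e-12, 1.0, xtol=1e-14, rtol=8.9e-16)
    assert abs(f(v)) < 1e-10
    return float(v)


def clustering_estimate(n: int, z: float) -> float:
    """Tree-likeness estimate: expected clustering coefficient ≈ p = z/(n-1)."""
    if n < 2:
        raise ValueError("need at least two nodes")
    return min(1.0, z / (n - 1))


def average_clustering(net: ThresholdNetwork) -> float:
    """Empirical average clustering coefficient (sparse triangle counting).

    Nodes of degree < 2 contribute 0, matching the usual convention.
    """
    if net.n == 0:
        return 0.0
    a = net.adjacency().astype(np.int64)
    # triangles through u = (A^2 ∘ A) row sums / 2
    tri2 = (a @ a).multiply(a).sum(axis=1)
    tri2 = np.asarray(tri2).ravel()
    deg = net.degrees()
    pairs = deg * (deg - 1)  # 2 * (deg choose 2)
    coef = np.zeros(net.n, dtype=np.float64)
    mask = pairs > 0
    coef[mask] = tri2[mask] / pairs[mask]
    return float(coef.mean())


# -- plain-text serialization ---------------------------------------------


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.json")


def write_edgelist(net: ThresholdNetwork, path: str | Path) -> None:
    """Write a network as a whitespace edge list plus a JSON sidecar.

    The edge list holds one ``u v`` pair per line (0-based). The sidecar
    (``<path>.meta.json``) holds n, thresholds, antagonist flags, seed nodes
    and the generating seed, so the round trip is lossless.
    """
    path = Path(path)
    with path.open("w") as fh:
        for u, v in net.edges:
            fh.write(f"{u} {v}\n")
    meta = {
        "n": net.n,
        "thresholds": net.thresholds.tolist(),
        "antagonist_flags": net.antagonist_flags.astype(int).tolist(),
        "seed_nodes": net.seed_nodes.tolist(),
        "mean_degree_target": None
        if np.isnan(net.mean_degree_target)
        else net.mean_degree_target,
        "edge_probability": None
        if np.isnan(net.edge_probability)
        else net.edge_probability,
        "rng_seed": net.rng_seed,
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def read_edgelist(path: str | Path) -> ThresholdNetwork:
    """Read a network written by :func:`write_edgelist`.

    Malformed edge lines are reported with their line number.
    """
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    edges: list[tuple[int, int]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two node indices, got {line!r}"
                )
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer node index in {line!r}"
                ) from exc
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop {u} {v}")
            edges.append((u, v))
    edge_arr = (
        np.array(edges, dtype=np.int64)
        if edges
        else np.empty((0, 2), dtype=np.int64)
    )
    mdt = meta.get("mean_degree_target")
    ep = meta.get("edge_probability")
    return ThresholdNetwork(
        n=int(meta["n"]),
        edges=edge_arr,
        thresholds=np.asarray(meta["thresholds"], dtype=np.float64),
        antagonist_flags=np.asarray(meta["antagonist_flags"], dtype=bool),
        seed_nodes=np.asarray(meta["seed_nodes"], dtype=np.int64),
        mean_degree_target=np.nan if mdt is None else float(mdt),
        edge_probability=np.nan if ep is None else float(ep),
        rng_seed=meta.get("rng_seed"),
    )


def build_network(
    n: int,
    edges: Sequence[tuple[int, int]],
    thresholds: Sequence[float],
    seed_nodes: Sequence[int],
    antagonists: Sequence[int] = (),
) -> ThresholdNetwork:
    """Convenience constructor for hand-specified (e.g. motif) networks."""
    flags = np.zeros(n, dtype=bool)
    flags[list(antagonists)] = True
    edge_arr = (
        np.array(list(edges), dtype=np.int64).reshape(-1, 2)
        if len(edges)
        else np.empty((0, 2), dtype=np.int64)
    )
    return ThresholdNetwork(
        n=n,
        edges=edge_arr,
        thresholds=np.asarray(thresholds, dtype=np.float64),
        antagonist_flags=flags,
        seed_nodes=np.asarray(seed_nodes, dtype=np.int64),
    )
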