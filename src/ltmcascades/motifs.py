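"""Minimal logic motifs: sub-networks that compute each k = 2 function.

A motif is a concrete network fragment — seed nodes ``a`` and ``b`` plus
internal nodes with explicit thresholds and antagonist flags — whose output
node computes a target Boolean function of the seeds under the cascade
dynamics. Direct edges stand in for paths: the path/edge distinction only
matters for occurrence probabilities, which are carried by powers of the
giant-component fraction v, not by fragment geometry.

Threshold representatives are fixed mid-interval (0.75 for "> 1/2", 0.25
for "<= 1/2", 0.5 for degree-3 gates needing phi in (1/3, 2/3]) so motif
behaviour is deterministic. Because edges are undirected, an internal relay
also senses its downstream gate; thresholds are chosen so that this
back-coupling can never change a node's firing decision before the
downstream gate has fired, which makes every cataloged fragment's output
independent of the update schedule. ``verify_motif`` checks this
exhaustively over all asynchronous schedules.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .boolfunc import BooleanFunction, extract_function_ids
from .cascade import fires, LabelState
from .network import ThresholdNetwork, build_network, gcc_fraction_theoretical, write_edgelist

__all__ = [
    "Motif",
    "build_motif",
    "verify_motif",
    "motif_probability",
    "motif_catalog_ids",
    "export_catalog",
    "embed_motif",
]

_HI = 0.75  # representative of phi in (1/2, 1)
_LO = 0.25  # representative of phi in (0, 1/2]
_MID = 0.5  # representative of phi in (1/3, 2/3] (degree-3 gates)
_THIRD = 0.25  # representative of phi in (0, 1/3] (degree-3 OR gates)

# Catalog of minimal fragments for every k = 2 function id.
# Node convention: 0 = a, 1 = b (seeds); internal nodes follow; the output
# node u is always the last index. Seeds get a placeholder threshold 0.5
# (they are clamped inputs; their own rule is never evaluated).
# entry: (n, edges, {node: phi}, antagonists, required_paths, required_gcc_nodes)
_CATALOG: dict[int, tuple] = {
    # -- pure-LTM monotone increasing family --
    0: (3, [], {2: _HI}, [], 0, 0),                                   # False
    1: (3, [(0, 2), (1, 2)], {2: _HI}, [], 2, 3),                     # a AND b
    3: (3, [(0, 2)], {2: _HI}, [], 1, 2),                             # a
    5: (3, [(1, 2)], {2: _HI}, [], 1, 2),                             # b
    7: (3, [(0, 2), (1, 2)], {2: _LO}, [], 2, 3),                     # a OR b
    # -- single-antagonist negations --
    8: (3, [(0, 2), (1, 2)], {2: _LO}, [2], 2, 3),                    # NOR
    10: (3, [(1, 2)], {2: _HI}, [2], 1, 2),                           # NOT b
    12: (3, [(0, 2)], {2: _HI}, [2], 1, 2),                           # NOT a
    14: (3, [(0, 2), (1, 2)], {2: _HI}, [2], 2, 3),                   # NAND
    15: (3, [], {2: _HI}, [2], 0, 0),                                 # True
    # -- two-stage non-monotone constructions and their negations --
    # Relay thresholds account for the undirected back-edge from the
    # downstream gate: a degree-2 antagonist relay with phi <= 1/2 fires
    # iff both neighbours are unlabelled when examined, and its downstream
    # gate cannot fire first, so the relay reads NOT(seed).
    # f2 = a AND (NOT b): antagonist relay w = NOT b feeding an AND gate
    2: (4, [(1, 2), (0, 3), (2, 3)], {2: _LO, 3: _HI}, [2], 3, 4),
    # f4 = (NOT a) AND b
    4: (4, [(0, 2), (1, 3), (2, 3)], {2: _LO, 3: _HI}, [2], 3, 4),
    # f6 = XOR = AND(NAND(a,b), OR(a,b)): 5 nodes, 6 paths; the degree-3
    # NAND gate needs phi in (1/3, 2/3], the degree-3 OR gate (0, 1/3]
    6: (
        5,
        [(0, 2), (1, 2), (0, 3), (1, 3), (2, 4), (3, 4)],
        {2: _MID, 3: _THIRD, 4: _HI},
        [2],
        6,
        5,
    ),
    # f13 = NOT f2 = (NOT a) OR b
    13: (4, [(0, 2), (1, 3), (2, 3)], {2: _LO, 3: _LO}, [2], 3, 4),
    # f11 = NOT f4 = a OR (NOT b)
    11: (4, [(1, 2), (0, 3), (2, 3)], {2: _LO, 3: _LO}, [2], 3, 4),
    # f9 = XNOR = OR(AND(a,b), NOR(a,b)): 5 nodes, 6 paths
    9: (
        5,
        [(0, 2), (1, 2), (0, 3), (1, 3), (2, 4), (3, 4)],
        {2: _MID, 3: _THIRD, 4: _LO},
        [3],
        6,
        5,
    ),
}


@dataclass
class Motif:
    """A fragment together with the function its output node computes."""

    target_function: BooleanFunction
    fragment: ThresholdNetwork
    output_node: int
    required_paths: int
    required_gcc_nodes: int


def motif_catalog_ids() -> list[int]:
    """Function ids with a cataloged minimal fragment (all 16 at k = 2)."""
    return sorted(_CATALOG)


def build_motif(function_id: int, k: int = 2) -> Motif:
    """Construct the cataloged minimal fragment for a k = 2 function id."""
    if k != 2:
        raise ValueError("motif constructions are cataloged for k = 2 only")
    if function_id not in _CATALOG:
        raise ValueError(f"no cataloged motif for function id {function_id}")
    n, edges, phis, antag, n_paths, n_gcc = _CATALOG[function_id]
    thresholds = np.full(n, 0.5)
    for node, phi in phis.items():
        thresholds[node] = phi
    fragment = build_network(
        n=n,
        edges=edges,
        thresholds=thresholds,
        seed_nodes=[0, 1],
        antagonists=antag,
    )
    return Motif(
        target_function=BooleanFunction.from_id(function_id, k),
        fragment=fragment,
        output_node=n - 1,
        required_paths=n_paths,
        required_gcc_nodes=n_gcc,
    )


# -- exhaustive verification ----------------------------------------------


def _reachable_fixed_points(
    net: ThresholdNetwork, pattern: np.ndarray
) -> set[tuple[int, ...]]:
    """All label fixed points reachable under any asynchronous schedule.

    Explores the single-node-commit transition system by DFS; every
    permutation-sweep schedule is one of its paths, so agreement across all
    reachable fixed points implies agreement across all update orders.
    """
    is_seed = net.is_seed_mask()
    start = np.zeros(net.n, dtype=bool)
    start[net.seed_nodes] = pattern
    seen: set[tuple[int, ...]] = set()
    fixed: set[tuple[int, ...]] = set()
    stack = [tuple(int(b) for b in start)]
    while stack:
        labels = stack.pop()
        if labels in seen:
            continue
        seen.add(labels)
        state = LabelState(labels=np.array(labels, dtype=bool), seed_pattern=pattern)
        fireable = [
            u
            for u in range(net.n)
            if not is_seed[u] and not labels[u] and fires(u, state, net)
        ]
        if not fireable:
            fixed.add(labels)
            continue
        for u in fireable:
            nxt = list(labels)
            nxt[u] = 1
            stack.append(tuple(nxt))
    return fixed


def verify_motif(m: Motif, exhaustive_max_nodes: int = 8) -> bool:
    """Does the fragment's output node compute the target on all patterns?

    For fragments up to ``exhaustive_max_nodes`` nodes the check is
    exhaustive over asynchronous update orders; larger fragments fall back
    to sampling 20 random schedules per pattern.
    """
    net = m.fragment
    k = net.k
    target = m.target_function.table
    from .boolfunc import input_patterns

    for x, pattern in enumerate(input_patterns(k)):
        if net.n <= exhaustive_max_nodes:
            for labels in _reachable_fixed_points(net, pattern):
                if labels[m.output_node] != target[x]:
                    return False
        else:
            from .cascade import run_cascade

            for trial in range(20):
                state = run_cascade(net, pattern, rng=trial)
                if int(state.labels[m.output_node]) != target[x]:
                    return False
    return True


# -- path probabilities ----------------------------------------------------


def motif_probability(function_id: int, z: float, n: int | None = None) -> float:
    """Unnormalized occurrence probability of a function's minimal motif.

    In the large-n limit the probability of a path between two random nodes
    is p_path ≈ v², and the probability of paths among m specific nodes
    approaches the probability that all m lie in the giant component, v**m.
    The constants f0/f15 require the output node to have *no* path to either
    seed: (1 - p_path)**2. ``n`` is accepted for signature completeness; the
    large-n limit is used.
    """
    if function_id not in _CATALOG:
        raise ValueError(f"no cataloged motif for function id {function_id}")
    v = gcc_fraction_theoretical(z)
    m_gcc = _CATALOG[function_id][5]
    if function_id in (0, 15):
        p_path = v * v
        return float((1.0 - p_path) ** 2)
    return float(v**m_gcc)


# -- export and embedding --------------------------------------------------


def export_catalog(out_dir: str | Path) -> list[Path]:
    """Write every cataloged fragment as edge-list + sidecar files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for fid in motif_catalog_ids():
        m = build_motif(fid)
        path = out_dir / f"motif_f{fid}.edgelist"
        write_edgelist(m.fragment, path)
        written.append(path)
    return written


def embed_motif(
    m: Motif, n: int, z: float, rng_seed: int = 0
) -> tuple[ThresholdNetwork, int]:
    """Embed a fragment into a larger network as an isolated component.

    The fragment keeps nodes ``0 .. f-1`` (its seeds become the network's
    seeds); the remaining ``n - f`` nodes get Erdős–Rényi edges among
    themselves with p = z/(n-1). Returns the network and the output node.
    """
    f = m.fragment.n
    if n < f:
        raise ValueError("embedding target smaller than fragment")
    rng = np.random.default_rng(rng_seed)
    p = min(1.0, z / (n - 1)) if n > 1 else 0.0
    extra = []
    for i in range(f, n):
        for j in range(i + 1, n):
            if rng.random() < p:
                extra.append((i, j))
    edges = list(map(tuple, m.fragment.edges.tolist())) + extra
    thresholds = np.concatenate(
        [m.fragment.thresholds, rng.uniform(np.nextafter(0, 1), 1.0, size=n - f)]
    )
    antagonists = list(np.flatnonzero(m.fragment.antagonist_flags))
    net = build_network(
        n=n,
        edges=edges,
        thresholds=thresholds,
        seed_nodes=list(m.fragment.seed_nodes),
        antagonists=antagonists,
    )
    return net, m.output_node


def extracted_id_at_output(net: ThresholdNetwork, output_node: int, rng=0) -> int:
    """Function id the cascade machinery assigns to one node (convenience)."""
    return int(extract_function_ids(net, rng=rng)[output_node])
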