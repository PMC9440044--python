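"""LTM/ALTM cascade execution.

A cascade starts from a binary perturbation pattern clamped onto the seed
nodes. Unlabelled non-seed nodes are examined in repeated uniformly random
permutation sweeps; a node that fires is labelled immediately
(asynchronously) and labels are permanent. The run terminates when a full
sweep labels no node.

Firing rule for node u with labelled-neighbour fraction L(u)/deg(u):

* non-antagonist: fires iff  L(u)/deg(u) >= phi_u
* antagonist:     fires iff  L(u)/deg(u) <  phi_u

Isolated nodes (deg = 0) have fraction 0, so an isolated non-antagonist
never fires and an isolated antagonist always does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .network import ThresholdNetwork

__all__ = ["LabelState", "fires", "run_cascade"]


@dataclass
class LabelState:
    """Final (or in-progress) activation state of one cascade run."""

    labels: np.ndarray  # per-node bool, 1 = labelled
    seed_pattern: np.ndarray  # length-k bool, aligned to net.seed_nodes
    sweeps: int = 0  # permutation sweeps executed (incl. the final empty one)
    trace: list[tuple[int, int]] | None = field(default=None, repr=False)
    # trace entries are (sweep index, node) labelling events, in commit order


def fires(u: int, state: LabelState, net: ThresholdNetwork) -> bool:
    """Would unlabelled non-seed node ``u`` fire in the given state?"""
    adj = net.adjacency()
    neigh = adj.indices[adj.indptr[u] : adj.indptr[u + 1]]
    deg = neigh.size
    frac = 0.0 if deg == 0 else float(state.labels[neigh].sum()) / deg
    if net.antagonist_flags[u]:
        return frac < net.thresholds[u]
    return frac >= net.thresholds[u]


@njit(cache=False)
def _cascade_kernel(indptr, indices, thresholds, antagonist, is_seed, labels, order_seed):
    n = labels.size
    lab_count = np.zeros(n, dtype=np.int64)
    for u in range(n):
        if labels[u]:
            for e in range(indptr[u], indptr[u + 1]):
                lab_count[indices[e]] += 1
    cand = np.empty(n, dtype=np.int64)
    c = 0
    for u in range(n):
        if not is_seed[u] and not labels[u]:
            cand[c] = u
            c += 1
    np.random.seed(order_seed)
    sweeps = 0
    changed = True
    while changed and c > 0:
        changed = False
        sweeps += 1
        perm = np.random.permutation(c)
        order = np.empty(c, dtype=np.int64)
        for t in range(c):
            order[t] = cand[perm[t]]
        newc = 0
        for t in range(c):
            u = order[t]
            deg = indptr[u + 1] - indptr[u]
            frac = 0.0 if deg == 0 else lab_count[u] / deg
            if antagonist[u]:
                fire = frac < thresholds[u]
            else:
                fire = frac >= thresholds[u]
            if fire:
                labels[u] = True
                changed = True
                for e in range(indptr[u], indptr[u + 1]):
                    lab_count[indices[e]] += 1
            else:
                cand[newc] = u
                newc += 1
        c = newc
    return sweeps + 1  # count the final sweep that labelled nothing


def _run_cascade_python(
    net: ThresholdNetwork, state: LabelState, rng: np.random.Generator
) -> None:
    """Reference implementation of the sweep semantics, with event trace."""
    is_seed = net.is_seed_mask()
    candidates = [u for u in range(net.n) if not is_seed[u] and not state.labels[u]]
    state.trace = []
    sweeps = 0
    changed = True
    while changed and candidates:
        changed = False
        sweeps += 1
        order = [candidates[i] for i in rng.permutation(len(candidates))]
        remaining = []
        for u in order:
            if fires(u, state, net):
                state.labels[u] = True
                state.trace.append((sweeps, u))
                changed = True
            else:
                remaining.append(u)
        candidates = remaining
    state.sweeps = sweeps + 1


def run_cascade(
    net: ThresholdNetwork,
    seed_pattern,
    rng: np.random.Generator | int | None = None,
    record_trace: bool = False,
) -> LabelState:
    """Run one cascade to its fixed point and return the final label state.

    Parameters
    ----------
    net
        Frozen network (edges, thresholds, flags unchanged across patterns).
    seed_pattern
        Boolean vector of length k; ``seed_pattern[i]`` is clamped onto
        ``net.seed_nodes[i]`` for the whole run. Seeds are inputs: they are
        never examined by the update rule.
    rng
        Source for the update-order stream (Generator, integer seed, or
        None for a fresh nondeterministic stream). For a pure LTM the fixed
        point does not depend on it; with antagonists present the fixed
        point is a sample over update orders.
    record_trace
        If True, run the (slower) traced path and attach the ordered list of
        (sweep, node) labelling events.
    """
    pattern = np.asarray(seed_pattern, dtype=bool).ravel()
    if pattern.size != net.k:
        raise ValueError(
            f"seed pattern length {pattern.size} != number of seeds {net.k}"
        )
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    labels = np.zeros(net.n, dtype=bool)
    labels[net.seed_nodes] = pattern
    state = LabelState(labels=labels, seed_pattern=pattern)

    if record_trace:
        _run_cascade_python(net, state, rng)
        return state

    adj = net.adjacency()
    order_seed = int(rng.integers(0, 2**31))
    state.sweeps = int(
        _cascade_kernel(
            adj.indptr.astype(np.int64),
            adj.indices.astype(np.int64),
            net.thresholds,
            net.antagonist_flags,
            net.is_seed_mask(),
            labels,
            order_seed,
        )
    )
    return state
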