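"""Boolean functions computed at network nodes.

A function on ``k`` inputs is a truth table of length ``2**k``. Rows are
input patterns in ascending integer order, with a pattern ``(a, b, ...)``
read as a binary number whose most significant bit is the first seed. The
canonical integer id is the table read most-significant-bit first::

    id = sum_x table[x] * 2**(2**k - 1 - x)

so that on k = 2 inputs AND = f1, XOR = f6, OR = f7, NAND = f14.

Decision-tree complexity is measured through Hamming-cube symmetry: with
D = k axes, let R be the number of axes along which the table is constant
(invariant under flipping that input bit); then C = D - R, the number of
relevant inputs. For monotone functions C equals the number of seed-to-node
paths the minimal computing motif requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade import run_cascade
from .network import ThresholdNetwork, gcc_fraction_theoretical

__all__ = [
    "BooleanFunction",
    "extract_functions",
    "extract_function_ids",
    "is_monotone",
    "complexity",
    "enumerate_monotone",
    "predicted_probability",
    "input_patterns",
]


def input_patterns(k: int) -> np.ndarray:
    """All 2**k input patterns as a (2**k, k) boolean array, ascending order.

    Column 0 is the first seed (most significant bit).
    """
    x = np.arange(2**k, dtype=np.int64)
    shifts = np.arange(k - 1, -1, -1)
    return ((x[:, None] >> shifts[None, :]) & 1).astype(bool)


@dataclass(frozen=True)
class BooleanFunction:
    """Truth table over k inputs with its canonical integer id."""

    k: int
    table: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.table) != 2**self.k:
            raise ValueError("table length must be 2**k")
        if any(b not in (0, 1) for b in self.table):
            raise ValueError("table entries must be 0 or 1")

    @property
    def id(self) -> int:
        rows = 2**self.k
        return sum(b << (rows - 1 - x) for x, b in enumerate(self.table))

    @classmethod
    def from_id(cls, func_id: int, k: int) -> "BooleanFunction":
        rows = 2**k
        if not 0 <= func_id < 2**rows:
            raise ValueError(f"function id {func_id} out of range for k={k}")
        table = tuple((func_id >> (rows - 1 - x)) & 1 for x in range(rows))
        return cls(k=k, table=table)

    def __call__(self, *inputs: int) -> int:
        if len(inputs) != self.k:
            raise ValueError(f"expected {self.k} inputs")
        x = 0
        for b in inputs:
            x = (x << 1) | (1 if b else 0)
        return self.table[x]

    def negation(self) -> "BooleanFunction":
        return BooleanFunction(self.k, tuple(1 - b for b in self.table))


# -- extraction from cascades ---------------------------------------------


def extract_function_ids(
    net: ThresholdNetwork, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Function id per node, from one cascade per input pattern.

    The network (edges, thresholds, flags) is frozen across all ``2**k``
    patterns; non-seed labels are reset before each run and each pattern
    uses an independent update-order stream drawn from ``rng``. The output
    bit of node u for pattern x is its final label. Entries for the seed
    nodes themselves are the projection functions they trivially compute.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    k = net.k
    rows = 2**k
    ids = np.zeros(net.n, dtype=np.int64)
    for x, pattern in enumerate(input_patterns(k)):
        state = run_cascade(net, pattern, rng=rng)
        ids += state.labels.astype(np.int64) << (rows - 1 - x)
    return ids


def extract_functions(
    net: ThresholdNetwork, rng: np.random.Generator | int | None = None
) -> dict[int, BooleanFunction]:
    """Map each non-seed node to the Boolean function it computes."""
    ids = extract_function_ids(net, rng=rng)
    is_seed = net.is_seed_mask()
    return {
        u: BooleanFunction.from_id(int(ids[u]), net.k)
        for u in range(net.n)
        if not is_seed[u]
    }


# -- structure of functions ------------------------------------------------


def _table_array(f: BooleanFunction | int, k: int | None = None) -> tuple[np.ndarray, int]:
    if isinstance(f, BooleanFunction):
        return np.asarray(f.table, dtype=np.int8), f.k
    if k is None:
        raise ValueError("k required when passing a raw function id")
    return (
        np.asarray(BooleanFunction.from_id(f, k).table, dtype=np.int8),
        k,
    )


def is_monotone(f: BooleanFunction | int, k: int | None = None) -> bool:
    """True iff the function is monotone increasing (x <= y implies f(x) <= f(y))."""
    table, k = _table_array(f, k)
    x = np.arange(2**k)
    for i in range(k):
        bit = 1 << (k - 1 - i)
        lo = x[(x & bit) == 0]
        if np.any(table[lo] > table[lo | bit]):
            return False
    return True


def complexity(f: BooleanFunction | int, k: int | None = None) -> int:
    """Decision-tree complexity C = D - R via axial reflections.

    R counts the Hamming-cube axes along which the table is constant; C is
    therefore the number of relevant inputs, 0 <= C <= k.
    """
    table, k = _table_array(f, k)
    x = np.arange(2**k)
    r = 0
    for i in range(k):
        bit = 1 << (k - 1 - i)
        lo = x[(x & bit) == 0]
        if np.array_equal(table[lo], table[lo | bit]):
            r += 1
    return k - r


def enumerate_monotone(k: int) -> list[BooleanFunction]:
    """All monotone-increasing functions on k inputs, ascending id order.

    Exhaustive scan over the 2**(2**k) candidates; rejected for k > 4.
    """
    if not 1 <= k <= 4:
        raise ValueError("enumerate_monotone supports 1 <= k <= 4")
    rows = 2**k
    ids = np.arange(2**rows, dtype=np.int64)
    shifts = rows - 1 - np.arange(rows)
    tables = (ids[:, None] >> shifts[None, :]) & 1  # (2^2^k, 2^k)
    ok = np.ones(ids.size, dtype=bool)
    x = np.arange(rows)
    for i in range(k):
        bit = 1 << (k - 1 - i)
        lo = x[(x & bit) == 0]
        ok &= np.all(tables[:, lo] <= tables[:, lo | bit], axis=1)
    return [BooleanFunction.from_id(int(i), k) for i in ids[ok]]


def predicted_probability(
    f: BooleanFunction | int, z: float, k: int | None = None
) -> float:
    """Complexity-based occurrence probability (unnormalized): v**(C+1).

    v is the giant-component fraction at mean degree z; below criticality
    (z <= 1) the prediction is 0 for every function. The exponent C + 1 is
    the node count of the minimal path structure a monotone function of
    complexity C requires (C seed-to-node paths plus the node itself, in a
    tree-like graph).
    """
    if isinstance(f, BooleanFunction):
        c = complexity(f)
    else:
        c = complexity(f, k)
    v = gcc_fraction_theoretical(z)
    return float(v ** (c + 1))
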