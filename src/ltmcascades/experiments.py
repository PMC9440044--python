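"""Ensemble experiments: function censuses and their headline statistics.

The central object is a :class:`FunctionCensus`: for an ensemble of random
threshold networks with fixed (n, k, z, theta), the per-realization counts
of how many non-seed nodes compute each Boolean function id. From a census
this module derives

* the rank ordering of mean function frequencies,
* the Pearson correlation between observed frequencies and the
  complexity-based prediction v**(C+1),
* the decreasing-exponential fit of log-frequency against rank, and
* the (z, theta) surface of mean unique-function counts, whose argmax over
  the antagonism fraction theta locates the diversity optimum.

The constant functions are excluded from frequency analyses: f0 always
(nodes with no path to any seed), and additionally the all-ones function
f_{2^{2^k}-1} whenever antagonists are present, since both can occur
outside the giant component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from .boolfunc import complexity, extract_function_ids
from .motifs import _CATALOG
from .network import gcc_fraction_theoretical, generate_network

__all__ = [
    "CensusConfig",
    "FunctionCensus",
    "function_census",
    "rank_ordering",
    "prediction_table",
    "prediction_correlation",
    "exponential_rank_fit",
    "unique_function_surface",
    "argmax_theta",
    "FULL_PRESET",
    "DESK_PRESET",
]

# Grid defaults: the full-scale study and a small desk-scale variant.
FULL_PRESET = {
    "n": 10000,
    "k": 2,
    "realizations": 500,
    "z_list": [0, 0.5, 1, 2, 4, 8, 16, 64, 256, 1024, 4096, 10000],
    "theta_list": [i / 6 for i in range(7)],
}
DESK_PRESET = {
    "n": 2000,
    "k": 2,
    "realizations": 50,
    "z_list": [8, 64, 1024],
    "theta_list": [i / 6 for i in range(7)],
}


@dataclass(frozen=True)
class CensusConfig:
    """Ensemble configuration for one (n, k, z, theta) cell."""

    n: int
    k: int
    z: float
    theta: float = 0.0
    realizations: int = 100
    master_seed: int = 0
    n_jobs: int = 1

    def all_ones_id(self) -> int:
        return 2 ** (2**self.k) - 1

    def default_exclusions(self) -> frozenset[int]:
        """f0 always; the all-ones function additionally when theta > 0."""
        if self.theta > 0:
            return frozenset({0, self.all_ones_id()})
        return frozenset({0})


@dataclass
class FunctionCensus:
    """Per-realization counts of function ids across non-seed nodes."""

    config: CensusConfig
    counts: list[dict[int, int]]
    realization_seeds: list[int] = field(default_factory=list)
    exclusions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.exclusions:
            self.exclusions = self.config.default_exclusions()

    @property
    def realizations(self) -> int:
        return len(self.counts)

    def observed_ids(self, apply_exclusions: bool = True) -> list[int]:
        ids: set[int] = set()
        for c in self.counts:
            ids.update(c)
        if apply_exclusions:
            ids -= self.exclusions
        return sorted(ids)

    def frequency_matrix(self, apply_exclusions: bool = True) -> pd.DataFrame:
        """Realizations x function-id frequency table (count / (n - k))."""
        ids = self.observed_ids(apply_exclusions)
        denom = self.config.n - self.config.k
        mat = np.zeros((self.realizations, len(ids)))
        col = {fid: j for j, fid in enumerate(ids)}
        for i, c in enumerate(self.counts):
            for fid, cnt in c.items():
                j = col.get(fid)
                if j is not None:
                    mat[i, j] = cnt / denom
        return pd.DataFrame(mat, columns=ids)

    def unique_counts(self) -> np.ndarray:
        """Per-realization count of distinct function ids, post-exclusion."""
        return np.array(
            [len(set(c) - self.exclusions) for c in self.counts], dtype=np.int64
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per (realization, function id)."""
        rows = [
            {"realization": i, "function_id": fid, "count": cnt}
            for i, c in enumerate(self.counts)
            for fid, cnt in sorted(c.items())
        ]
        df = pd.DataFrame(rows, columns=["realization", "function_id", "count"])
        for key in ("n", "k", "z", "theta", "master_seed"):
            df[key] = getattr(self.config, key)
        return df


def _one_realization(config: CensusConfig, net_seed: int, order_seed: int) -> dict[int, int]:
    net = generate_network(
        n=config.n, z=config.z, k=config.k, theta=config.theta, rng_seed=net_seed
    )
    ids = extract_function_ids(net, rng=order_seed)
    non_seed = ~net.is_seed_mask()
    vals, cnts = np.unique(ids[non_seed], return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, cnts)}


def function_census(config: CensusConfig) -> FunctionCensus:
    """Run the ensemble and tally function counts per realization.

    Each realization draws a fresh network seed and cascade-order seed from
    a stream derived from the master seed, so results are deterministic
    given the config and bit-identical whether realizations run serially or
    in parallel.
    """
    if config.realizations < 1:
        raise ValueError("need at least one realization")
    ss = np.random.SeedSequence(config.master_seed)
    state = ss.generate_state(2 * config.realizations) & 0x7FFFFFFF
    net_seeds = state[: config.realizations]
    order_seeds = state[config.realizations :]
    if config.n_jobs == 1:
        counts = [
            _one_realization(config, int(ns), int(os_))
            for ns, os_ in zip(net_seeds, order_seeds)
        ]
    else:
        counts = Parallel(n_jobs=config.n_jobs)(
            delayed(_one_realization)(config, int(ns), int(os_))
            for ns, os_ in zip(net_seeds, order_seeds)
        )
    return FunctionCensus(
        config=config, counts=counts, realization_seeds=[int(s) for s in net_seeds]
    )


# -- rank ordering and predictions ----------------------------------------


def rank_ordering(census: FunctionCensus) -> pd.DataFrame:
    """Mean function frequencies in descending order.

    Exclusions (f0, and the all-ones function when theta > 0) are applied
    first; ties are broken by ascending function id. Columns:
    function_id, mean_frequency, std_frequency, rank.
    """
    freq = census.frequency_matrix(apply_exclusions=True)
    if freq.shape[1] == 0:
        return pd.DataFrame(
            columns=["function_id", "mean_frequency", "std_frequency", "rank"]
        )
    mean = freq.mean(axis=0)
    std = freq.std(axis=0, ddof=0)
    df = pd.DataFrame(
        {
            "function_id": mean.index.to_numpy(dtype=np.int64),
            "mean_frequency": mean.to_numpy(),
            "std_frequency": std.to_numpy(),
        }
    )
    df = df.sort_values(
        ["mean_frequency", "function_id"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(len(df))
    return df


def prediction_table(k: int, z: float, function_ids=None) -> pd.DataFrame:
    """Complexity-based predictions per function id.

    Columns: function_id, complexity C, exponent C + 1, predicted value
    v**(C+1), and (for k = 2) the motif exponent — the number of nodes whose
    joint giant-component membership the minimal motif requires.
    """
    if function_ids is None:
        from .boolfunc import enumerate_monotone

        function_ids = [f.id for f in enumerate_monotone(k)]
    v = gcc_fraction_theoretical(z)
    rows = []
    for fid in function_ids:
        c = complexity(int(fid), k)
        motif_exp = np.nan
        if k == 2 and fid in _CATALOG:
            motif_exp = _CATALOG[fid][5]
        rows.append(
            {
                "function_id": int(fid),
                "complexity": c,
                "exponent": c + 1,
                "predicted": v ** (c + 1),
                "motif_exponent": motif_exp,
            }
        )
    return pd.DataFrame(rows)


def prediction_correlation(
    census: FunctionCensus, predictions: pd.DataFrame | None = None
) -> float:
    """Pearson r between mean observed frequency and predicted probability.

    Computed across the observed function ids after exclusions (raw values;
    Pearson r is invariant to centering and rescaling, so overlays that
    normalize the prediction do not change it). Raises on fewer than three
    functions or on a constant vector, where r is undefined.
    """
    ranked = rank_ordering(census)
    if len(ranked) < 3:
        raise ValueError("need at least three functions after exclusions")
    if predictions is None:
        predictions = prediction_table(
            census.config.k, census.config.z, ranked["function_id"]
        )
    pred = predictions.set_index("function_id")
    x = ranked["mean_frequency"].to_numpy()
    y = pred["predicted"].reindex(ranked["function_id"]).to_numpy()
    if np.isnan(y).any():
        raise ValueError("prediction table missing an observed function id")
    if np.ptp(y) == 0 and "exponent" in pred.columns:
        # High connectivity: v is so close to 1 that v**(C+1) rounds to a
        # constant in double precision. Pearson r is scale/shift invariant,
        # so correlate with log-space predictions (C+1)*log(v) instead,
        # computed stably via log1p(-exp(-z v)); this is the exact limit of
        # r as v -> 1 and reduces to the same value whenever both are
        # representable.
        z = census.config.z
        v = gcc_fraction_theoretical(z)
        if v > 0 and np.exp(-z * v) > 0:
            log_v = np.log1p(-np.exp(-z * v))
            y = pred["exponent"].reindex(ranked["function_id"]).to_numpy() * log_v
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def exponential_rank_fit(ranked: pd.DataFrame) -> tuple[float, float]:
    """Fit log(mean frequency) against rank by ordinary least squares.

    Entries with zero mean frequency are dropped before taking the log.
    Returns ``(decay_rate, r_squared)`` where the fitted model is
    ``frequency ∝ exp(-decay_rate * rank)``.
    """
    sub = ranked[ranked["mean_frequency"] > 0]
    if len(sub) < 3:
        raise ValueError("need at least three positive-frequency entries")
    res = stats.linregress(
        sub["rank"].to_numpy(dtype=float), np.log(sub["mean_frequency"].to_numpy())
    )
    return float(-res.slope), float(res.rvalue**2)


# -- antagonism grid -------------------------------------------------------


def unique_function_surface(
    z_list,
    theta_list,
    n: int = DESK_PRESET["n"],
    k: int = 2,
    realizations: int = DESK_PRESET["realizations"],
    master_seed: int = 0,
    n_jobs: int = 1,
    progress: bool = False,
) -> pd.DataFrame:
    """Mean unique-function count over a (z, theta) grid.

    Per cell, the mean over realizations of the number of distinct function
    ids appearing in that realization, after the cell's exclusions (f0
    always; the all-ones function additionally when theta > 0). Each cell
    derives its own census seed from the master seed and its grid position.
    """
    rows = []
    base = np.random.SeedSequence(master_seed)
    cells = [(zi, ti) for zi in range(len(z_list)) for ti in range(len(theta_list))]
    cell_seeds = base.generate_state(len(cells)) & 0x7FFFFFFF
    iterator = zip(cells, cell_seeds)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc="surface cells")
    for (zi, ti), cell_seed in iterator:
        z, theta = z_list[zi], theta_list[ti]
        census = function_census(
            CensusConfig(
                n=n,
                k=k,
                z=z,
                theta=theta,
                realizations=realizations,
                master_seed=int(cell_seed),
                n_jobs=n_jobs,
            )
        )
        uniq = census.unique_counts()
        rows.append(
            {
                "z": z,
                "theta": theta,
                "mean_unique": float(uniq.mean()),
                "std_unique": float(uniq.std(ddof=0)),
                "realizations": realizations,
            }
        )
    return pd.DataFrame(rows)


def argmax_theta(
    surface: pd.DataFrame, z_range: tuple[float, float] | None = None
) -> float:
    """Theta maximizing mean unique-function count averaged over a z range.

    Ties are broken toward smaller theta.
    """
    sub = surface
    if z_range is not None:
        lo, hi = z_range
        sub = surface[(surface["z"] >= lo) & (surface["z"] <= hi)]
    if sub.empty:
        raise ValueError("surface does not cover the requested z range")
    by_theta = sub.groupby("theta")["mean_unique"].mean().sort_index()
    return float(by_theta.idxmax())  # idxmax returns the first (smallest) max
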