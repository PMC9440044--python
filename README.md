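# ltmcascades

Computation emerges spontaneously in randomly connected threshold networks:
when a cascade (avalanche) model is run from a small set of perturbed input
nodes, every other node ends up computing a Boolean function of the inputs.
`ltmcascades` simulates this process, identifies the function computed at
every node, and reproduces the statistics that govern *which* functions
emerge. It is aimed at researchers in complex networks, computational
neuroscience and statistical physics who want a reproducible, tested
implementation of threshold-cascade logic.

## The model

**Linear threshold model (LTM).** An Erdős–Rényi–Gilbert graph G(N, p) with
p = z/(N−1) for mean degree z; each node u draws a threshold φ_u ~ U(0, 1).
Nodes are *unlabelled* (0) or *labelled* (1). A perturbation pattern is
clamped onto k designated seed nodes; unlabelled nodes are then examined in
repeated uniformly random permutation sweeps, and u becomes labelled
(permanently, asynchronously) when its labelled-neighbour fraction reaches
its threshold:

    L(u) / deg(u) ≥ φ_u .

**Antagonistic LTM (ALTM).** An *antagonistic* (inhibitory) node uses the
negated rule, firing when L(u)/deg(u) < φ_u. A fraction θ of non-seed nodes
is antagonistic.

**Function extraction.** Freezing the network and running one cascade per
input pattern (all 2^k of them) assigns each non-seed node a truth table —
a Boolean function f of the seeds, numbered by its bit string read
most-significant-row first (k = 2: AND = f₁, XOR = f₆, OR = f₇, NAND = f₁₄).
A pure LTM can only compute monotone increasing functions with f(0,…,0) = 0
(f₀, f₁, f₃, f₅, f₇ at k = 2); antagonism unlocks the rest, including a
universal (NAND/NOR) basis.

**Why some functions are common and others rare.** A function needs paths
from the seeds to the computing node. In a supercritical random graph those
path probabilities reduce to giant-component membership: with v solving the
self-consistency v = 1 − e^{−zv} (nonzero only above z_c = 1), a function
whose minimal *logic motif* ties together m nodes occurs with probability
∝ v^m. For monotone functions m = C + 1, where C = D − R is the
decision-tree complexity read off the Hamming cube (D = k axes, R of which
leave the table invariant — so C counts relevant inputs):

    p(f) ∝ v^(C(f) + 1) .

Frequency therefore decreases with complexity, producing the exponential
rank ordering the ensembles exhibit. The minimal XOR automaton is the
documented exception: it needs 5 jointly connected nodes (6 paths), not
C + 1 = 3.

## Worked example

```python
from ltmcascades import (CensusConfig, function_census, rank_ordering,
                         prediction_correlation, gcc_fraction_theoretical)

print(round(gcc_fraction_theoretical(4.0), 5))   # 0.98017

cfg = CensusConfig(n=10000, k=2, z=4.0, theta=0.0, realizations=500,
                   master_seed=42)
census = function_census(cfg)                     # ~5 s
print(rank_ordering(census))
print(round(prediction_correlation(census), 3))
```

Output:

```
0.98017
   function_id  mean_frequency  std_frequency  rank
0            3    3.924785e-04       0.000727     0
1            5    3.498700e-04       0.000711     1
2            7    9.001800e-06       0.000201     2
3            1    8.001600e-07       0.000018     3
0.997
```

Reading it: at z = 4 the giant component holds 98% of nodes, yet cascades
from two seeds stay local (uniform thresholds keep avalanches subcritical),
so non-zero functions are rare and skewed. The projections f₃ = a and
f₅ = b (complexity C = 1, prediction v²) are hundreds of times more common
than OR and AND (C = 2, prediction v³), and the frequency/prediction
Pearson correlation is ≈ 1.

The same machinery drives the CLI:

```bash
ltm-cascades census --n 10000 --z 4 --k 2 --realizations 500 --seed 42 --out out/
ltm-cascades motifs --out motifs/     # verifies all 16 k=2 logic automata
ltm-cascades surface --preset desk --seed 3 --out surf/
```

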