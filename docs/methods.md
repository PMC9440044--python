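# Methods

## Model definition and update semantics

A `ThresholdNetwork` is an undirected Erdős–Rényi–Gilbert graph on N nodes
with edge probability p = z/(N−1), clamped to 1 when z ≥ N−1 (so z = N
denotes the complete graph). Thresholds are i.i.d. uniform on the *open*
interval (0, 1): excluding φ = 0 (a measure-zero event under U[0,1])
guarantees that an excitatory node with no labelled neighbours can never
fire, which keeps the all-zero input pattern inert in the pure LTM. Each
network carries k distinct seed nodes chosen uniformly, and
round(θ·(N−k)) uniformly chosen non-seed nodes are antagonistic. Seeds are
clamped inputs — they are never examined by the update rule — so they are
never flagged antagonistic (their rule would be irrelevant).

A cascade clamps a binary pattern onto the seeds and then performs
permutation sweeps: each sweep examines the currently unlabelled non-seed
nodes in a fresh uniformly random order, labelling a node immediately when
its rule fires (asynchronous commitment). Labels are permanent; the run
ends when a full sweep labels nothing, which bounds the number of sweeps by
N + 1 since every non-final sweep labels at least one node. Isolated nodes
have labelled-neighbour fraction 0 by convention: excitatory isolates never
fire, antagonistic isolates always do (hence the constant-1 function
appears off the giant component).

Two consequences of permanence are worth stating plainly:

* **Pure LTM (θ = 0) is schedule-independent.** Labelling is a monotone
  closure operator, so the fixed point is unique; the test suite verifies
  identity across random schedules, and the numba kernel is cross-checked
  against a pure-Python reference implementation on this case.
* **ALTM (θ > 0) is schedule-dependent.** An antagonist examined before its
  neighbourhood activates fires (fraction 0 < φ); examined later, it may
  not, and there is no unlabelling rule that could repair the difference.
  Extracted functions under antagonism are therefore samples over the
  update-order distribution, reproducible through the seeded order stream.

## Function identification, complexity, and predictions

For one frozen network, one cascade per input pattern (2^k patterns,
ascending integer order, first seed = most significant bit) yields each
node's truth table; its id is the table read most-significant-row first,
fixing AND = 1, XOR = 6, OR = 7, NAND = 14 at k = 2. Monotone functions
are enumerated by brute-force scan (k ≤ 4; 168 monotone functions at
k = 4). Decision-tree complexity is implemented exactly as the axial-
reflection count on the Hamming cube: C = D − R with D = k and R the
number of input axes along which the table is constant — i.e. the number of
relevant inputs. No complexity notion is invented for non-monotone
functions beyond this.

The occurrence prediction for a function is v^(C+1), with v the largest
root of v = 1 − e^{−zv} (bisection-bracketed Brent solve on (10⁻¹², 1],
residual < 10⁻¹⁰; v = 0 for z ≤ 1). The motif catalog supplies the
path-based alternative: every k = 2 function has a concrete minimal
fragment whose output node provably computes it, verified exhaustively over
all asynchronous update orders by depth-first search over the reachable
label states (this transition system subsumes every permutation-sweep
schedule). For non-constant monotone functions the motif's
jointly-connected node count equals C + 1, so both prediction families
coincide; for XOR the minimal fragment needs 5 nodes and 6 paths against
the complexity argument's 3 — the known defect of the complexity bound for
non-monotone functions, which the package reproduces rather than repairs.

Fragment design note: because edges are undirected, an internal relay also
senses its downstream gate. Thresholds in the catalog are chosen so that
this back-coupling cannot flip any firing decision before the downstream
gate fires (degree-2 antagonist relays use φ = 0.25 ≤ 1/2; degree-3 NAND
gates use φ = 0.5 ∈ (1/3, 2/3]; degree-3 OR gates use φ = 0.25 ≤ 1/3). The
XNOR fragment is built as OR(AND, NOR) rather than a node-by-node negation
of the XOR fragment, because negating the output node would place an
antagonist downstream of non-seed nodes and make the fragment
schedule-dependent under permanent labels.

## Ensembles and statistics

A census runs R independent realizations of one (N, k, z, θ) cell; each
realization derives its own network seed and cascade-order seed from the
master seed through a `SeedSequence` stream, so results are bit-identical
whether realizations run serially or through joblib workers. Frequencies
are per-node: count/(N−k). Exclusions follow the giant-component logic:
f₀ is always dropped (no path to any seed), and the all-ones function is
additionally dropped whenever θ > 0 (isolated antagonists produce it off
the giant component). Rank orderings sort by descending mean frequency with
ascending-id tie-break; the exponential rank law is fit by ordinary least
squares of log mean frequency on rank (zero-frequency entries dropped
before the log); correlations are plain Pearson r on raw values — Pearson
is scale- and shift-invariant, so the centered/normalized overlays used for
plotting do not change it.

**Degenerate high-connectivity predictions.** At z = 64, v = 1 − e^{−64}
rounds to 1.0 in double precision and v^(C+1) becomes constant. The
correlation routine then substitutes the exact v → 1 limit: it correlates
with (C+1)·log v, computed stably as log1p(−e^{−zv}). Pearson invariance
makes this the limit of the nominal definition, not an alternative
statistic.

## Problem sizes and defaults

Full-scale ensembles use the study conditions N = 10⁴, k ∈ {2, 4}, z = 4,
500 realizations; the mixed-model cell uses z = 64, θ = 1/3. The
antagonism grid's full preset is N = 10⁴, 500 realizations over
z ∈ {0, ½, 1, 2, 4, 8, 16, 64, 256, 1024, 4096, 10⁴} and θ ∈ {0, 1/6, …,
1}; the packaged `desk` preset (N = 2000, 50 realizations,
z ∈ {8, 64, 1024}) covers the connectivity decades where the diversity
optimum is reported while keeping the grid to a few minutes on one core.
The cascade inner loop is a numba kernel (CSR adjacency, incremental
labelled-neighbour counts); G(n, p) edges are sampled by vectorized
geometric inter-arrival skips over the linearized upper triangle — the same
O(n+m) algorithm networkx's sparse generator uses, cross-checked against it
distributionally in the test suite.

## What the generator emulates — and what passing tests do not show

All inputs are synthetic by design: the object of study is the ensemble of
uniform-threshold ER networks itself, not a fitted model of data. Passing
tests therefore certify the mathematics of that idealized ensemble —
percolation theory, motif logic, frequency laws — and say nothing about
real neuronal or social networks, whose degree correlations, clustering,
weighted synapses and plasticity are outside the model class (the LTM has
no layering, weights, or geometry).

## Known limitations and observed discrepancies

* **Cascades are subcritical at uniform thresholds.** From finite seed
  sets, avalanches stay local for every z (the vulnerable-cluster condition
  never holds under U(0,1) thresholds), so non-zero functions are rare
  events: at N = 10⁴, z = 4, k = 2 the projections appear at ~4·10⁻⁴
  frequency and AND at ~10⁻⁶. Rank statistics consequently need hundreds of
  realizations, and the k = 2 correlation is undefined (< 3 observed
  functions) on small ensembles.
* **The k = 4 frequency/prediction correlation is not a convergent
  statistic.** Computed over *observed* functions, it declines as the
  ensemble grows and rarer complex functions enter the observed set
  (≈ 0.999 at 500 realizations, ≈ 0.9 at 3000, ≈ 0.56 in the
  all-monotone-functions limit). Reference values for it are therefore tied
  to a specific ensemble size and implementation; this package computes it
  at 500 realizations and reports what it measures. The exponential rank
  law itself is stable (r² ≈ 0.88).
* **Antagonistic ensembles are order-noise dominated at high z.** At
  z = 64, θ = 1/3, antagonists fire essentially at random relative to the
  input pattern (whoever is examined before local activity arrives), so
  extracted functions are dominated by schedule noise: two-input gates
  (C = 2) outnumber projections (C = 1) and the frequency/prediction
  correlation comes out strongly *negative* (≈ −0.7), not positive. A
  positive correlation there would require different ALTM semantics (e.g.
  re-examination/unlabelling to an attractor), which the permanent-label
  definition adopted here deliberately excludes; this is the model's main
  semantic ambiguity and we document rather than hide it.
* **Desk-scale diversity surface saturates.** At N = 2000 every grid cell
  with θ ≥ 1/3 realizes all 14 non-constant k = 2 functions, so θ = 1/3 is
  selected as the smallest antagonism fraction achieving full diversity
  (ties break toward smaller θ; θ = 1/6 falls just short at ≈ 13.4–13.9).
  The optimum is thus reproduced as a saturation onset rather than an
  interior peak at this scale.
* Thresholds are i.i.d. uniform only; k ≤ 4; ER topology only. Rewiring,
  geometric constraints, transfer-entropy analyses and very large N are out
  of scope.
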