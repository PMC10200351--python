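# Methods

## The model class

`ktnreduce` operates on continuous-time Markov chains defined on kinetic
transition networks (KTNs): graphs whose nodes are discrete states (for a
molecular system, potential-energy minima) and whose edges carry pairwise
transition rates. The chain is stored column-oriented: `K[i, j]` is the rate
of the jump `j -> i`, the mean waiting time of node `j` is
`tau_j = 1 / sum_g K[g, j]`, the branching matrix is `B = K D^-1` with
`D = diag(1/tau)` (columns of `B` sum to one), and the generator is
`Q = K - D` (columns sum to zero, so `dP/dt = Q P` conserves probability).
Chains built from node energies with shared transition-state energies
satisfy detailed balance, `K_ji pi_i = K_ij pi_j` with
`pi ~ exp(-E/T)`, exactly by construction; reversibility is flagged when the
largest relative pairwise flux residual is at most 1e-10.

The regime of interest is strong metastability: rate constants spanning many
orders of magnitude, with trajectories trapped in communities of states for
times vastly longer than the internal relaxation. In that regime the
eigendecompositions behind first-passage-time (FPT) distributions lose
precision, and plain kinetic Monte Carlo (kMC) stalls by flickering inside
traps — the two failure modes this package is organized around.

## Graph transformation

Graph transformation (GT) removes states exactly. Eliminating one state `z`
renormalizes the survivors as

    B'_ij  = B_ij + B_iz B_zj / (1 - B_zz)
    tau'_i = tau_i + tau_z B_zi / (1 - B_zz)

and a block `Z` is removed in one shot through the Green's matrix
`G_Z = [I - B_ZZ]^-1`:

    B' = B_OO + B_OZ G_Z B_ZO,    tau' = tau_O + tau_Z G_Z B_ZO.

Branching probabilities between retained states, absorption (splitting)
probabilities, and mean first-passage times between retained states are all
invariant under this operation, in any elimination order. The stationary
distribution renormalizes by the waiting-time ratio,
`pi'_i = pi_i tau'_i / tau_i`, which sums to one identically; the code
asserts this to 1e-10 and treats violation as an internal error. If the
input satisfies detailed balance, so does the reduced chain with `pi'`.

Numerical choices:

- The survival factor `1 - B_zz` is always accumulated as the sum of the
  off-diagonal column entries — nonnegative numbers of similar magnitude —
  never by subtracting from one. This keeps single-node GT valid for
  arbitrarily ill-conditioned chains.
- Block elimination first estimates the 1-norm condition number of
  `I - B_ZZ`; above 1e10 (configurable) it falls back to the state-by-state
  route. Default block size is 64.
- Elimination order is ascending stationary probability (fast, weakly
  occupied states first), processed in blocks. The result is
  order-invariant; the ordering only limits fill-in and conditioning along
  the way.
- Self-loops `B'_ii > 0` produced by elimination are retained: the
  renormalized generator `Q' = [B' - I] D'` consumes them, and the samplers
  are written to handle them.

### Partial GT

Full GT reduction to sources and sinks yields mean FPTs only. Partial GT
stops earlier: given a community partition, it retains every community's
boundary nodes (states with an edge into another community — all
inter-community flux passes through them) plus the single state of maximal
stationary probability per community (`b0`), and eliminates everything else.
Because entry into a community always lands on one of its boundary nodes,
inter-community mean FPTs are exactly preserved for any initial distribution
supported on retained states, and in the metastable regime the full FPT
*distribution* is preserved to high accuracy (escape statistics become
insensitive to the initial distribution once the internal mixing time is
much shorter than the escape time).

## Spectral first-passage analysis

For a target set `A`, the sub-generator `Q_S` over `S = Omega \ A` (diagonal
keeps the full escape rates) yields the FPT density as a sum of exponential
modes, `p(t) = sum_l lambda_l c_l exp(-lambda_l t)` with weights
`c_l = (1 . w^R_l)(w^L_l . P_S(0))`, and the log-time density
`P(y) = sum_l lambda_l e^{y - lambda_l e^y} c_l`, `y = ln t`, which
separates competing pathways into distinct peaks. The mean is
`sum_l c_l / lambda_l`, cross-checked against the independent linear-solve
route `tau_S [I - B_SS]^-1 P_S(0)`; disagreement beyond 1e-6 relative
triggers a warning recommending the GT route.

- Reversible chains are diagonalized via the symmetric similarity transform
  `diag(pi^-1/2) Q_S diag(pi^1/2)` (real spectrum, orthogonal eigenbasis);
  non-reversible chains use a general solver with explicit
  biorthonormalization.
- Precision guard: if the mode weights fail `|sum_l c_l - 1| <= 1e-6`, or any
  single `|c_l| > 1e3` (wild cancellation), the computation aborts with a
  diagnostic instead of returning an invalid distribution — this is the
  finite-precision failure mode that motivates GT reduction in the first
  place.
- Default evaluation grid: 400 log-spaced points on
  `[1e-2/lambda_max, 1e2/lambda_min]`.

Community metastability is quantified by the mixing time
`tau_m = 1/(lambda_1 - lambda_0)` of the community sub-generator (escape
included); the product `lambda_0 tau_m` is the metastability ratio, and the
dominant right eigenvector normalized to unit sum is the quasi-stationary
distribution (QSD). Four initial distributions are provided: local
Boltzmann (`Boltz`), a delta at `b0` (`Min`), uniform (`Uni`), and `Mix` —
uniform evolved for one mixing time conditional on remaining in the
community, which shifts downstream distributions by `tau_m`.

## Stochastic sampling

The kMC sampler is rejection-free: jumps drawn from the branching-matrix
column of the current state, dwell times exponential with the state's mean
waiting time. On reduced networks, self-loop probability is folded into a
geometric number of consecutive visits with the total dwell drawn from the
matching gamma distribution — preserving both the mean and the distribution
of the occupation time without iterating self-jumps. Each trajectory uses a
generator seeded as `(seed, trajectory_index)`, so ensembles are
reproducible and order-independent.

The basin-escape sampler treats the escape from a community as a single
draw: GT eliminates every community state except the start, the remaining
renormalized branching column gives the absorption probabilities onto the
external neighbours, and the escape time is drawn as one exponential with
the renormalized mean escape time. The mean is exact (a GT guarantee); the
single-exponential shape is an approximation that becomes exact in the
metastable limit, where escape is dominated by one slow mode. Higher
moments of individual basin-escape times are therefore approximate, which
is documented behaviour, not a defect.

## Synthetic landscape generator

The generator emulates a multi-well molecular energy landscape as the test
bed for reduction fidelity. Defaults (all configurable):

- 3x3 grid of wells, 110 nodes per well (990 states), target mean degree
  8.7; nodes placed with Gaussian scatter (sigma 0.18) around well centres
  spaced 1.0 apart.
- Node energy = well base energy (uniform on [-2, 0]) + curvature x r^2
  (curvature 30) + Gaussian roughness (sigma 0.3). The curvature is chosen
  so the local Boltzmann weight at T = 1 is substantially concentrated at
  each community's minimum — the qualitative feature of a low-temperature
  molecular landscape — rather than near-uniform.
- Intra-well edges: pairs sampled with distance-decaying probability to the
  target count, plus a minimum spanning tree for connectivity; this yields a
  Poisson-like degree distribution (variance/mean within [0.5, 2]).
- Inter-well edges: the nearest cross pairs with distinct endpoints between
  grid-adjacent wells (8 per adjacent pair by default); their endpoints are
  the ground-truth boundary nodes.
- Every edge gets a shared transition-state energy
  `E+ = max(E_i, E_j) + barrier`, with barriers drawn as a floor plus an
  exponential (intra: 0.1 + Exp(1.0); inter: 3.0 + Exp(3.0), all in k_B T at
  T = 1). The exponential draws produce broad rate spectra; the inter/intra
  separation makes the wells metastable, increasingly so as T falls. Rates
  follow the Arrhenius form `K_ij = nu exp(-(E+ - E_j)/T)` (prefactor
  nu = 1, units k_B = h = 1), computed and returned in log form so deep
  barriers never underflow.

With these defaults the pipeline reproduces the intended regime: a
~990-node, ~4400-edge network whose partial-GT reduction retains roughly
20% of the states, with per-community metastability ratios of order 1e-3 at
T = 1. What the generator does *not* emulate: real molecular connectivity
(funnels, long-range shortcuts), correlated barrier heights, or any
particular deposited dataset — tests passing on these synthetic landscapes
demonstrate the algebraic and statistical machinery, not agreement with any
specific molecular system.

Scaled-down variants are used where ensembles of trajectories are involved:
the reduction-fidelity experiments run on a 2x2-well system with 15 nodes
per community (60 states), deeper inter-well floors (4.0 k_B T) so every
community has metastability ratio <= 1e-2, and ensembles of 1000
trajectories — sizes chosen so the full validation pipeline runs on one CPU
in minutes.

## Effective free energies and disconnectivity graphs

A reduced chain has no literal potential, but its renormalized stationary
distribution and rates define an effective free-energy surface at
temperature T: `f_w = -T ln pi'_w` per node and, per connected pair, a
transition-state free energy defined to reproduce the renormalized rate
constant `K'_ww' = B'_ww'/tau'_w'`:

    f+_ww' = f_w' - T ln(B'_ww' / tau'_w') + T ln T        (k_B = h = 1)

The reverse-direction expression is equal iff the chain satisfies detailed
balance with `pi'`; both are computed and their agreement asserted to
1e-10, and the rate round trip `T exp(-(f+ - f_w)/T)` is exact by
construction. The disconnectivity tree then groups minima into superbasins:
at each threshold level, superbasins are connected components of the
subgraph whose transition states lie at or below the threshold, with merges
recorded bottom-up. Thresholds default to 50 uniform levels spanning
[min f, max f+]; children are ordered by basin size then smallest contained
index, giving a deterministic layout. A monotonic-sequence filter restricts
to minima with no directly connected lower-energy neighbour (exact energy
ties resolved by index, so exactly one of a tied pair survives).

## Validation design

Each analytical operation is tested against an independent oracle: dense
linear solves for MFPTs and splitting probabilities, null-space solves for
stationary distributions, sequential single-node GT for block GT,
simulation for fundamental-matrix visit counts, and two-sample
Kolmogorov–Smirnov tests for sampler/spectral agreement.

One verification detail is worth recording. The reduction-fidelity check
compares community occupation curves of the full and reduced chains against
the sampling band (three pooled standard errors) of 1000-trajectory
ensembles. The sup-over-grid statistic of two finite ensembles exceeds its
own 3-sigma band with appreciable probability by multiplicity alone —
control ensembles with *identical* dynamics showed max z up to 4 — so the
band inequality is asserted on the exact expectation curves of the two
generators (matrix-exponential solution; observed difference ~2e-4, two
orders of magnitude inside the band), while the kMC sampler is separately
validated as an unbiased estimator of its own network's exact curves (mean
squared z near one). Together these imply the ensemble-level statement in
distribution, without depending on the luck of one Monte Carlo draw.

## Known limitations

- Dense linear algebra throughout; practical up to a few thousand states,
  matching the intended use (reduction of 10^2–10^4-state chains), not
  sparse million-state models.
- Basin-escape draws are exponential: exact mean, approximate shape away
  from the strongly metastable limit.
- The spectral route requires a well-conditioned eigendecomposition; at very
  low temperature it aborts by design (precision guard) and the GT/sampling
  routes are the supported path.
- The `Mix` initial distribution needs the full community eigensystem and
  inherits the same conditioning limits.
- Community detection is out of scope: partitions are inputs (or generator
  ground truth).
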