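# Methods

## Model

A demographic model is a sequence of epochs, each piecewise-constant in its
parameters: a vector of relative haploid deme sizes `s_i` and a square
scaled migration matrix `M`, valid from the epoch's `start_time` (backward
in time) to the next epoch's start; the last epoch extends to infinity.
Rates follow the island-model convention `M = 2Nm`: `M[i][j]` is the
expected number of haploid genes deme `i` receives from deme `j` per
generation, equivalently the scaled backward rate at which a lineage in `i`
traces its ancestry to `j`.

All computations run on the coalescent scale: one unit of time is `N_ref`
generations (`N_ref` = haploid genes per reference deme).  On that scale a
single lineage in deme `i` migrates to `j` at rate `M[i][j] / 2` and two
lineages in a deme of relative size `s` coalesce at rate `1 / s`.  This is
the unique scaling under which the lumped n-island chain's slowest decay
rate equals the printed `β` formula (checked by a unit test that compares
`beta_asymptote` with the numerically smallest eigenvalue of the lumped
generator), and it makes the recent-time limit of the same-deme IICR equal
to the local relative deme size.

### Two-lineage state space

For a sample of two lineages the structured coalescent collapses to an
absorbing CTMC over the unordered deme pairs `{i, j}` (`n(n+1)/2` transient
states for `n` demes) plus one absorbing "coalesced" state.  From `{i, i}`
the chain absorbs at rate `1/s_i` and each of the two lineages migrates at
its `M/2` rates; from `{i, j}` each lineage migrates independently.  The
coalescence time `T2` is the absorption time, hence phase-type within each
epoch, and

```
S(t) = P(T2 > t) = p(t) · 1,     f(t) = p(t) · a,
```

where `p(t)` is the transient distribution and `a` the vector of absorption
rates.  `IICR(t) = S(t)/f(t)`.

### Epoch boundaries, splits, admixture

Deme counts change between epochs only through a remap applied at the
boundary instant: each lineage in deme `d` moves to `remap[d]`, with
probability `p = 1` for a clean merge (a population split seen backward in
time) or `p < 1` for an admixture pulse (each lineage moves independently).
The remap acts on pair states as the tensor product of the two independent
single-lineage relocations; it never absorbs, so it is a stochastic matrix
between the two epochs' transient spaces.  Survival and density are
left-continuous at boundaries: the remap applies first, then the new
epoch's generator acts.

## Numerics

* Within an epoch, `p(t)` is propagated by the matrix exponential of the
  transient block.  An eigendecomposition fast path is used when available
  — it evaluates whole time grids in one vectorised expression — but it is
  trusted only after reproducing `scipy.linalg.expm` at a probe time to a
  relative tolerance of `1e-11`; otherwise the code falls back to one
  Padé/scaling-and-squaring exponential per grid point.  The contract is
  the tolerance, not the algorithm.
* `t = 0` is reported as the analytic limit (`s_i` for same-deme sampling,
  `+inf` for different-deme sampling) instead of evaluating `0/0`.
* Tiny negative probabilities from spectral roundoff are clipped at zero,
  and the total transient mass is capped at the mass that entered the
  epoch.
* If the sampled pair can never reach the absorbing state (disconnected
  demes), the exact and simulated paths raise by default; an
  `allow_infinite` flag instead returns the defective distribution
  (survival not tending to zero, `inf` simulated values), in which case the
  IICR is conditional on coalescence having a hazard at all.

## Simulation

`simulate_t2` simulates the absorbing chain directly: exponential waiting
times from the current state's total exit rate and categorical jumps.  A
waiting time that crosses the next epoch start is truncated at the
boundary, the remap is sampled, and the wait is redrawn under the new
generator — exact for piecewise-constant rates (memorylessness), no
thinning involved.  All replicates advance in lock-step and are grouped by
(epoch, state) so each round is a handful of vectorised draws; 10⁶
replicates of a 10-deme model take about a second.  Identical
`(model, sampling, n_rep, seed)` gives bit-identical output.

The draws are i.i.d. coalescence times of *unlinked* loci.  This emulates
the input that defines the IICR itself; it does **not** emulate a genome:
there is no recombination, no linkage between consecutive trees, no
mutation layer and no sequence-based inference step.  Passing tests
therefore validate the demographic calculation and the estimator, not the
behaviour of PSMC-style inference on finite genomes, whose own estimation
noise and time discretisation sit on top of everything modelled here.

`emit_ms_command` renders the model as a command line for Hudson's `ms`.
`ms` counts time in units of `4 N0` generations and migration as `4 N0 m`
with `N0` diploids per deme; identifying the haploid deme size `N = 2 N0`
gives `ms_time = t / 2` while the migration-matrix entries `M_ij = 2Nm =
4 N0 m` carry over unchanged.  The command is emitted as text only; the
simulator itself is cross-validated distributionally against msprime (a KS
test of msprime-drawn `T2` values against the exact survival function) in
the test suite.

## Estimation

The empirical IICR on a grid `t_1 < … < t_k` is

```
(1 − F̂(t_i)) / f̂(t_i),   f̂(t_i) = (F̂(t_{i+1}) − F̂(t_i)) / (t_{i+1} − t_i)
```

with `F̂` the ECDF.  Design choices:

* forward finite differences of the ECDF, no kernel smoothing — the bias is
  then a transparent bin-average effect (`f̂` estimates the mean density
  over the bin, not the density at `t_i`), which matters wherever the
  density decays appreciably within one bin;
* survival evaluated at the left bin edge, consistent with the bin the
  density lives on;
* empty bins yield NaN (flagged missing), never an error; the last grid
  point has no bin and is NaN;
* bins are considered reliable for accuracy statements when they hold at
  least 100 observations (an artifact convention, not a theorem);
* default grid: 64 log-spaced points on `[1e-3, 1e2]` coalescent time
  units — IICR dynamics span orders of magnitude, so log spacing is the
  default everywhere.

Because of the bin-average bias, fidelity tests compare the estimate with
the exact survival function pushed through the *same* discretisation
(`S(t_i)` over the exact bin-averaged density), which isolates Monte-Carlo
error; against the pointwise exact curve only an agreement up to
`O(bin width)` holds, and a median-deviation check covers that.

`compare_curves` interpolates both curves (log-log) onto a shared log grid
over the overlap of their ranges and returns the mean `|Δ log IICR|` —
symmetric, zero iff the curves agree on the grid, and insensitive to the
orders-of-magnitude span of IICR values.  There is no significance
calibration attached; it is a descriptive exclusion distance.

## Preset families

* **n-island**: `n` demes of size 1; total scaled immigration `M` per deme
  split evenly over the `n − 1` others.
* **Stepping stone** (1D/2D lattice, bounded by default, torus via a
  flag): each deme's total emigration `M` is split equally among its
  nearest neighbours, keeping per-deme immigrant counts comparable with an
  n-island of the same `M`; a `per_link` mode assigns rate `M` to every
  edge instead.  Bounded lattices are the default because edge and central
  demes are deliberately distinguishable.  Deme indexing is row-major.
* **Continent–island**: sizes `(ratio, 1)`; the island's scaled
  immigration is `M` and the continent's `M/ratio`, so the expected number
  of migrant genes is conserved across the exchange; a `symmetric` flag
  sets both scaled rates to `M`.
* **Asymmetric gene flow**: `make_asymmetric_model` takes the full
  migration matrix — every directed rate explicit, no symmetry assumed.
* **Population splits**: `add_population_split` appends an epoch whose
  remap merges the listed demes into a fresh ancestral deme; surviving
  demes keep their mutual rates and exchange with the ancestral deme at a
  configurable symmetric rate.

## Scaling

`ScalingConfig` holds the physical constants: haploid reference deme size
`N_ref` (default 500 genes), generation time (default 25 years) and a
mutation rate (default 2.5×10⁻⁸ per site per generation) carried as
metadata only, for labelling parity with sequence-based studies — nothing
here simulates sequences.  Scaling multiplies times by `N_ref`
(generations) and by the generation time (years), and sizes by `N_ref`
(haploid genes); the coalescent-scale arrays ride along on the curve so
descaling is bit-exact.  Sizes are reported as haploid gene counts; the
plotting helper offers a diploid display that divides by two and relabels.

## Problem sizes in the test suite

Distributional checks use 10⁵ replicates per model family (one-sample KS
against the exact survival function at the 5% critical value) and the
estimator-fidelity check uses 10⁶ replicates, matching the replicate count
used for the empirical curves this estimator is designed for.  Exact-curve
identities (closed form vs matrix exponential, split-model identity,
time-shift invariance) are asserted at `1e-10` relative on 64-point log
grids.

## Known limitations

* Sample size is fixed at two lineages; the IICR of `T_k` for `k > 2` is
  out of scope.
* Models are piecewise-constant in time and discrete in space; no
  continuous-space or selection models.
* The state space grows as `n(n+1)/2`; lattices beyond a few hundred demes
  make the dense matrix exponential expensive.
* The exclusion distance is descriptive; converting it into a calibrated
  test statistic (e.g. within an ABC framework) is left to the user.
* Very ancient plateau evaluation relies on floating-point survival values
  around `e^{-βt}`; at times far beyond the mixing time both `S` and `f`
  underflow together, and the implementation evaluates plateaus at times
  where they are still well-conditioned.
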