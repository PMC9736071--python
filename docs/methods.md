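# Methods

`tapspath` implements travelling-salesman automated path searching (TAPS):
an iterative scheme that refines a discretized transition path between two
metastable conformations toward the minimum free-energy path (MFEP), then
profiles the free energy along the found path by umbrella sampling and
WHAM.  This note records the model, the parameters that matter, the
numerical choices, and what the desk-scale benchmarks do and do not show.

## Path collective variables

A path is an ordered list of N node conformations.  Any configuration x
projects onto it through Gaussian weights w_i = exp(−λ d(x, node_i)²):

    s(x) = Σ_i i·w_i / Σ_i w_i,        z(x) = −(1/λ) ln Σ_i w_i,

with both sums over i = 1..N and

    λ = 2.3 (N−1) / Σ_i d(node_i, node_{i+1})².

Conventions adopted here (PCV conventions differ across the literature):

* **s is in node-index units 1..N**, not rescaled to [0,1].  Umbrella
  windows are spaced directly in these units (default gap 0.5).
* **z carries squared-distance units** because the exponent uses d².  In
  the sharp-weight limit z → min_i d², the squared distance to the nearest
  node; at the derived λ (which makes λ·gap² = 2.3 regardless of
  coordinate scale) z is a *soft* minimum and can be slightly negative
  when several nodes are close — this matters for convergence monitoring
  (below).
* λ is recomputed on every `Path` construction; supplying a stale value
  raises.  Since λ·gap² is scale-invariant, limit analyses
  (s → argmin d, z → min d²) use the explicit `lam_scale` argument rather
  than coordinate scaling.
* d is Euclidean in toy mode and align/compute-set RMSD in molecular mode:
  superpose on the alignment atom set only (proper Kabsch rotation,
  reflections excluded, unweighted), then take the RMS deviation over the
  separate compute set.  Splitting the sets keeps the rigid scaffold as
  the reference frame while measuring only the mobile region.

The convergence monitor is z̄(A | ref) = (1/N_A) Σ_i z(node_i of A | ref),
the mean departure of one path's nodes from a reference path.

## Sampling model

Configurational sampling uses Euler–Maruyama overdamped Langevin dynamics,

    x_{t+1} = x_t − D β ∇(U + U_bias) dt + √(2 D dt) ξ,

with β = 1 by default so that energies and free energies read in k_BT.
TAPS needs only equilibrium sampling in restrained ensembles, which
Brownian dynamics provides; inertial/thermostat machinery is out of scope.
A nominal "ns" maps to steps through `STEPS_PER_NS = 1e5` — a bookkeeping
constant, not physics — so the conventional per-umbrella budget of "2 ns"
is 2×10⁵ steps by default.  `dt` must satisfy the harmonic stability bound
D·β·k·dt < 2 against a per-potential stiffness estimate; the restraint's
contribution uses the mean node gap as the |ds/dx| scale (a locally tight
node pair steepens s only in a region the restrained walker does not
visit).

Bundled landscapes:

* **Müller–Brown** (standard coefficients).  At β = 1 the canonical
  energies (wells at −146.7, −108.2, −80.8; saddles at −72.2, −40.7) make
  this an effectively low-temperature surface — appropriate, since
  valley-floor relaxation is what the path search needs.  Sampler steps of
  dt = 1e−5 respect the ~6×10³ peak curvature.
* **Two-basin double well** U = a(x²−1)² + Δ·σ(x/w), σ the tanh smooth
  step (w = 0.1).  Because σ saturates well before |x| = 1, the stationary
  points stay pinned at ±1 and the configured Δ *is* the well offset to
  within 10⁻⁸ — a linear tilt would shift the minima and blur what "the
  configured offset" means.  Barrier from the lower well: a + Δ/2.
* A 2D extension (harmonic transverse confinement), a three-hole surface,
  harmonic wells, and a flat potential for null tests.

Restrained node sampling biases **only PCV-s** (½k_s(s−i)²) with the exact
chain-rule gradient of s; z is left free — the point of the hyperplane
sampling is to let the system relax orthogonally to the path.  On a flat
potential this means the perpendicular coordinates free-diffuse with
σ² = 2Dt; "the path does not move" is therefore only true within that
noise bound, which the tests use explicitly.

The targeted-dynamics initial-path generator pulls with a harmonic
restraint on the *distance to target* whose set-point shrinks linearly to
zero, then resamples the recorded frames uniformly in the set-point.
Equal steps in distance-to-target are not equal steps in arclength on a
curved route, so oversized spatial gaps are bridged afterwards with
additional recorded frames (the returned endpoints are always the exact
input conformations).

## The TAPS iteration

1. **Perpendicular sampling** at every interior node, with per-node seeds
   derived from a `SeedSequence` over (seed, iteration, node) so node
   order cannot affect reproducibility.  A diverging node run is kept as
   its own candidate with a warning rather than aborting the iteration.
2. **Candidate selection**: greedy density-peak medoids on the pooled
   samples — repeatedly take the sample with the most neighbours within
   `density_radius`, then suppress that neighbourhood.  Density peaks
   approximate the free-energy minima within the sampled hyperplanes,
   which is what makes the displaced path collapse onto the valley floor.
3. **Reordering**: shortest open tour from the fixed start to the fixed
   end through all candidates — exact Held–Karp dynamic programming up to
   12 interior nodes, nearest-neighbour seeding plus deterministic 2-opt
   beyond.  Ties break by node index.
4. **Reparametrization**: insert metric midpoints into gaps above
   d_max_factor·resolution, then delete — never an endpoint — the node
   whose removal least increases total length from gaps below
   d_min_factor·resolution, alternating at most 10 rounds.
5. **Convergence**: declared when z̄(current, previous) < tol for
   `convergence_window` (default 5) consecutive iterations, with tol
   defaulting to 1% of the initial path's mean squared gap.  The
   comparison is *signed*: once the new path lies inside the previous
   path's Gaussian tube, z̄ sits at a small negative value (soft-min
   property above), which is exactly the converged regime.

Two defaults were set from an explicit stability study on Müller–Brown
(straight 12-node chord between the two deep wells, k_s = 50,
400 samples/node recorded every 10 steps):

* `density_radius = 0.8 × target_resolution`.  At 0.5× the suppression
  step admits two candidates per resolution element; the TSP tour then
  zigzags through perpendicular sampling noise, the path length inflates,
  and midpoint insertion amplifies the node count iteration over
  iteration (observed: 12 → 35 nodes and z̄-to-reference drift).  At 0.8×
  one candidate per element survives and the loop is stable.
* `n_candidates` is frozen at the *initial* interior node count rather
  than tracking the current count.  The tracking variant couples into the
  same inflation feedback (more nodes → more candidates → longer, noisier
  tour → more insertions); the frozen variant held the node count at
  15–18 and the path within ~3% (z̄ relative to the initial mean squared
  gap) of an independent string-method reference over 30 iterations.

With these settings the restraint relaxation time (≈1/(D k_s (ds/dx)²) ≈
10⁻³ time units ≈ 100 steps) is well inside the per-node budget of 4000
steps, and the medoid jitter (≲0.02) keeps the z̄ noise floor below the
1% convergence tolerance.

## Free-energy profile

Umbrella windows are centered 1, 1+gap, …, N (default gap 0.5 s-units,
last center exactly N), each biased by ½k_umb(s−s_c)² (default k_umb = 20,
giving σ_s ≈ 0.22 and adjacent-window histogram overlap ≈ 0.25 on a flat
landscape — comfortably above the 0.05 diagnostic threshold; failing
pairs get a proposed midpoint center).  Windows start from the path node
nearest their center and discard the first 10% of samples as
equilibration.

WHAM iterates the standard self-consistent equations over bin
probabilities and per-window constants in log space (gauge fixed to
window 0) until max|Δg_k| < 1e−7 (max 10⁵ iterations).  Bins: 10 per unit
s by default; all-window-empty bins are masked, never imputed, and empty
runs of three or more bins separating occupied regions raise a
disconnected-histogram error since the window constants are then only
defined per island.

TS/IS identification takes the interior extrema of the profile with
topographic prominence ≥ 0.5 k_BT (scipy peak prominences), enforces
minimum/maximum alternation by discarding the lower-prominence violator,
and then adds a profile end as an end state unless an interior minimum
already flanks it — the sampled s-range usually extends past the physical
end states, and near s = 1 and s = N the s(x) mapping saturates, which
compresses probability into the edge bins and can fabricate shallow edge
extrema.  ΔG between two identified minima is the plain profile
difference f(b) − f(a) in k_BT, negative when b is more stable.

On the two-basin landscape the straight 8-node path spans [−1.3, 1.3] so
both wells are interior; the node layout is symmetric about the barrier,
so the ds/dx Jacobian contribution to f(s) is equal at the two wells and
cancels in ΔG.  With the default 2×10⁵ steps per window the configured
2 k_BT offset is recovered to ≈±0.15 across seeds.

## Reference oracle

`make_fixture("mueller_brown_mfep")` ships an independent reference MFEP:
zero-temperature string method (capped steepest descent with cubic-spline
equal-arclength redistribution, 101 nodes) followed by Newton polishing
restricted to the direction perpendicular to each node's central-difference
tangent, until every interior node satisfies |∇U_perp| < 10⁻³.  Minima and
saddles come from a dense-grid seeded Newton search on ∇U = 0, classified
by finite-difference Hessian eigenvalues and filtered by residual gradient
norm.  The oracle never calls the TAPS machinery.

## What the benchmarks show — and what they do not

The toy landscapes exercise every algorithmic component (projection
formulas, restrained sampling, candidate selection, reordering,
reparametrization, WHAM, state identification) under exactly known
ground truth.  They do not emulate molecular reality: no rugged
high-dimensional energy surface, no metric with alignment degeneracies,
no sampling bottlenecks requiring per-window reweighting diagnostics
beyond histogram overlap.  Passing them demonstrates correctness of the
machinery and internal consistency of the statistical estimators, not
transferability of any specific parameter default to a protein-sized
problem; for molecular systems k_s, the resolution band, and the window
stiffness must be chosen against the RMSD metric's scale.

## Problem sizes used in the shipped checks

Müller–Brown search: 12 initial nodes, 10 interior windows × 4000 steps
per iteration, convergence typically in 7–10 iterations (~40 k restrained
samples).  Umbrella profiles: 15–17 windows × 2×10⁵ steps.  Sampler
physics: 10⁵–2×10⁶ steps.  These sizes were chosen as the smallest at
which the statistical tolerances above hold with margin.

## Known limitations

* Analytic s-gradients (hence biased dynamics) exist for the Euclidean
  metric only; RMSD-metric paths support projection and z̄ monitoring but
  not restrained sampling.
* The perpendicular sampler does not cap |z|; on landscapes with distant
  competing basins at the same s a node could in principle migrate to a
  parallel valley.  Finding multiple parallel MFEPs is explicitly out of
  scope.
* 2-opt beyond 12 interior nodes is a local heuristic; optimality is
  exact only in the Held–Karp regime (the shipped configurations stay
  within it after reparametrization).
* WHAM returns no error bars; a block bootstrap over window series is the
  recommended add-on if uncertainties are needed.
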