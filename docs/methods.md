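# Methods

This note documents the model, the numerical choices, the measurement
protocols and the synthetic fixtures implemented in `vortexmelt`, and
the limits of what desk-scale runs can show.

## Model

The package simulates a generalized Toner–Tu continuum model for the
velocity field **u**(x, t) of a dense active suspension (bacterial or
spermatozoan) in two dimensions, in nondimensional form:

    ∂t u + λ u·∇u = −∇p − (1 + Δ)² u − (α + β|u|²) u,   ∇·u = 0.

* **λ** (`lambda_adv`) — active advection, modelling nematic active
  stresses; large λ corresponds to strong extensile stresses.
* **α** (`alpha`) — activity. For α < 0 the Swift–Hohenberg operator
  (1 + Δ)² makes plane waves with |k| near 1 linearly unstable:
  σ(k) = −(1 − k²)² − α, maximal at k = 1 (wavelength 2π).
* **β** (`beta`) — cubic saturation; β = 0.01 throughout (it can be
  scaled out).

Depending on (λ, α), small doubly periodic domains settle into a
stationary square flow lattice (λ ≪ 1), spatiotemporally chaotic
active turbulence (AT), or an active vortex lattice (AVL): a triangular
crystal of same-sign vortices that forms after a turbulent transient
through spontaneous breaking of the ± polarity symmetry.

The solver integrates the equivalent vorticity form (ω = ∇×u), which
eliminates the pressure:

    ∂t ω + λ u·∇ω = −(1 + Δ)² ω − α ω − β ∇×(|u|²u),
    d⟨u⟩/dt = −(1 + α)⟨u⟩ − β ⟨|u|²u⟩,

with the spatial-mean velocity ⟨u⟩ (the k = 0 mode, invisible to ω)
integrated alongside.

## Numerics

* **Spatial discretization.** Fourier pseudo-spectral on an N×N grid of
  a doubly periodic square (optionally rectangular for lattice-identity
  fixtures) of edge L. The state is the `rfft2` half-spectrum, so
  Hermitian symmetry (real ω) is structural. Nyquist modes are pinned
  to zero. Convention: ω = ∂x u_y − ∂y u_x, u = (∂y ψ, −∂x ψ) with
  Δψ = −ω; the velocity is recovered spectrally and its discrete
  divergence vanishes to round-off.
* **Dealiasing.** The quadratic (advection) and cubic terms are
  evaluated on a 2N grid (2× zero padding), which removes aliasing
  exactly for a cubic nonlinearity (the usual 2/3 rule is exact only
  for quadratic ones).
* **Time stepping.** Classical RK4 combined with an integrating factor
  that propagates the entire linear operator −(1 − k²)² − α (and
  −(1 + α) for ⟨u⟩) exactly; only the advective and cubic terms are
  explicit. A zero field is therefore an exact fixed point and a single
  seeded mode grows at exactly exp(σ(k) t) up to nonlinear corrections.
* **Reality constraint.** In the rfft2 layout the ky = 0 column stores
  both ±kx entries, which must be complex conjugates for ω to be real.
  The FFT guarantees that only to round-off, and the non-Hermitian
  defect lives in a subspace the physical-space nonlinear terms never
  touch while the integrating factor amplifies it at σ(k) > 0 — from a
  1e−16 seed it reaches order one after t ≈ 95 (ln 10³³ / σ_max) and
  silently corrupts any long run. The solver therefore projects the
  constraint back (conjugate-averaging that column) every step; the
  projection is exact, cost-free, and verified by a regression test.
* **Stability guard.** The advection operator λu·∇ has eigenvalues
  iλ(u·k), so RK4's imaginary-axis bound requires
  |λ|·max|u|·dt·kmax < 2.83, i.e. max(1, |λ|)·max|u|·dt·N/L < 0.90.
  The solver aborts — keeping the last finite snapshot and the partial
  energy series — when that product exceeds 0.85, and the experiment
  layer resumes from the snapshot with dt/2 (`run_resilient`), so rare
  velocity spikes (close vortex encounters) cost a halved step only
  locally instead of pricing the whole run at the worst case.
* **Initial conditions.** Band-limited white noise: Gaussian spectrum
  restricted to |k| ≤ 2 (covering the unstable shell), rescaled to an
  rms vorticity of 0.5 by default, zero mean flow. Fully reproducible
  from a single integer seed.
* **Upscaling.** A converged field can be tiled 2×2 (or 8×8) onto a
  domain of 2L (8L), with Hermitian spectral noise of radial amplitude
  A(k) ∝ k·exp(−(k − 4)²) added to decorrelate the copies. The profile
  peaks at scales smaller than the vortex scale so individual vortices
  survive; the default noise rms is 10⁻³ of the rms vorticity.

## Crystalline-order diagnostics

* **Vortex detection.** Cores are periodic local maxima of |ω|
  exceeding 0.2 × max|ω| (per field), merged within a minimum
  separation of π (half the preferred wavelength) keeping the stronger
  core, with parabolic sub-grid refinement; polarity is the sign of ω
  at the core. Validated against synthetic Gaussian-vortex fields with
  exact ground truth (recall = precision = 1 for well-separated cores).
* **Periodic Voronoi adjacency.** 3×3 image replication around the
  torus, `scipy.spatial.Voronoi`, adjacency from ridges between cells.
  The tessellation runs on exact coordinates: qhull itself merges
  exactly cocircular configurations, so a perfect square lattice keeps
  its exact coordination 4 (diagonal cells meet only in a point), while
  any generic point set yields the full Delaunay graph, for which mean
  coordination is exactly 6 on the torus and the topological charge
  Σ(6 − N(i)) vanishes. A deterministic 10⁻⁹-of-spacing jitter is
  applied only if qhull fails outright. Caveat: adjacency is reported
  as a simple graph, so point sets sparse enough for a pair to be
  adjacent through two images (never the case for a vortex lattice)
  lose multi-edges.
* **Bond-orientational order.** ψ_i = Σ_j exp(6iθ_ij)/N(i) over
  Voronoi neighbors, θ_ij against the x-axis with minimum-image bonds;
  deviation angle θ̂_i = arg ψ_i − ⟨arg ψ⟩. |ψ_i| = 1 exactly on an
  equilateral triangular lattice; ψ_i = 0 on a square lattice.
  Because √3/2 is irrational, an exactly equilateral lattice never fits
  a *square* torus; exact-identity tests therefore use a commensurate
  rectangular torus, while square-torus fixtures carry a reported ≲4%
  row compression.
* **Orientational correlation.** G6(r) = ⟨ψ_i*ψ_j δ(r−r_ij)⟩ /
  ⟨δ(r−r_ij)⟩, computed over all pairs with minimum-image distances,
  binned (default bin width a/4) up to L/2. Phase labels follow the
  standard decay signatures — constant → solid, algebraic → hexatic,
  exponential → liquid — decided by small-sample-corrected AIC over
  fits of the three models to log|G6|, with the full fit report
  attached so borderline calls are auditable. At least 10 occupied bins
  spanning a decade in r are required, otherwise "undetermined".
* **Tracking and dynamic Lindemann parameter.** Mutual-nearest-neighbor
  matching between consecutive snapshots within max_disp (default a/2),
  positions unwrapped across the boundaries; only full-window survivors
  enter. γ_L(t) = ⟨(Δx_i − Δx_j)²⟩ / (2a²) over Voronoi-neighbor pairs
  fixed at the window start — the standard two-dimensional practice for
  "neighboring" cores — optionally averaged over consecutive windows
  with the across-window spread reported. Oracles: rigid motion gives
  γ_L ≡ 0; iid positional jitter of std s per component plateaus at
  4s²/a²; independent random walks grow linearly.

## Dynamical states and transitions on small domains

The energy density E(t) = ⟨|u|²⟩/2 distinguishes the states: the packed
AVL has high E and small fluctuations, AT lower E and large
fluctuations. Near the coexistence boundary the whole domain switches
intermittently between the two, making the stationary PDF of E bimodal.
The PDF is estimated by Freedman–Diaconis histogram (smoothed with a
2-bin Gaussian for peak finding; peak prominence 5% of the maximum;
boundary bins checked explicitly). When exactly two peaks exist, E_min
is the density minimum between them and the order parameter of the
AVL–AT transition is T_AVL/T_total = P(E > E_min), with a standard
deviation over five contiguous segments of the series (the large-scale
study re-ran five independent simulations instead; both are supported,
the segment variant is the desk-scale default). Unimodal runs are
labelled by their lattice order (|ψ6|, polarity balance) and stationarity.
Hysteresis scans run a parameter ladder in both directions, each value
initialized from the previous value's final state, so bistable dynamics
with memory open a loop.

Default burn-in before PDF estimation is t < 200 (the reference
protocol discards ~5000 time units on its much longer runs; scaled
down, configurable).

## Transient-duration statistics

A uniform AVL has formed when the count of strong vortices of one sign
reaches 93% of the capacity floor(2L²/(√3 a²)) of an ideal triangular
lattice, with the spacing a taken from the radial spectral peak of a
converged lattice (first Bragg ring: a = 4π/(√3 k_peak)). Because
vortex lifetimes in active turbulence are approximately exponential,
the transient time T — the maximum survival time of the losing
polarity's vortices, assuming independent decays — follows

    P(T) = (δ/τ)(1 − e^{−T/τ})^{δ−1} e^{−T/τ},

exactly the max-of-δ-exponentials law for integer δ. Fitting is by
maximum likelihood on raw durations (binning-free and efficient;
histogram least squares would differ at the percent level), started
from moment-matched values, with observed-information standard errors
and a min–max band over five disjoint subsamples. The MLE was checked
to be unbiased at these parameter values (20 seeds, n = 10⁴ each) and
equivariant under time rescaling.

## Synthetic fixtures

Generators provide every downstream stage with inputs of known ground
truth, so accuracy tests never depend on large-scale PDE runs:
triangular lattices with controllable jitter, vacancies and polarity
assignment (ideal adjacency recorded); signed Gaussian-blob vorticity
fields (positions/polarities attached); trajectory ensembles with
exactly prescribed displacement statistics (rigid / jitter / walk);
and Poisson point patterns as the liquid null. What they deliberately
do not emulate: vortex-core shape fluctuations, correlated lifetimes,
interactions between defects — so passing fixture tests validates the
measurement chain, not the hydrodynamics; the solver-based tests cover
the latter at desk scale.

## Desk-scale study conditions

The reference study ran domains up to L = 1000π on 4096²–8192² grids
(with 256²–1024² for the L = 20π state diagram and 256² for the
L = 10π transient ensembles). This package targets single-CPU desk
scale — N = 64 grids, dt set by the λ-aware advective bound — and at
that resolution the state diagram is measurably shifted: near the
AVL/AT boundary (λ = 7–8, α = −0.8, where the reference resolves
crystallization with dx = 0.12–0.25) random initial conditions remain
in mixed-polarity turbulence beyond desk time horizons (verified up to
t = 600 at dx = 0.49 and t = 400 at dx = 0.245), and a prepared
single-polarity lattice melts. Deep in the crystal regime the
phenomenology is fully present: at the reference solid-phase
parameters (λ = 15, α = −0.9) a random start on L = 20π, N = 64 breaks
the polarity symmetry through a turbulent transient within tens of
time units and crystallizes into a defect-free single-polarity
triangular lattice with mean |ψ6| > 0.9 (≈23 vortices at spacing
≈13).

The shipped tests and the reproduction script therefore use:

* dispersion/fixed-point oracles: N = 16–64, seconds;
* crystallization, transient durations and the 93% rule: the
  solid-phase parameters (λ = 15, α = −0.9) on L = 20π, N = 64,
  dt = 0.004, ensembles of a handful of runs (the reference used 10⁴);
  the capacity of the 93% rule is the vortex count of a converged
  reference lattice at the same parameters, since desk lattices pack
  slightly below the ideal 2L²/(√3a²) (torus commensurability), and a
  crossing must be sustained over three consecutive checks because a
  freshly seeded noise field over-detects cores for the first few time
  units;
* AT (λ = 3, α = −0.8) and the square flow-lattice (λ = 0.1,
  α = −0.2) at their reference parameters, N = 64;
* the boundary-adjacent protocols (AVL at λ = 8, coexistence at
  λ = 5.6, transient ensembles at λ = 7, all α = −0.8) are run as
  specified at desk sizes and their checks document the shifted
  boundary by failing — a faithful negative result, not a skipped one.

## Known limitations

* The AVL/AT boundary at desk resolution sits at noticeably larger λ
  (and more negative α) than the reference diagram; all
  boundary-adjacent reproductions (coexistence bimodality, the printed
  (τ, δ) transient fits at λ = 7) are out of desk reach and their
  acceptance checks fail by design. The solid-phase reproductions
  stand in for the physics.
* Desk-scale ensembles (a handful of runs) make δ of the transient law
  uncertain at the tens-of-percent level; the monotone growth of δ
  with L across 10π/20π/40π demands ensemble budgets (hundreds of runs
  at increasing L) beyond the test suite's scope.
* Phase classification of |G6| is by-eye in the reference work; the AIC
  rule here is deterministic but can disagree near the hexatic/liquid
  boundary, and the fit range matters — the report carries both.
* The melting order parameter uses the per-field half-max rule; for
  fields whose smoothed maximum is itself depressed (deep in the melt)
  the area fraction saturates rather than reaching 0.
* No GPU, no adaptive stepping (the resume-at-dt/2 recovery is a
  failure protocol, not step control), square (or fixture-rectangular)
  periodic domains only.
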