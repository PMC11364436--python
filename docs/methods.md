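# Methods

## Model

### Grid-cell rate map

A cell's rate is the product of three cosine gratings rotated by 60°:

    G(x, y) = (Amax/8) ∏_{k=0}^{2} (1 + cos[k_k · (r − b)]),
    k_k = a (sin(πk/3 + γ), cos(πk/3 + γ)),   a = 4π/(√3 s).

The wavevector magnitude `a` is fixed by requiring the firing-field centers
to form a triangular lattice of spacing `s`; the peak rate at a field center
is then exactly `Amax` and the average over one lattice cell is `5·Amax/32`
(only the zero-frequency part of the triple product survives, because
`k_0 − k_1 + k_2 = 0` identically). Defaults: `Amax = 8 spk/s`, `s = 30 cm`,
`γ = 0`, `N = 1024` cells per population.

Phase offsets are stored in *square* coordinates `(x̂, ŷ) ∈ [0,1)²` and
mapped to the unit rhombus (the lattice's fundamental domain) by the shear
`(x̂ + ŷ/2, √3 ŷ/2)`; the Cartesian offset is `b = s · rhombus(x̂, ŷ)`.
Uniform square coordinates map to the uniform distribution on the rhombus,
which is the distribution that makes the population's spatial sampling
unbiased. Clustered phases draw each square axis independently from a von
Mises distribution (center `2π μs`, concentration `κs`); whether clustering
is applied in square or rhombus axes is not empirically constrained — the
square-axis convention is used because the clustering estimator also works
in square axes, and the choice moves fitted κ̂s only marginally.

### Trajectories

All walks move at constant speed `v = 10 cm/s` with time step
`Δt = 0.01 s` unless stated otherwise.

* *Star-like walk*: `Nθ = 360` radial segments of `r_max = 300 cm` (ten grid
  spacings) from a common origin, directions 0°…359°, teleporting back to
  the origin between segments. Path hexasymmetry is zero by construction
  (`< 10⁻¹⁰` numerically).
* *Piecewise-linear walk*: the same segments laid end to end in uniformly
  random order without replacement; continuous, no teleports.
* *Random walk*: heading diffuses as a Wiener process,
  `θ_{t+Δt} = θ_t + σθ √Δt 𝒩(0,1)` with tortuosity `σθ = 0.5 rad/s^{1/2}`
  (heading SD ≈ 0.5 rad ≈ 29° after 1 s); default duration 9000 s
  (M = 9·10⁵ steps). Step m displaces along θ_m; each step is its own
  linear segment for averaging purposes.

Bounded square/circular arenas are supported by rejection sampling of
heading increments, multiplying the working tortuosity by 1.1 after every
50 consecutive rejections and resetting it on acceptance (prevents the walk
from sticking at boundaries). The initial heading is uniform on [0, 2π) and
walks start at the arena center — symmetric defaults where no empirical
constraint exists. With a huge arena the bounded generator reproduces the
unbounded one draw for draw.

### Mechanisms

* **Conjunctive HD tuning** multiplies each conjunctive cell's rate by
  `h(θ) = exp(κc cos(θ − μc))/I0(κc)`, whose circular mean is 1 — tuning
  redistributes activity over directions without changing the time average.
  `round(pc N)` cells are conjunctive; `μc = (π/3)k + η`, `k` uniform on
  {0..5}, `η ~ 𝒩(0, σc²)`. Ideal: κc = 50 rad⁻² (width 1/√κc ≈ 8.1°),
  σc = 0, pc = 1; realistic: κc = 4 rad⁻², σc = 3°, pc = 1/3.
* **Adaptation** integrates `τr da/dt = drive − a` by forward Euler at the
  trajectory's Δt and outputs `G^r = max(G − w_r a, 0)`. The drive is the
  *adapted* output rate by default; this choice (over driving with the raw
  rate) is what yields the reference single-cell attenuations of ≈24%
  (axis-aligned run through field centers, inter-field interval
  s/v = 3 s = τr) and ≈18% (30°-misaligned, interval √3·s/v). A
  `drive="raw"` switch exposes the alternative. `a(0) = 0`; on star-like
  walks the adaptation variable resets at every teleport unless
  `carry_over=True`. Ideal: τr = 3 s, w_r = 1; weaker: 1.5 s, 0.5. The
  stability guard requires Δt < τr (error if violated, warning above τr/10).
* **Clustering** needs no activity machinery — only the phase sampler.
  Ideal κs = 10, realistic κs = 0.1, center (0,0).

### Hexasymmetry statistics

With per-step (or per-segment) mean activities Ām at directions θm,

    H = |(1/M) Σ Ām e^{−6iθm}|,   Ã0 = (1/M) Σ Ām,   |T6| = |(1/M) Σ e^{−6iθm}|.

A pure hexadirectional sinusoid of amplitude 2c gives H = c; H ≤ Ã0 always.
The apparent orientation is `−arg(Ã6)/6` mod 60°, reported in degrees; it is
undefined (signalled) when |Ã6| is at floating-point scale relative to the
mean activity. The path contribution `|T6|·Ã0` is the H an untuned
population would inherit from the walk; per condition, H across
realizations is compared against the contribution across realizations with
a two-sided Mann-Whitney U test (sidedness configurable; the contribution
group is passed first, so complete separation appears as U = 0).

Three legacy fMRI metrics are provided for comparison: the two-stage GLM
(orientation from quadrature regressors on the first half of the data,
amplitude on the second, H = β/2, possibly negative), the same with a ±1
aligned/misaligned (15° bins mod 60°) regressor, and circular-linear
regression `H = √(β1²+β2²)/2` with circular-shift surrogate z-scores
(uniform shifts for random walks, whole-segment shifts for star-like and
piecewise walks; 300 surrogates by default). All regressions include an
intercept — direction-resolved activity has a large mean offset that would
otherwise bias the amplitude.

## Analytic evaluators

### Segment integrals

The average of G along a ray at angle ψ between radii r0 and r1 integrates
in closed form: expanding the triple product gives one constant, three
single-grating, six pairwise and four triple-sum terms, each of the form
`∫cos(d r − e) dr = sin(d r − e)/d` with `d` the projected (summed)
wavevector and `e` the corresponding phase constant. Every vanishing
projection (`|d| < 10⁻¹² a`, a float-safe relative threshold verified by
continuity tests) is replaced by its limit `r cos(e)`. Degenerate branches
are not exotic: on a star-like walk they fire at every multiple of 30°, and
the combination `d_0 − d_1 + d_2 = 0` is degenerate at *every* direction —
it carries the `5/32` spatial mean. Segments not through the origin are
shifted there by absorbing the start point into the phase constants.
Agreement with adaptive quadrature is ~10⁻¹³ relative (asserted < 10⁻⁹ over
randomized cases, < 10⁻⁸ in the acceptance property).

HD tuning multiplies a segment's mean by h(ψ) outside the integral;
adaptation has no closed form (history dependence), so the API forces the
numeric route in that case. The numeric route evaluates the rate at each
step's midpoint (composite midpoint rule, O(Δt²)); at Δt = 0.01 s it agrees
with the analytic route to ~10⁻⁶ relative in H. A numba kernel fuses rate
evaluation and Euler integration for the adaptation path so full-size runs
(10⁶ steps × 1024 cells) stay within minutes on one CPU.

### Expected path hexasymmetry

Heading differences after m steps are wrapped-normal with variance
`m σθ² Δt`, so `E cos 6(θ_{m1} − θ_{m2}) = e^{−α|m1−m2|}` with
`α = 18 σθ² Δt`, and

    E(|T6|²) = (1/M²) (M + Σ_{m1≠m2} e^{−α|m1−m2|})

has a geometric-series closed form (used above M = 10⁴; the explicit double
sum below, and both agree to 10⁻¹² where they overlap). √E(|T6|²) is an
upper bound on E|T6| (Jensen) and a tight one in the Rayleigh regime
(Monte-Carlo means sit between 0.8× and 1× the bound for Mα ≫ 1).
Simplified regimes: 1/√M for α ≫ 1 (α = 1 at σθ ≈ 2.36 for Δt = 0.01 s),
`√[(1 + 2/(e^α−1))/M]` for Mα ≫ 1, and `(1/√M)/(3σθ√Δt)` for α ≪ 1, which
yields the equivalent-step factor `ΔM = (σA² ΔtA)/(σB² ΔtB)` for matching
the expected path hexasymmetry of two walks (e.g. ΔM = 4 for σA = 1 vs
σB = 0.5 at equal Δt). For the default random walk (M = 9·10⁵, σθ = 0.5),
√E(|T6|²) ≈ 0.007, i.e. a path contribution of ~0.7% of Ã0.

## Voxel phase fields

A voxel is an n³ lattice (default 200³ sites, 15 µm apart = 3×3×3 mm³).
Per phase axis, a unit-modulus complex field with iid uniform angles is
convolved — real and imaginary parts separately — with a spatial kernel,
and the argument of the result is the correlated phase angle. Convolution
is circular (spectral multiplication); wrap-around boundaries avoid the
edge artifacts that zero padding would inject into κ̂s (boundary handling
is otherwise unconstrained). Translation-invariant smoothing leaves the
marginal uniform. Kernels: none; isotropic Gaussian (σ = 30 µm, truncated
at 4σ); "grid-like" — Gaussian bumps (σ = 30 µm) on an FCC-like lattice
with 300 µm nearest-neighbor (in-plane peak) separation, truncated at
1.6× the peak spacing. The grid-like geometry beyond the 300 µm separation
is a package construction: its observable signature is the dip near 300 µm
in the pairwise phase-distance curve, which the tests assert.

Pairwise curves sample random site pairs (default 10⁶; per-bin SE at the
default is ≲0.002 in phase-distance units, scale up for smoother curves),
bin anatomical distance on [10, 500] µm (50 bins), and average the toroidal
rhombus phase distance (minimum over the 3×3 rhombus translates).

κ̂s fits a von Mises concentration per axis to `2π x̂` by maximum likelihood
(mean-resultant-length inversion `I1(κ)/I0(κ) = R̄`, solved by bracketed
root finding) and averages the two axes. MLE and moment matching coincide
for this one-parameter family. The estimator has a finite-sample floor:
uniform phases give `E κ̂s ≈ √(π/N)` (≈0.05 at N = 10³, the reference value
for voxel-scale cell counts), so fitted concentrations must always be read
against the floor for the N at hand. Subsampling curves κ̂s(N) decrease
toward zero for uncorrelated fields and saturate at the full-field value
when a kernel imposes real clustering.

One known discrepancy: the full-field κ̂s of the 200³ voxel under the 30 µm
Gaussian kernel is ≈0.008 in expectation (realization SD ≈25%; 0.0055 at
the test's seed), whereas the reference value for that configuration is
0.014. The no-kernel floor (≈0.001 at n = 200) and the N = 10³ subsample
floor (≈0.05) both reproduce, so the fitting machinery is consistent; the
gap points at an unstated detail of the reference kernel (width convention
or truncation). The corresponding test is left asserting the reference
value and currently fails; see the repository's test output.

## Condition sweeps

`runner` expands a base configuration into the 18 mechanism × walk × preset
conditions, derives per-realization seeds from the condition seed by a
counter-based scheme (SeedSequence over (master, index)), and emits one row
per realization plus a Mann-Whitney summary per condition. Clustered-phase
piecewise/random conditions are annotated as path-subsampling artifacts:
with near-coincident fields, only segments crossing the shared fields carry
activity, and that subsample of directions has nonzero hexasymmetry even
when the full walk has none — an apparent H that decays as 1/M and is not a
neural effect.

The bundled significance-pattern test runs the grid at a reduced scale
chosen for test-time statistical power (256 cells, 120 directions, 1200 s
random walks, 20 realizations): mechanism-driven separations there are
order-of-magnitude and survive the reduction, while the two random-walk
conditions whose H is dominated by the path term (realistic conjunctive
tuning — H_neural ≈ 5.5 spk/s at N = 1024, *below* the ≈8 spk/s path
contribution even at M = 9·10⁵; and ideal clustering, a subsampling
artifact) are expected non-significant at this sample size and asserted as
such.

## Limitations

* No neural→BOLD forward model: H is in spikes/s; mapping to fMRI signal
  change is outside scope.
* Single grid module per population (one spacing/orientation); no
  field-to-field rate variability; constant running speed.
* The synthetic walks idealize real navigation (no pauses, no speed
  modulation, perfect direction coverage in star/piecewise walks), so
  passing tests bound mechanism behavior under clean sampling, not under
  realistic human paths.
* Forward-Euler adaptation is first-order; Δt ≤ τr/10 keeps the worked
  attenuation values stable to well under a percentage point.
* The voxel model places cells on a regular grating with
  translation-invariant correlations — no anatomical gradients, module
  boundaries, or realistic EC geometry.
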