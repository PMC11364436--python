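# gridhex

Simulation and analysis of **hexadirectional modulation** in grid-cell
population activity.

Entorhinal grid cells fire on the vertices of a triangular lattice. fMRI
studies infer their presence indirectly from a six-fold (60°-periodic)
modulation of entorhinal activity as a function of a subject's movement
direction — "macroscopic grid-like representations". `gridhex` is a toolkit
for the computational question behind that measure: *under which mechanisms
does the summed activity of many grid cells actually become hexadirectionally
modulated, and how much of the observed modulation is inherited from the
navigation path itself?* It is aimed at computational neuroscientists and at
designers of fMRI/iEEG navigation experiments.

Three candidate mechanisms are implemented on top of a common firing-rate
model `G(x,y) = (Amax/8) ∏k (1 + cos[k_k·(r − b)])` (wavevectors `k_k` of
magnitude `4π/(√3 s)` rotated 60° apart; spacing `s`, phase offset `b`):

* **conjunctive grid × head-direction tuning** — each cell's rate is
  multiplied by a von Mises factor `h(θ) = e^{κc cos(θ−μc)}/I0(κc)` with
  preferred directions on the grid axes (jitter σc, conjunctive fraction pc);
* **repetition suppression** — subtractive firing-rate adaptation
  `G^r = max(G − w_r a, 0)`, `τ_r da/dt = G^r − a`, which suppresses aligned
  runs (fields arrive every `s/v` seconds) more than misaligned ones;
* **structure–function mapping** — phase offsets clustered on the unit
  rhombus (von Mises concentration κs per axis), emulating anatomical
  clustering of similar phases inside a voxel.

The hexasymmetry of direction-resolved population activity is measured as
the magnitude of its sixth circular Fourier harmonic,

    H = | (1/M) Σm  Ām e^{−6iθm} |        [spk/s]

and compared against the *path hexasymmetry* `|T6| = |(1/M) Σ e^{−6iθm}|` of
the trajectory itself: `|T6|·Ã0` is the modulation a completely untuned
population would inherit from the walk. Exact closed-form line integrals of
the rate along linear path segments serve as a fast evaluator and as an
oracle for the numeric pipeline, and `E(|T6|²)` of a correlated random walk
has an analytic closed form used for experiment design. A voxel module
simulates 3-D grid-phase topographies (optionally smoothed by Gaussian or
grid-like spatial kernels) and estimates the phase-clustering concentration
κ̂s an fMRI voxel would exhibit.

## Worked example

1024 cells with uniform phases, ideal conjunctive tuning (κc = 50 rad⁻²,
σc = 0, pc = 1), on a star-like walk of 360 × 300 cm radial segments:

```python
import gridhex as gx
from gridhex import hexmetrics
from gridhex.hypotheses import ConjunctiveParams, assign_hd_preferences

pop  = gx.GridPopulation(phases=gx.sample_phases(1024, seed=0))
hd   = assign_hd_preferences(1024, p_c=1.0, sigma_c=0.0, seed=1)
traj = gx.star_walk(n_angles=360, r_max=300.0, v=10.0, dt=0.01)
prof = gx.population_activity(traj, pop,
                              conjunctive=ConjunctiveParams(kappa_c=50.0),
                              hd_assignment=hd)
res = hexmetrics.hex_result(prof)
print(f"A0 = {res.A0:.1f} spk/s")
print(f"H  = {res.H:.1f} spk/s")
print(f"|T6| = {res.T6:.2e}")
print(f"orientation = {res.orientation:.2f} deg")
```

prints

```
A0 = 1286.4 spk/s
H  = 896.8 spk/s
|T6| = 6.98e-17
orientation = 0.04 deg
```

`A0` is the time-averaged population rate — close to the lattice average
`N·5·Amax/32 = 1280 spk/s`, since the star walk samples directions evenly.
`H` is the hexasymmetry: sharp axis-aligned tuning turns ~70% of the mean
rate into a six-fold modulation. `|T6| ≈ 0` confirms the walk itself carries
no hexasymmetry, so `H` is entirely neural; the apparent orientation sits on
a grid axis (0° mod 60°). Replacing the tuning with ideal adaptation shifts
the orientation to 30° (misaligned runs survive suppression better), and a
plain population with clustered phases produces sharp peaks instead of a
sinusoid — the three mechanisms are distinguishable in both size and shape.

A CLI mirrors the library for shell use, e.g.

```sh
gridhex hexsym --hypothesis repsup --trajectory star --realizations 20
gridhex theory --sigma-theta 0.5 --m-max 1000000     # path-hex theory curves
gridhex voxel --n 64 --kernel gaussian --sigma 30    # -> kappa_s=0.03515
gridhex trajectory random --T 900 --out walk.tsv
gridhex compare-metrics --trajectory star            # legacy fMRI metrics
```

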