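# Methods

## Acoustic model

The simulator treats ultrasound image formation as deterministic ray casting
through a scalar attenuation field δ(x) ≥ 0 sampled on a regular grid with
physical spacing. Three kernels drive the image, all normalised by the
volume-wide maximum M = max δ:

* reflection toward the probe, R = max(0, **d**·∇δ/‖∇δ‖)·(‖∇δ‖/2M)ⁿ;
* interface transmittance, t = 1 − (‖∇δ‖/2M)²;
* depth attenuation, I(L)/I₀ = exp(−∫₀ᴸ (‖∇δ‖/2M)² ds) along the beam.

For media described by density and sound speed the classical impedance
kernels are provided instead: Q = ρV, specular K = ((Q₂−Q₁)/(Q₂+Q₁))², and
the diffuse lobe cosⁿθ·K. The exponent n (default 1) controls how sharply
reflectance falls off with incidence angle and hence how much interface
detail survives into the image.

Assumptions and deliberate simplifications: no frequency-dependent
attenuation, no speckle or interference physics, no RF-signal simulation,
and linear-array geometry only (parallel beams; no sector scan conversion).
The transmittance keeps its squared normalised-gradient term for every
reflection exponent n; generalising that exponent alongside n would be a
modelling choice the underlying formulation does not pin down, so the
squared form is the shipped behaviour for all n.

Sign convention: the cosine factor **d**·∇δ/‖∇δ‖ is clamped at zero, so
gradients facing away from the probe contribute no echo. ∇δ below 1e-12 in
magnitude is treated as exactly zero, avoiding a 0/0 in the cosine. M is
global to the volume and cached once; a per-neighbourhood maximum would make
reflection strength depend on position in a way that is harder to reason
about and to test.

## Discretisation

Gradients are central differences scaled by the physical spacing in the
interior and one-sided differences on boundary faces (zero padding would
fabricate interfaces at the volume edge). Central differences are exact for
linear fields, which the test suite exploits with ramp phantoms. Off-grid
values of ∇δ are obtained by trilinear interpolation of the per-voxel
gradient field. The attenuation integral uses the midpoint rule at the ray
step λ, with the final partial step shortened to land exactly on the
requested depth; on smooth phantoms the result at step λ and λ/10 agrees
within 1 %, and on constant-gradient ramps it matches the closed form
exp(−(g/2M)²·L) to high precision.

## Echo compositing and gray mapping

The per-sample echo is `I/I₀ · Π t · R`: the depth-attenuated beam, further
reduced by the transmittance of every interface already crossed, reflected
by the local kernel. This compositing is standard ray-cast ultrasound
practice; each factor is computed by the kernels above. Gray mapping is log
compression `clamp(round(scale·log(1 + gain·echo)), 0, 255)` with defaults
gain = 1000, scale = 40, chosen once so that echoes of order 0.1–0.5 span
the upper gray range while silence maps to 0. After mapping, any sample
whose accumulated attenuation ratio is below the shadow threshold (default
0.92) is overwritten with the shadow floor gray (default 50). The renderer
returns the boolean shadow mask alongside the image, because log mapping
can land on the floor value by coincidence and the rule would otherwise be
untestable.

## Synthetic phantoms

`PhantomSpec` builds test media as: uniform background → depth-stratified
layers (applied in order along axis 2) → ellipsoidal/spherical inclusions →
optional additive Gaussian texture clipped at zero, seeded for bitwise
reproducibility. The default spacing (0.59, 0.59, 0.6) mm mirrors a clinical
acquisition grid; the documented full-size grid is 521 × 512 × 344 voxels
(the odd 521 is suspected to be a transcription slip for 512 and is kept as
documented rather than silently corrected), but any shape is accepted and
the bundled examples use 64³ grids, which render in seconds on one CPU.
What these phantoms do **not** emulate: speckle statistics, anatomical
texture, refraction, or any tissue-specific calibration from CT numbers to
δ. Passing tests therefore demonstrate the correctness of the ray model's
arithmetic and contracts, not fidelity to clinical images.

## Quantitation layer

PCR: Yₙ = X·(1+E)ⁿ with E ∈ [0,1], implemented as an iterated product so
the per-cycle recursion Yₙ = Yₙ₋₁(1+E) holds bitwise in floating point. The
exponential regime is capped by a hard plateau at a configurable cycle
(default 30, the upper end of the typical 20–30 range); a smooth logistic
plateau is deliberately not attempted. Relative expression uses the
standard 2^−ΔΔCt double difference with the efficiency-2 assumption.

ELISA: standard series are geometric serial dilutions `[top, top/f, …, 0]`
(an explicit-list constructor covers non-geometric panels). Calibration
interpolates log-concentration against log-signal between the bracketing
standards, so a response at the geometric midpoint of two standards'
signals maps to the geometric midpoint of their concentrations; responses
below the blank floor at 0 with a `below_blank` flag, responses between the
blank and the lowest standard interpolate linearly in concentration
(`below_range`), and responses above the top standard are flagged
`above_range`. Four-parameter logistic fitting is deliberately omitted —
the bundled use cases never need it and it would add an opaque optimiser to
an otherwise closed-form path.

## Evaluation statistics

ROC: AUC by exhaustive Mann–Whitney pair counting with ties counted ½,
which equals the trapezoidal area under the empirical ROC (the test suite
carries an independent trapezoid implementation and checks the identity on
random tied data). The standard error is Hanley–McNeil; the 95 % CI is
auc ± 1.96·SE truncated to [0, 1]. The cut-off maximises the Youden index
over midpoints between adjacent distinct pooled values plus ±∞ sentinels,
with ties broken toward higher specificity; the caller states the marker's
direction (`greater`/`less`) since sensitivity is defined on the case
group. Welch's t uses the unequal-variance statistic with
Welch–Satterthwaite degrees of freedom; only the t-distribution tail
probability comes from scipy. Two constant, equal groups return t = 0,
p = 1 rather than an error.

## Bundled dataset

`load_sp_fixture()` returns per-subject serum SP-A and SP-D concentrations
(ng/mL) for 50 stable COPD patients and 50 healthy controls, stored at full
printed precision in a CSV whose SHA-256 is verified on every load. COPD
cases run higher on both markers; the dataset is the worked material for
the ROC and Welch routines and their brute-force oracles.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng` seeded from the
  phantom spec or the CLI `--seed`; identical inputs give bitwise-identical
  volumes and images.
* Rays that leave the volume mid-march return a truncated profile with an
  `exited` flag; asking for an attenuation ratio over a segment that exits
  raises an error naming the exit depth.
* Volumes are stored as float32 NIfTI with spacing in the header zooms;
  images as lossless 8-bit PNG/PGM.
* Known limitations: no scan conversion, no time-gain compensation beyond
  the shadow rule, no chi-square machinery or ICC in the statistics layer,
  and no calibration from CT attenuation numbers to δ.
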