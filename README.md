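# echoray

Ray-cast B-mode ultrasound simulation over 3D attenuation phantoms, with a
companion quantitation layer (exponential PCR amplification, ELISA standard
series) and hand-implemented evaluation statistics (ROC analysis, Welch's
t-test).

## Who this is for

`echoray` is aimed at researchers prototyping image-formation models for
ultrasound from CT-like scalar volumes — for example to study how acoustic
shadowing behind strong absorbers appears in simulated B-mode images — and
at anyone who needs the small, auditable statistical companion pieces
(serial-dilution panels, relative qPCR quantification, ROC cut-off
selection) that typically surround such an imaging study.

## The model

The medium is a non-negative scalar attenuation field δ(x) on a regular grid
with physical spacing (defaults: 0.59 mm in-plane, 0.6 mm between slices).
Writing g(x) = ∇δ(x) and M = max δ over the volume, a beam with unit
direction **d** marching at step λ experiences, at each point:

* **reflection** R = max(0, **d**·g/‖g‖) · (‖g‖ / 2M)ⁿ — interfaces reflect
  in proportion to the normalised gradient magnitude, weighted by the cosine
  of the incidence angle (back-facing interfaces reflect nothing);
* **transmittance** t = 1 − (‖g‖ / 2M)² — the fraction passing through the
  interface;
* **depth attenuation** I(L)/I₀ = exp(−∫₀ᴸ (‖g(x+s**d**)‖ / 2M)² ds),
  evaluated by the midpoint rule at the ray step with trilinear sampling.

The echo recorded at sample k along a beam is
`attenuation_ratio(depth_k) · Π_{j<k} t_j · R_k`, log-compressed to 8-bit
gray as `clamp(round(scale·log(1 + gain·echo)), 0, 255)`. Wherever the
accumulated attenuation ratio has fallen below the shadow threshold
(default **0.92**) the pixel is overwritten with the shadow floor gray
(default **50**) — the acoustic-shadow rule. For impedance-based media the
classical kernels are also exposed: Q = ρV and
K = ((Q₂−Q₁)/(Q₂+Q₁))², with the diffuse variant cosⁿθ·K.

The quantitation layer models PCR as Yₙ = X·(1+E)ⁿ for efficiency E ∈ [0,1]
with a hard plateau cap (default cycle 30), relative expression as 2^−ΔΔCt,
and ELISA standards as serial-dilution series with monotone log-linear
calibration. The statistics layer computes ROC AUC by Mann–Whitney pair
counting (ties ½), its standard error by the Hanley–McNeil formula, the
Youden-optimal cut-off, and Welch's unequal-variance t-test. A bundled
per-subject dataset of serum surfactant proteins SP-A and SP-D (50 stable
COPD patients vs. 50 healthy controls, ng/mL) serves as worked material.

## Worked example

```python
import numpy as np
from echoray import (PhantomSpec, ScanGeometry, make_phantom, render_bmode,
                     roc_analysis, welch_test, load_sp_fixture)
from echoray.volume import Layer

# a 64^3 phantom: background delta 1 with a steep absorber band at 10-14 mm
spec = PhantomSpec(grid_shape=(64, 64, 64), spacing=(0.5, 0.5, 0.5),
                   background_delta=1.0,
                   layers=(Layer(10.0, 5.0), Layer(14.0, 1.0)))
vol = make_phantom(spec)
geom = ScanGeometry.linear_array(vol, beam_count=32, samples_per_beam=60, step=0.5)
img = render_bmode(vol, geom)
print("shadow-pixel fraction:", round(float(img.shadow_mask.mean()), 4))
print("gray in shadow:", np.unique(img.gray[img.shadow_mask]))

fx = load_sp_fixture()["SP-D"]                  # control vs. COPD, ng/mL
roc = roc_analysis(fx.group_b, fx.group_a)      # COPD as cases
print("SP-D AUC = %.4f  SE = %.4f" % (roc.auc, roc.se))
print("cutoff = %.3f ng/mL  Se = %.2f  Sp = %.2f"
      % (roc.cutoff, roc.sensitivity, roc.specificity))
w = welch_test(fx)
print("Welch t = %.3f  df = %.1f  p = %.3g" % (w.t, w.df, w.p))
```

prints

```
shadow-pixel fraction: 0.6833
gray in shadow: [50]
SP-D AUC = 0.9284  SE = 0.0272
cutoff = 22.591 ng/mL  Se = 0.80  Sp = 1.00
Welch t = -10.034  df = 64.2  p = 8.98e-15
```

Every pixel beyond the absorber band where the beam's attenuation ratio
dropped below 0.92 renders at exactly gray 50; SP-D separates COPD cases
from controls with AUC ≈ 0.93, and its group difference is overwhelming
(negative t because `group_a` is the control group).

The same operations are available from a CLI:

```sh
echoray phantom --spec spec.json --out phantom.nii.gz
echoray simulate --volume phantom.nii.gz --beams 64 --samples 64 --out bmode.png
echoray pcr --x0 100 --efficiency 0.9 --cycles 25
echoray roc --cases cases.csv --controls controls.csv
```

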