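# tofmlaa

Joint reconstruction of activity and attenuation for time-of-flight (TOF)
PET, with autonomous resolution of the inherent scale ambiguity.

## The problem

Quantitative PET needs an attenuation map (μ, cm⁻¹ at 511 keV), normally
taken from a CT scan. TOF emission data contain enough information to
estimate attenuation *jointly* with activity (MLAA-style alternating
maximum-likelihood updates) — but only up to a global scale: if
(λ, μ) explains the data, so does (Cλ, μ + log C · μ_unit), where the
*unit attenuation medium* μ_unit has line integral 1 along every detectable
line of response (LOR) through the object. Left unresolved, this gauge
freedom makes joint reconstruction drift or diverge.

This package implements a practical CT-less pipeline that fixes the scale
using a volume of interest (VOI) with known mean attenuation (in patients,
e.g. the liver; here, a water region of the phantom):

1. **Activity update** — TOF OSEM with attenuation factors from the current μ̂:

   λ̂ ← λ̂ / (Hᵀa) · Σₜ Hₜᵀ[a yₜ / (a Hₜλ̂ + sₜ)],  a = e^(−χμ̂)

2. **Attenuation update (XMLTR)** — an additive transmission-tomography step
   from the non-TOF data with activity projection p = Hλ̂:

   μ̂ ← μ̂ + χᵀ[b(1 − y/ȳ)] / χᵀ[b(1 − ys/ȳ²)·χ1],  b = p·e^(−χμ̂), ȳ = b + s

3. **Scaling** — from the VOI weights w and known mean attenuation μ_true:

   log C = (wᵀμ_true − wᵀμ̂) / (wᵀμ_unit);   λ̂ ← Cλ̂,  μ̂ ← [μ̂ + log C·μ_unit]₊

4. **Additive-term refresh** — a hook for scatter re-estimation (external
   scatter sinograms are accepted; no scatter physics is simulated here).

A built-in simulator generates the evaluation phantom — a 35 cm water
cylinder (μ = 0.096 cm⁻¹) with lung (μ water/3) and air cylinders and hot
lesions of 22 mm (contrasts 1.5, 6) and 37 mm (contrast 3) — and draws
Poisson TOF counts from the same forward model, so everything runs with no
external data.

## Worked example

```python
import numpy as np
from tofmlaa import *
from tofmlaa.scanner_model import get_projector

geom, tof = ScanGeometry(), TOFModel()            # 84.2 cm ring, 300 ps
act_grid = ImageGrid(192, 192, 0.2)               # 2 mm activity voxels
att_grid = ImageGrid(96, 96, 0.4)                 # 4 mm attenuation voxels

spec = default_phantom()                          # 35 cm cylinder, 5e6 trues
lam, mu = build_phantom(spec, act_grid, att_grid)
sim = simulate_tof_counts(lam, mu, None, spec.total_trues, seed=1,
                          geometry=geom, tof=tof)

support = support_mask(spec, att_grid, margin=1.0)
obj = support_mask(spec, att_grid, margin=0.0)
unit = compute_unit_medium(get_projector(geom, att_grid), obj)
print(f"unit medium residual: {unit.residual:.3f}")

cfg = JointConfig(voi=VOISpec.disk(att_grid, (5.0, -5.0), 12.0, WATER_MU))
res = run_joint(sim.counts, None, geom, tof, act_grid, att_grid,
                support_mask(spec, act_grid, margin=1.0), support, cfg,
                unit=unit, object_support=obj,
                truth=ActivityImage(sim.trues_scale * lam.values, act_grid))
print("log C per iteration:", np.round(res.trace.log_c, 4))
print("whole-image %Bias per iteration:",
      np.round(res.diagnostics["percent_bias"], 2))
```

prints (seed 1):

```
unit medium residual: 0.350
log C per iteration: [-0.1703 -0.0394  0.0022  0.0115  0.0108  0.0081  0.0054  0.0035  0.0022  0.0013]
whole-image %Bias per iteration: [-0.16 -5.14 -5.56 -4.86 -4.07 -3.45 -3.03 -2.75 -2.58 -2.46]
```

The scaling constant C = e^(log C) converges to one within a few
iterations — the VOI has pinned the gauge. The whole-image bias of this
single noisy 2D replicate settles at a few percent; on noiseless data it
falls to ~0.1% (see `docs/methods.md` for what desk-scale noise does and
does not show). The unit-medium residual is the worst deviation of its
line integrals from 1 over interior LORs; it is concentrated at
near-tangent LORs and reported, never hidden.

There is also a CLI over the same functions:

```bash
tofmlaa simulate    --config config.yaml --seed 1 --out runs/sim
tofmlaa unit-medium --config config.yaml --out runs/unit.h5
tofmlaa recon-joint --config config.yaml --counts runs/sim/counts.h5 --out runs/joint
tofmlaa evaluate    --config config.yaml --recon runs/joint/activity_joint.h5 \
                    --truth runs/sim/activity_true.h5 --out runs/metrics.csv
```

Exit codes: 0 success, 2 configuration error, 3 numerical divergence.

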