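# hemoflow

Image-to-hemodynamics analysis of the retinal microvasculature: synthetic
confocal-scale vascular phantoms, 3-D vessel segmentation, centerline graph
extraction, and a reduced-order non-Newtonian network flow solver that maps
wall shear stress (WSS), velocity and pressure over the capillary network
under ocular perfusion-pressure and capillary-dropout scenarios.

**Who it is for.** Researchers modelling retinal perfusion — e.g. how
elevated intraocular pressure (acting through venous pressure) or capillary
rarefaction redistributes wall shear stress in the rat retina — who need a
desk-scale, fully testable pipeline instead of a commercial 3-D CFD stack.

## The model

Blood is a Carreau–Yasuda (CY) shear-thinning fluid,

&nbsp;&nbsp;&nbsp;&nbsp;η(γ̇) = η∞ + (η0 − η∞)·[1 + (λγ̇)^a]^((n−1)/a),

flowing steadily through a vessel graph of rigid cylindrical segments.
Volumetric flow in each segment follows the Weissenberg–Rabinowitsch–Mooney
integral Q = (πR³/τ_w³)·∫₀^{τ_w} τ²γ̇(τ)dτ with wall shear stress
τ_w = Δp·R/(2L); nodal mass conservation with Dirichlet pressures at the
arteriole inlets and venule outlets closes the system, and a Picard
iteration couples the shear-dependent viscosity to the flow field. In the
Newtonian limit the solver reproduces Hagen–Poiseuille exactly.

The synthetic generator builds a rat-retina-scale slab
(2300 × 2300 × 60 µm): arteriole and venule trees alternating radially
around the optic disc, interdigitated terminal branches bridged by 4–7 µm
capillary rungs, calibres set by shear-driven structural adaptation so that
baseline capillary WSS lies in the physiological 0–20 Pa range. Pressure
scenarios (arteriole 100/130/150 mmHg, venule 10/30/50 mmHg) and
volume-targeted capillary dropout (10/30/50%) reproduce the study design
the package is built around.

## Worked example

```python
import numpy as np
from hemoflow import (BoundaryConditions, DropoutSpec, RheologyParams,
                      apply_dropout, generate_network, solve_network)

net = generate_network(seed=1)                       # rat-scale phantom
bc = BoundaryConditions.from_preset(net, "baseline")  # 100/10 mmHg
sol = solve_network(net, bc, RheologyParams())

caps = [i for i, s in enumerate(net.segments) if s.vessel_class == "capillary"]
tau = sol.wall_shear_stress[caps]
print(f"capillary WSS: mean {tau.mean():.2f} Pa, max {tau.max():.2f} Pa")

dropped = apply_dropout(net, DropoutSpec(0.30, seed=1))
sol_d = solve_network(dropped, BoundaryConditions.from_preset(dropped, "baseline"))
wss0, wss1 = sol.wss_of(), sol_d.wss_of()
surv = [s.id for s in dropped.segments if s.vessel_class == "capillary"]
change = 100 * (np.mean([wss1[i] for i in surv]) / np.mean([wss0[i] for i in surv]) - 1)
print(f"mean capillary WSS change after 30% dropout: {change:+.1f}%")
```

prints

```
capillary WSS: mean 12.30 Pa, max 18.14 Pa
mean capillary WSS change after 30% dropout: +26.7%
```

The first line is the baseline calibration of the phantom: capillary-network
wall shear in the physiological window, nothing above 20 Pa. The second line
is the rarefaction effect — with boundary pressures fixed, removing 30% of
the capillary volume concentrates perfusion on the surviving capillaries and
raises their mean wall shear stress by roughly a quarter to a third,
depending on which capillaries the seeded removal draws.

A command-line interface covers the same pipeline for files on disk:

```bash
hemoflow generate --seed 1 --out net.json --vtk net.vtk
hemoflow solve --network net.json --bc elevated_venule_1 --csv fields.csv
hemoflow render --network net.json --label-out truth.tiff --image-out stack.tiff
hemoflow segment --in stack.tiff --out mask.tiff --truth truth.tiff
hemoflow extract --mask mask.tiff --out extracted.json
hemoflow experiment --network net.json --out-dir results/
```

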