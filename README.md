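# ipdtplan

Treatment planning for **interstitial photodynamic therapy (iPDT)** of
spherical tumor nodes illuminated by cylindrical diffusing fibers (CDFs).

In iPDT, optical fibers with radially emitting tips are inserted into a
bulky tumor and driven so that the light dose across the target volume
falls inside a therapeutic window — enough fluence to activate the
photosensitizer, not so much as to risk thermal damage. `ipdtplan` answers
the planning question for a spherical node of known optical properties:
*where do the fibers go, how long are their diffusing tips, and what linear
power does each need so that the dose window covers at least 90% of the
node volume?* It is aimed at biomedical-optics researchers prototyping
light-dosimetry and planning pipelines.

## Model

Fluence rate of one diffuser in an infinite homogeneous turbid medium, via
the diffusion approximation with the fiber discretized as N point sources:

    φ(p) = (3 s l μs′)/(4π (N−1)) · Σᵢ exp(−μ_eff rᵢ)/rᵢ,   μ_eff = √(3 μa (μa+μs′))

with linear power *s* (mW/cm), diffusing length *l*, and rᵢ the distance
from the i-th source point to p. Dose (J/cm²) is fluence rate × time /
1000, summed over fibers. The node (diameter 0.5–5 cm) is voxelized at
0.1 cm pitch and cut into 1 mm slices. One fiber spans the vertical
diameter; when it cannot satisfy the per-slice 90% condition, three fibers
are added at the gravity centers of the equatorial 120° sectors —
`x = 2r sin(a)/(3a)` from the center, lengths fitted so the tips touch the
sphere — and, if total coverage still falls short, four fibers at 90°
sector centers replace them. Powers are found by an ascending grid search
(5–500 mW/cm, step 5). A voxel counts as treated when its dose is inside
the window (20–50 J/cm² by default) or when it is overdosed within 0.17 cm
of a fiber, where diffusion theory underestimates the true fluence;
overdose farther out is dismissed.

See `docs/methods.md` for assumptions, defaults, and numerical choices.

## Worked example

Plan a 0.5 cm node with the default breast-tumor optical properties
(μa = 0.085 cm⁻¹, μs′ = 16 cm⁻¹, 150 s illumination):

```
$ ipdtplan plan --diameter 0.5 --out out/
1-fiber plan: s1=35 mW/cm, total coverage 100.0%
wrote out/plan.json
wrote out/slices.csv
wrote out/dose.nrrd
```

The central diffuser alone, at 35 mW/cm, brings every one of the 81
in-sphere voxels into the therapeutic window (or the near-source region),
so no surrounding fibers are added and all five slices report 100%
coverage. The same run from the library:

```python
from ipdtplan import plan_node

plan = plan_node(0.5)
print(plan.n_fibers_used, plan.central_power, plan.total_ratio)
# 1 35.0 100.0
```

For larger nodes the planner adds surrounding fibers and escalates from
four to five when four cannot reach the 90% threshold:

```python
plan = plan_node(3.0)
print(plan.n_fibers_used, plan.escalated, round(plan.total_ratio, 1))
# 5 True 39.4
```

The feasibility flags (`plan.s1_feasible`, `plan.s2_feasible`) report when
a slice condition could not be met at any grid power and the best-effort
power was used instead; under this kernel the therapeutic window cannot
cover 90% of nodes this large at any power (see `docs/methods.md`,
*Known limitations*).

A full diameter sweep (0.5–5 cm, the published study grid) with forced
four-fiber layouts:

```
$ ipdtplan sweep --fibers 4 --out out/
```

writes `out/summary.csv` with one row per node: diameter, slice count, the
slice the central power reaches, s1, s2, total coverage, surrounding fiber
length, and the sector-centroid distance x.

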