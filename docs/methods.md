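# Methods

## Physical model

Light transport is modelled with the diffusion approximation for an infinite
homogeneous turbid medium. A point source of power *P* produces a fluence
rate proportional to `exp(-mu_eff * r) / r`, with the effective attenuation

    mu_eff = sqrt(3 * mua * (mua + musp))      [1/cm]

A cylindrical diffusing fiber (CDF) of diffusing length *l* and linear power
*s* (mW/cm) is discretized as *N* point sources spaced `dx = l/(N-1)` along
its axis, one always at the midpoint (*N* odd):

    phi(p) = (3 s l musp) / (4 pi (N-1)) * sum_i exp(-mu_eff r_i) / r_i

where `r_i` is the distance from the i-th source point to the observation
point `p`. The prefactor uses `musp` rather than the `mua + musp` of the
standard diffusion coefficient; the difference is 0.5% at the default
optical properties and the kernel is kept in this exact form deliberately.
Dose is fluence rate times illumination time, divided by 1000 to convert
mW·s/cm² to J/cm².

Numerical notes on the discretization:

- The weight `l/(N-1)` over *N* endpoint-inclusive points makes the sum an
  endpoint-weighted quadrature of the continuous line-source integral: it
  exceeds the bare integral by the half-weight endpoint excess, bounded by
  the factor `N/(N-1)` (&approx; 1.01 at the default N = 101). For
  node-scale diffusers (2.5–5 cm) the excess stays below 0.5% at all
  clinically relevant distances; for short fibers it approaches the 1%
  bound in the far field. The far-field limit is the point-source closed
  form times `N/(N-1)`.
- Because of the same normalization, the value is *N*-independent (below
  10⁻³ relative) only where the diffuser subtends a large angle — for a
  5 cm diffuser, radial distances up to about 2 cm. Beyond that, refining
  *N* drifts the value by up to `1/(N-1)` as the normalization factor
  decays. Within the node, where all dosimetry happens, the default
  N = 101 is fully converged.
- Distances below 0.05 cm (half the voxel pitch) are clamped so the kernel
  stays finite on the fiber itself. Clamped voxels lie well inside the
  near-source region (below) and are classified by the near-source rule,
  so the clamp value does not influence coverage.

## Node model and fiber placement

The tumor node is a sphere of diameter 0.5–5 cm centred at the origin,
voxelized at a 0.1 cm pitch: cells tile `[-R, R]^3` with centres at
half-pitch offsets, and a voxel belongs to the node when its centre lies
within the sphere. This registration produces exactly `diameter/pitch`
horizontal slices of one-pitch thickness (indexed 1 from the bottom) and
reproduces the published equatorial-slice population of the 5 cm node
(1976 voxels) exactly.

Fibers are vertical. The central fiber spans the vertical diameter. The
surrounding fibers stand at the centroid radius of the equatorial angular
sectors — `x = 2 r sin(a) / (3a)` for a sector of half-angle `a` — three
fibers for 120° sectors or four for 90° sectors, azimuthally equispaced
(az. 90°/210°/330° and 45°/135°/225°/315° respectively; coverage is nearly
rotation-invariant, and fixing the azimuths makes every run reproducible).
Their lengths are fitted so the tips touch the sphere:
`L = 2 sqrt(R^2 - x^2)`.

## Dose-coverage rule

A voxel counts as treated when its total dose lies in the therapeutic
window (default 20–50 J/cm²), **or** when it lies within the near-source
radius (0.17 cm) of some fiber and is overdosed: the diffusion model badly
underestimates fluence that close to a source, so near-fiber overdose is
taken at face value. Overdose beyond the near-source radius is dismissed
(treated as failure, modelling thermal-damage avoidance); underdose never
counts. The coverage ratio of a voxel set is the percentage of its voxels
that count. Enlarging the near-source radius or widening the window can
only increase coverage — both monotonicities are asserted in the tests.

## Power optimization

Powers are searched on an ascending grid (5 to 500 mW/cm in steps of 5 —
the hardware ceiling of the modelled diffusers). Because the dose field is
linear in each fiber's power, per-fiber unit-power dose fields are cached
once and every candidate power is evaluated as a scaled sum.

1. **Central power** `s1`: the first grid power whose dose covers at least
   90% of the *starting slice*. The power is then tested on each slice
   advancing toward the top; `reaches_up_to_slice` records the last
   consecutive slice that still satisfies the condition ("all" when none
   fails — in that case the plan uses the central fiber alone).
2. **Surrounding power** `s2` (all surrounding fibers equal): the first
   grid power bringing the equatorial slice to 90% coverage, given `s1`.
3. **Escalation**: if the four-fiber total coverage is below 90% and the
   fiber budget allows, the three 120°-sector fibers are replaced by four
   90°-sector fibers and step 2 reruns; both configurations are kept in
   the plan record.

The starting slice defaults to the slice just below the equatorial plane.
The bottom-most slice is a poor anchor at the default geometry: for small
nodes it lies entirely inside the near-source radius of the central fiber,
so any power that merely exceeds the window floor "covers" it, and the
search returns a power far too weak for the wider slices. The
equator-adjacent slice is the widest cross-section and anchors the search
on the hardest single-fiber constraint; with it, the 0.5 cm node plans to a
single fiber at 100% coverage. The choice remains configurable
(`--start-slice equator|bottom|<index>`).

Feasibility is handled best-effort: if no grid power reaches the threshold
on a slice search, the max-coverage power (lowest such power) is used and
the plan is flagged (`s1_feasible` / `s2_feasible` false). For nodes of
3 cm and larger the equatorial slice cannot reach 90% under this kernel at
any power — the window spans only a factor 2.5 while the dose field around
each fiber falls much faster, so in-window shells are thin and the
overdose-dismissal shells around the fibers are wide. An outright error is
raised only when no power covers a single voxel (e.g. a degenerate power
grid). Ties in coverage resolve to the lower power automatically via the
ascending scan.

## Defaults and units

| Parameter | Default | Units | Note |
|---|---|---|---|
| mua | 0.085 | 1/cm | mean published breast-tumor absorption at 690 nm |
| musp | 16 | 1/cm | mean published reduced scattering at 690 nm |
| time | 150 | s | typical continuous-illumination session |
| dose window | 20–50 | J/cm² | clinically motivated therapeutic band |
| coverage threshold | 0.90 | — | plan acceptance fraction |
| nsf radius | 0.17 | cm | near-source validity bound of diffusion theory |
| power grid | 5–500 step 5 | mW/cm | hardware CW ceiling 500 mW/cm |
| pitch | 0.1 | cm | voxel edge and slice thickness |
| N | 101 | — | point sources per fiber; dx ≤ 0.05 cm for l ≤ 5 cm |

## Determinism and problem sizes

The method contains no randomness: identical configurations produce
byte-identical `plan.json`, `slices.csv` and `summary.csv` (sorted JSON
keys, fixed float formatting — 4 decimals for lengths, 1 for ratios,
integers for powers). The largest studied node (5 cm) holds ~65,000 voxels
and a five-fiber plan over it completes in a few seconds on one core; the
full 10-diameter sweep runs in well under a minute. Tests use nodes of
0.5–3 cm, which exercise every code path (single-fiber, four-fiber,
escalation) at a fraction of the cost.

## What the fixtures do and do not show

The built-in configurations are idealized: a perfectly spherical,
homogeneous node with literature-mean optical properties, perfectly
vertical fibers, and a uniform emission profile along each diffuser.
Passing tests demonstrate the internal consistency of the kernel, the
geometry, and the optimizer on those idealizations — not dosimetric
accuracy in real tissue, where optical properties vary between patients
and within a tumor, fibers bend, and diffusion theory itself breaks down
near sources and boundaries.

## Known limitations

- Infinite-medium kernel: no boundary conditions, so dose near the node
  surface (close to real tissue boundaries) is approximate.
- Homogeneous optical properties only; no heterogeneity maps.
- Spherical nodes only; fiber positions are fixed by the sector-centroid
  geometry and only powers (and fitted lengths) are optimized.
- No photosensitizer photochemistry or oxygen dosimetry: "dose" means
  light fluence.
- For nodes of 3 cm and above the 20–50 J/cm² window cannot cover 90% of
  the volume under this kernel at any grid powers (the optimizer then
  reports its best effort with feasibility flags). Published plans that
  claim otherwise for the same geometry imply a flatter effective kernel
  than the one specified here.
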