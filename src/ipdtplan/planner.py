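"""Power optimization and dose-volume coverage for interstitial PDT plans.

The planning pipeline:

1. Voxelize the node and place the central fiber along the vertical diameter.
2. Scan the linear-power grid ascending and pick the first power whose dose
   covers >= 90% of the starting slice; then test the same power on each
   slice advancing toward the top, recording how far the per-slice condition
   holds.
3. If the condition breaks before the top, add three surrounding fibers at
   the 120-degree sector gravity centres and scan for the (equal) surrounding
   power that brings the equatorial slice to >= 90% coverage, given the
   central power.
4. Compute the total coverage over all in-sphere voxels.  If it falls short
   of the threshold, escalate to four surrounding fibers at 90-degree sector
   centres and repeat step 3.

A voxel counts as covered when its total dose lies inside the therapeutic
window (20-50 J/cm^2 by default), or when it sits within the near-source
radius (0.17 cm) of some fiber and is overdosed there -- the diffusion model
underestimates the true fluence that close to a source, so such points are
assumed treated.  Overdosed voxels beyond the near-source radius are
dismissed; underdosed voxels never count.

Everything is linear in the fiber powers, so per-fiber unit-power dose
fields are cached once and the power scans are cheap vector operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import FiberPlacement, NodeModel, build_node, distance_to_fiber, place_fibers
from .optics import (
    BREAST_TUMOR_690NM,
    CylindricalDiffuser,
    OpticalProperties,
    cdf_fluence_rate,
    dose_from_fluence,
)

__all__ = [
    "PlanConfig",
    "TreatmentPlan",
    "DoseField",
    "InfeasiblePlanError",
    "voxel_meets_target",
    "coverage_ratio",
    "optimize_central_power",
    "optimize_surrounding_power",
    "plan_node",
]

logger = logging.getLogger(__name__)


class InfeasiblePlanError(RuntimeError):
    """No power on the configured grid makes any progress on the starting slice."""

    def __init__(self, message: str, *, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class PlanConfig:
    """Tunable planning parameters (defaults are the study conditions).

    dose_low / dose_high : therapeutic window bounds, J/cm^2.
    time : illumination time, s.
    coverage_threshold : acceptance fraction of voxels per slice / in total.
    nsf_radius : near-source radius within which overdose still counts, cm.
    power_min / power_max / power_step : ascending linear-power grid, mW/cm.
    max_fibers : 4 disables the five-fiber escalation, 5 enables it.
    pitch : voxel edge and slice thickness, cm.
    n_points : point sources per diffuser in the fluence kernel.
    start_slice : "equator" (slice just below the equatorial plane),
        "bottom", or an explicit 1-based slice index.
    """

    dose_low: float = 20.0
    dose_high: float = 50.0
    time: float = 150.0
    coverage_threshold: float = 0.90
    nsf_radius: float = 0.17
    power_min: float = 5.0
    power_max: float = 500.0
    power_step: float = 5.0
    max_fibers: int = 5
    pitch: float = 0.1
    n_points: int = 101
    start_slice: int | str = "equator"

    def __post_init__(self) -> None:
        if not (self.dose_low < self.dose_high):
            raise ValueError("dose_low must be < dose_high")
        if self.power_step <= 0 or self.power_max < self.power_min:
            raise ValueError("power grid is empty or ill-formed")
        for name in ("time", "coverage_threshold", "nsf_radius", "pitch", "n_points"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def power_grid(self) -> np.ndarray:
        """Ascending candidate linear powers, mW/cm."""
        n = int(np.floor((self.power_max - self.power_min) / self.power_step)) + 1
        return self.power_min + self.power_step * np.arange(n)

    def resolve_start_slice(self, node: NodeModel) -> int:
        if self.start_slice == "equator":
            return node.equatorial_lower_slice
        if self.start_slice == "bottom":
            return 1
        idx = int(self.start_slice)
        if not (1 <= idx <= node.n_slices):
            raise ValueError(f"start_slice {idx} outside 1..{node.n_slices}")
        return idx


class DoseField:
    """Per-fiber unit-power dose cache over the node voxels.

    ``unit_dose[i]`` is the dose field of fiber ``i`` at 1 mW/cm; by
    linearity the total dose at powers ``s`` is ``sum_i s_i * unit_dose[i]``.
    """

    def __init__(
        self,
        node: NodeModel,
        fibers: tuple[CylindricalDiffuser, ...],
        props: OpticalProperties,
        time: float,
    ):
        self.node = node
        self.fibers = fibers
        self.props = props
        self.time = time
        pts = node.voxel_centers
        self.unit_dose = np.stack(
            [
                dose_from_fluence(cdf_fluence_rate(f.with_power(1.0), pts, props), time)
                for f in fibers
            ]
        )
        self.distances = np.stack([distance_to_fiber(pts, f) for f in fibers])
        self.nearest_distance = self.distances.min(axis=0)

    def dose(self, powers) -> np.ndarray:
        """Total dose (J/cm^2) per voxel at the given per-fiber linear powers."""
        powers = np.asarray(powers, dtype=float)
        if powers.shape != (len(self.fibers),):
            raise ValueError(f"expected {len(self.fibers)} powers, got {powers.shape}")
        return powers @ self.unit_dose


def voxel_meets_target(
    dose, nearest_fiber_distance, config: PlanConfig
) -> np.ndarray | bool:
    """Therapeutic-window test with the near-source overdose rule.

    True iff ``dose_low <= dose <= dose_high``, or the voxel lies within
    ``nsf_radius`` of the nearest fiber and is overdosed there.  Underdose
    never counts; overdose beyond the near-source radius is dismissed.
    """
    dose = np.asarray(dose, dtype=float)
    dist = np.asarray(nearest_fiber_distance, dtype=float)
    in_window = (dose >= config.dose_low) & (dose <= config.dose_high)
    near_overdose = (dist <= config.nsf_radius) & (dose > config.dose_high)
    out = in_window | near_overdose
    return bool(out) if out.ndim == 0 else out


def coverage_ratio(
    dose: np.ndarray,
    nearest_fiber_distance: np.ndarray,
    config: PlanConfig,
    subset: np.ndarray | None = None,
) -> float:
    """Percentage of (subset) voxels meeting the target-dose rule, in [0, 100]."""
    ok = voxel_meets_target(dose, nearest_fiber_distance, config)
    if subset is not None:
        ok = ok[subset]
    if ok.size == 0:
        raise ValueError("coverage ratio of an empty voxel subset is undefined")
    return 100.0 * float(np.count_nonzero(ok)) / ok.size


def _slice_coverage(field: DoseField, dose: np.ndarray, config: PlanConfig, index: int) -> float:
    return coverage_ratio(dose, field.nearest_distance, config, field.node.slice_mask(index))


def optimize_central_power(
    node: NodeModel,
    central: CylindricalDiffuser,
    props: OpticalProperties,
    config: PlanConfig,
) -> tuple[float, int | str, bool]:
    """Ascending-scan search of the central fiber power.

    Returns ``(s1, reaches_up_to_slice, feasible)``.  ``s1`` is the first
    grid power whose dose covers >= the threshold of the starting slice;
    ``reaches_up_to_slice`` is the last consecutive slice (advancing upward
    from the starting slice) still meeting the per-slice condition at
    ``s1`` -- ``"all"`` when the condition holds to the top slice.

    When no grid power reaches the threshold on the starting slice, the
    power with the best starting-slice coverage is returned flagged
    ``feasible=False`` (the per-slice condition is then considered broken at
    the starting slice itself, so surrounding fibers will be added).  When
    no power covers any voxel at all, planning cannot proceed and
    :class:`InfeasiblePlanError` is raised.
    """
    field = DoseField(node, (central,), props, config.time)
    start = config.resolve_start_slice(node)
    threshold = 100.0 * config.coverage_threshold
    start_mask = node.slice_mask(start)
    if not start_mask.any():
        raise InfeasiblePlanError(f"starting slice {start} contains no voxels")

    grid = config.power_grid
    # all powers at once: coverage is monotone in neither direction because of
    # the window's upper edge, so the whole grid is evaluated explicitly
    unit = field.unit_dose[0][start_mask]
    dist = field.nearest_distance[start_mask]
    cov = np.array(
        [coverage_ratio(s * unit, dist, config) for s in grid]
    )
    feasible_idx = np.flatnonzero(cov >= threshold)
    if feasible_idx.size:
        s1 = float(grid[feasible_idx[0]])
        feasible = True
    elif cov.max() > 0.0:
        s1 = float(grid[int(np.argmax(cov))])
        feasible = False
        logger.debug(
            "central search: no grid power reaches %.0f%% of slice %d; "
            "best effort s1=%g mW/cm covers %.1f%%",
            threshold, start, s1, cov.max(),
        )
    else:
        raise InfeasiblePlanError(
            "no grid power covers any voxel of the starting slice",
            diagnostics={"start_slice": start, "grid": grid.tolist()},
        )
    logger.debug("central search: start slice %d -> s1=%g mW/cm", start, s1)

    reaches: int | str = start if feasible else 0
    if feasible:
        dose = s1 * field.unit_dose[0]
        broke = False
        for k in range(start + 1, node.n_slices + 1):
            c = _slice_coverage(field, dose, config, k)
            logger.debug("central propagation: slice %d coverage %.1f%%", k, c)
            if c >= threshold:
                reaches = k
            else:
                broke = True
                break
        if not broke:
            reaches = "all"
    return s1, reaches, feasible


def optimize_surrounding_power(
    field: DoseField,
    central_power: float,
    config: PlanConfig,
) -> tuple[float, bool]:
    """Equal surrounding-fiber power from the equatorial-slice condition.

    Scans the grid ascending and returns the first power for which the
    central slice's coverage (total dose of all fibers) reaches the
    threshold.  When none qualifies -- which happens for large nodes, where
    the equatorial slice cannot be covered at any power -- the power
    maximising central-slice coverage is returned with ``feasible=False``.
    """
    node = field.node
    central_idx = node.equatorial_lower_slice
    mask = node.slice_mask(central_idx)
    threshold = 100.0 * config.coverage_threshold
    base = central_power * field.unit_dose[0][mask]
    sur_unit = field.unit_dose[1:, mask].sum(axis=0)
    dist = field.nearest_distance[mask]
    best_s2, best_cov = None, -1.0
    for s2 in config.power_grid:
        cov = coverage_ratio(base + s2 * sur_unit, dist, config)
        logger.debug("surrounding search: s2=%g -> central slice %.1f%%", s2, cov)
        if cov >= threshold:
            return float(s2), True
        if cov > best_cov:
            best_s2, best_cov = float(s2), cov
    logger.debug(
        "surrounding search: infeasible, best effort s2=%g (%.1f%%)", best_s2, best_cov
    )
    return best_s2, False


@dataclass(frozen=True)
class TreatmentPlan:
    """Result of planning one node."""

    diameter: float
    props: OpticalProperties
    config: PlanConfig
    placement: FiberPlacement
    central_power: float
    surrounding_power: float | None
    reaches_up_to_slice: int | str
    per_slice_ratio: np.ndarray
    total_ratio: float
    n_fibers_used: int
    s1_feasible: bool = True
    s2_feasible: bool = True
    escalated: bool = False
    four_fiber_record: dict | None = None

    @property
    def n_slices(self) -> int:
        return len(self.per_slice_ratio)


def _evaluate(field: DoseField, powers: np.ndarray, config: PlanConfig):
    dose = field.dose(powers)
    node = field.node
    per_slice = np.array(
        [_slice_coverage(field, dose, config, k) for k in range(1, node.n_slices + 1)]
    )
    total = coverage_ratio(dose, field.nearest_distance, config)
    return per_slice, total


def plan_node(
    diameter: float,
    props: OpticalProperties = BREAST_TUMOR_690NM,
    config: PlanConfig = PlanConfig(),
    n_surrounding: int | str = "auto",
) -> TreatmentPlan:
    """Run the full planning pipeline for one spherical node.

    Parameters
    ----------
    n_surrounding : "auto", 0, 3 or 4
        "auto" applies the escalation logic (central only if it suffices,
        else 3 surrounding fibers, else 4); an integer forces that layout
        (a forced layout still collapses to the central fiber alone when the
        central power already satisfies every slice).
    """
    if n_surrounding not in ("auto", 0, 3, 4):
        raise ValueError(f"n_surrounding must be 'auto', 0, 3 or 4, got {n_surrounding}")
    node = build_node(diameter, config.pitch)
    central_placement = place_fibers(node, 0, n_points=config.n_points)
    s1, reaches, s1_ok = optimize_central_power(
        node, central_placement.central, props, config
    )

    central_suffices = reaches == "all"
    if central_suffices or n_surrounding == 0:
        placement = central_placement.with_powers(s1)
        field = DoseField(node, placement.fibers, props, config.time)
        per_slice, total = _evaluate(field, np.array([s1]), config)
        return TreatmentPlan(
            diameter=node.diameter,
            props=props,
            config=config,
            placement=placement,
            central_power=s1,
            surrounding_power=None,
            reaches_up_to_slice=reaches,
            per_slice_ratio=per_slice,
            total_ratio=total,
            n_fibers_used=1,
            s1_feasible=s1_ok,
        )

    def run_layout(n_sur: int):
        placement = place_fibers(node, n_sur, n_points=config.n_points)
        field = DoseField(node, placement.fibers, props, config.time)
        s2, s2_ok = optimize_surrounding_power(field, s1, config)
        powers = np.array([s1] + [s2] * n_sur)
        per_slice, total = _evaluate(field, powers, config)
        return placement.with_powers(s1, s2), s2, s2_ok, per_slice, total

    first_layout = 4 if n_surrounding == 4 else 3
    placement, s2, s2_ok, per_slice, total = run_layout(first_layout)
    logger.info(
        "%d-fiber plan for %.1f cm node: s1=%g, s2=%g, total %.1f%%",
        first_layout + 1, diameter, s1, s2, total,
    )

    escalated = False
    four_fiber_record = None
    threshold = 100.0 * config.coverage_threshold
    if (
        n_surrounding == "auto"
        and first_layout == 3
        and total < threshold
        and config.max_fibers >= 5
    ):
        four_fiber_record = {
            "surrounding_power": s2,
            "s2_feasible": s2_ok,
            "per_slice_ratio": per_slice,
            "total_ratio": total,
        }
        placement, s2, s2_ok, per_slice, total = run_layout(4)
        escalated = True
        logger.info(
            "escalated to 5 fibers: s2=%g, total %.1f%%", s2, total
        )

    return TreatmentPlan(
        diameter=node.diameter,
        props=props,
        config=config,
        placement=placement,
        central_power=s1,
        surrounding_power=s2,
        reaches_up_to_slice=reaches,
        per_slice_ratio=per_slice,
        total_ratio=total,
        n_fibers_used=1 + placement.n_surrounding,
        s1_feasible=s1_ok,
        s2_feasible=s2_ok,
        escalated=escalated,
        four_fiber_record=four_fiber_record,
    )
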