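"""Serialization of plans and diameter sweeps.

Emits, per plan: ``plan.json`` (fibers, powers, coverage, config echo),
``slices.csv`` (per-slice coverage table behind the dose-profile figures) and
``dose.nrrd`` (the voxel dose grid, ASCII NRRD, NaN outside the sphere).
Sweeps over node diameters are flattened to ``summary.csv`` whose columns are
a superset of the published result-table layout, so a cell-by-cell diff is
scriptable.

All outputs are deterministic: the method has no randomness, floats are
formatted with a fixed policy (4 decimals for lengths and distances, 1 for
coverage ratios, integers for powers), and JSON keys are sorted -- identical
runs produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from .optics import OpticalProperties, BREAST_TUMOR_690NM
from .planner import InfeasiblePlanError, PlanConfig, TreatmentPlan, plan_node

__all__ = [
    "run_sweep",
    "export_plan",
    "export_sweep",
    "write_nrrd",
    "read_nrrd",
    "dose_grid",
    "DEFAULT_SWEEP_DIAMETERS",
]

logger = logging.getLogger(__name__)

#: The studied node sizes: 0.5 to 5 cm in 0.5 cm increments.
DEFAULT_SWEEP_DIAMETERS = tuple(np.round(np.arange(0.5, 5.01, 0.5), 1))

SUMMARY_COLUMNS = [
    "node",
    "diameter_cm",
    "total_slices",
    "reaches_up_to_slice",
    "central_power_mw_cm",
    "surrounding_power_mw_cm",
    "total_ratio_pct",
    "surrounding_length_cm",
    "distance_x_cm",
    "n_fibers",
    "s1_feasible",
    "s2_feasible",
    "escalated",
    "error",
]


def _software() -> str:
    try:
        return f"ipdtplan {_pkg_version('ipdtplan')}"
    except PackageNotFoundError:  # pragma: no cover - not installed
        return "ipdtplan"


def _fmt4(x) -> str:
    return "" if x is None else f"{float(x):.4f}"


def _fmt1(x) -> str:
    return "" if x is None else f"{float(x):.1f}"


def _fmt_power(x) -> str:
    return "" if x is None else str(int(round(float(x))))


def run_sweep(
    diameters=DEFAULT_SWEEP_DIAMETERS,
    props: OpticalProperties = BREAST_TUMOR_690NM,
    config: PlanConfig = PlanConfig(),
    n_surrounding: int | str = "auto",
) -> tuple[pd.DataFrame, dict[float, TreatmentPlan]]:
    """Plan every diameter and tabulate the results.

    ``n_surrounding`` "auto" applies the 4-to-5 fiber escalation; 3 or 4
    force the four- and five-fiber layouts (regenerating the two published
    result tables).  Per-node failures are logged and recorded in the
    ``error`` column without aborting the sweep.

    Returns the summary table and the per-diameter plans that succeeded.
    """
    rows = []
    plans: dict[float, TreatmentPlan] = {}
    for i, d in enumerate(diameters, start=1):
        row = {c: None for c in SUMMARY_COLUMNS}
        row.update(node=i, diameter_cm=float(d))
        try:
            plan = plan_node(d, props, config, n_surrounding=n_surrounding)
        except (InfeasiblePlanError, ValueError) as exc:
            logger.error("planning failed for %.1f cm node: %s", d, exc)
            row["error"] = str(exc)
            rows.append(row)
            continue
        plans[float(d)] = plan
        row.update(
            total_slices=plan.n_slices,
            reaches_up_to_slice=plan.reaches_up_to_slice,
            central_power_mw_cm=plan.central_power,
            surrounding_power_mw_cm=plan.surrounding_power,
            total_ratio_pct=plan.total_ratio,
            surrounding_length_cm=plan.placement.surrounding_length,
            distance_x_cm=plan.placement.gravity_distance,
            n_fibers=plan.n_fibers_used,
            s1_feasible=plan.s1_feasible,
            s2_feasible=plan.s2_feasible,
            escalated=plan.escalated,
            error="",
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS), plans


def export_sweep(table: pd.DataFrame, path) -> Path:
    """Write the sweep summary as CSV with the fixed formatting policy."""
    path = Path(path)
    out = table.copy()
    for col, fmt in [
        ("central_power_mw_cm", _fmt_power),
        ("surrounding_power_mw_cm", _fmt_power),
        ("total_ratio_pct", _fmt1),
        ("surrounding_length_cm", _fmt4),
        ("distance_x_cm", _fmt4),
    ]:
        out[col] = out[col].map(lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v)) else fmt(v))
    _write_text(path, out.to_csv(index=False))
    return path


def plan_record(plan: TreatmentPlan) -> dict:
    """JSON-ready canonical description of a plan."""
    cfg = plan.config
    record = {
        "software": _software(),
        "determinism": "fully deterministic: the method involves no randomness",
        "diameter_cm": round(plan.diameter, 4),
        "optical_properties": {"mua_cm": plan.props.mua, "musp_cm": plan.props.musp},
        "config": {
            "dose_low_j_cm2": cfg.dose_low,
            "dose_high_j_cm2": cfg.dose_high,
            "time_s": cfg.time,
            "coverage_threshold": cfg.coverage_threshold,
            "nsf_radius_cm": cfg.nsf_radius,
            "power_min_mw_cm": cfg.power_min,
            "power_max_mw_cm": cfg.power_max,
            "power_step_mw_cm": cfg.power_step,
            "max_fibers": cfg.max_fibers,
            "pitch_cm": cfg.pitch,
            "n_points": cfg.n_points,
            "start_slice": cfg.start_slice,
        },
        "fibers": [
            {
                "center_cm": [round(c, 4) for c in f.center],
                "axis": [round(a, 6) for a in f.axis],
                "length_cm": round(f.length, 4),
                "linear_power_mw_cm": int(round(f.linear_power)),
            }
            for f in plan.placement.fibers
        ],
        "sector_angle_deg": plan.placement.sector_angle,
        "gravity_distance_cm": (
            None
            if plan.placement.gravity_distance is None
            else round(plan.placement.gravity_distance, 4)
        ),
        "surrounding_length_cm": (
            None
            if plan.placement.surrounding_length is None
            else round(plan.placement.surrounding_length, 4)
        ),
        "central_power_mw_cm": int(round(plan.central_power)),
        "surrounding_power_mw_cm": (
            None if plan.surrounding_power is None else int(round(plan.surrounding_power))
        ),
        "reaches_up_to_slice": plan.reaches_up_to_slice,
        "per_slice_ratio_pct": [round(r, 1) for r in plan.per_slice_ratio.tolist()],
        "total_ratio_pct": round(plan.total_ratio, 1),
        "n_fibers_used": plan.n_fibers_used,
        "s1_feasible": plan.s1_feasible,
        "s2_feasible": plan.s2_feasible,
        "escalated": plan.escalated,
    }
    if plan.four_fiber_record is not None:
        rec = plan.four_fiber_record
        record["four_fiber_record"] = {
            "surrounding_power_mw_cm": int(round(rec["surrounding_power"])),
            "s2_feasible": rec["s2_feasible"],
            "per_slice_ratio_pct": [round(r, 1) for r in rec["per_slice_ratio"].tolist()],
            "total_ratio_pct": round(rec["total_ratio"], 1),
        }
    return record


def export_plan(plan: TreatmentPlan, out_dir) -> dict[str, Path]:
    """Write plan.json, slices.csv and dose.nrrd under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["plan"] = out_dir / "plan.json"
    _write_text(
        paths["plan"], json.dumps(plan_record(plan), sort_keys=True, indent=2) + "\n"
    )

    node = build_plan_node(plan)
    rows = []
    for k in range(1, node.n_slices + 1):
        z0, z1 = node.slice_z_range(k)
        rows.append(
            {
                "slice": k,
                "z_min_cm": f"{z0:.4f}",
                "z_max_cm": f"{z1:.4f}",
                "n_voxels": int(np.count_nonzero(node.slice_mask(k))),
                "ratio_pct": f"{plan.per_slice_ratio[k - 1]:.1f}",
            }
        )
    paths["slices"] = out_dir / "slices.csv"
    _write_text(paths["slices"], pd.DataFrame(rows).to_csv(index=False))

    grid, origin = dose_grid(plan)
    paths["dose"] = out_dir / "dose.nrrd"
    write_nrrd(paths["dose"], grid, spacing=plan.config.pitch, origin=origin)
    return paths


def build_plan_node(plan: TreatmentPlan):
    from .geometry import build_node

    return build_node(plan.diameter, plan.config.pitch)


def dose_grid(plan: TreatmentPlan) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Dose on the full cubic voxel grid, NaN outside the sphere, J/cm^2."""
    from .planner import DoseField

    node = build_plan_node(plan)
    field = DoseField(node, plan.placement.fibers, plan.props, plan.config.time)
    powers = np.array([f.linear_power for f in plan.placement.fibers])
    dose = field.dose(powers)
    n = node.n_slices
    grid = np.full((n, n, n), np.nan)
    idx = np.rint(
        (node.voxel_centers + node.radius) / node.pitch - 0.5
    ).astype(int)
    grid[idx[:, 0], idx[:, 1], idx[:, 2]] = dose
    origin = tuple([-node.radius + 0.5 * node.pitch] * 3)
    return grid, origin


# --- minimal ASCII NRRD I/O -------------------------------------------------
# The dose grids are regular scalar volumes; the ASCII encoding keeps the
# files plain text and round-trips float64 exactly (shortest-repr printing).

def write_nrrd(path, array: np.ndarray, *, spacing: float, origin) -> Path:
    path = Path(path)
    a = np.asarray(array, dtype=float)
    if a.ndim != 3:
        raise ValueError("expected a 3-D array")
    header = [
        "NRRD0004",
        "type: double",
        "dimension: 3",
        f"sizes: {a.shape[0]} {a.shape[1]} {a.shape[2]}",
        "encoding: ascii",
        "space dimension: 3",
        f"space directions: ({spacing!r},0,0) (0,{spacing!r},0) (0,0,{spacing!r})",
        f"space origin: ({origin[0]!r},{origin[1]!r},{origin[2]!r})",
    ]
    # fastest axis first per NRRD convention; blank line separates the header
    body = "\n".join(repr(float(v)) for v in a.ravel(order="F"))
    _write_text(path, "\n".join(header) + "\n\n" + body + "\n")
    return path


def read_nrrd(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    lines = path.read_text().split("\n")
    if not lines[0].startswith("NRRD"):
        raise ValueError(f"{path} is not a NRRD file")
    header: dict[str, str] = {}
    i = 1
    while i < len(lines) and lines[i].strip():
        if not lines[i].startswith("#"):
            key, _, value = lines[i].partition(":")
            header[key.strip()] = value.strip()
        i += 1
    if header.get("encoding") != "ascii":
        raise ValueError("only ascii-encoded NRRD is supported")
    sizes = tuple(int(s) for s in header["sizes"].split())
    values = np.array(
        [float(v) for v in " ".join(lines[i + 1 :]).split()], dtype=float
    )
    return values.reshape(sizes, order="F"), header


def _write_text(path: Path, text: str) -> None:
    try:
        path.write_text(text)
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
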