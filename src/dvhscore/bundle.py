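"""Native plan-bundle and DVH-table I/O.

A plan bundle is a directory::

    plan.json          # plan_id, rx_gy, fractions, structure file map
    dose.nrrd          # 32-bit float dose, Gy
    masks/<file>.nrrd  # one 8-bit occupancy volume per structure

Volumes are NRRD (standard, compact, language-neutral); metadata is JSON.
Structure names may contain characters that are awkward in filenames
(``_Brain&BODY``), so ``plan.json`` carries an explicit name -> file map.

DVH tables use a three-column CSV (``structure, dose_gy, cum_volume_cc``,
one row per bin edge) matching common TPS cumulative-DVH exports; importing
one yields a DVH-only plan on which every metric except the conformation
number can be scored.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .dvh import DoseGrid, DVHCurve, StructureMask
from .errors import BundleError
from .scoring import PlanRecord
from .structures import StructureSet

_META = "plan.json"
_DOSE = "dose.nrrd"


def _write_volume(path: Path, values: np.ndarray, spacing, origin, dtype) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.astype(dtype)))
    # SimpleITK orders spacing/origin (x, y, z); arrays are (z, y, x)
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
    img.SetOrigin(tuple(float(o) for o in origin[::-1]))
    sitk.WriteImage(img, str(path), useCompression=False)


def _read_volume(path: Path):
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img)
    spacing = tuple(img.GetSpacing()[::-1])
    origin = tuple(img.GetOrigin()[::-1])
    return values, spacing, origin


def _safe_filename(name: str, taken: set[str]) -> str:
    base = re.sub(r"[^A-Za-z0-9._-]", "_", name) or "structure"
    candidate, i = base, 1
    while candidate in taken:
        candidate = f"{base}_{i}"
        i += 1
    taken.add(candidate)
    return candidate


def write_plan_bundle(plan: PlanRecord, path) -> None:
    """Serialize a dose-grid-backed plan to a bundle directory."""
    if plan.dose is None or plan.structures is None:
        raise BundleError("only dose-grid-backed plans can be written as bundles")
    path = Path(path)
    (path / "masks").mkdir(parents=True, exist_ok=True)
    _write_volume(path / _DOSE, plan.dose.values, plan.dose.spacing,
                  plan.dose.origin, np.float32)
    taken: set[str] = set()
    files = {}
    for name in plan.structures.names():
        mask = plan.structures[name]
        fname = _safe_filename(name, taken) + ".nrrd"
        files[name] = fname
        _write_volume(path / "masks" / fname, mask.occupancy > 0.5,
                      mask.spacing, mask.origin, np.uint8)
    meta = {
        "plan_id": plan.plan_id,
        "rx_gy": plan.rx_gy,
        "fractions": plan.fractions,
        "structure_files": files,
        "aliases": plan.aliases,
    }
    (path / _META).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_plan_bundle(path) -> PlanRecord:
    """Load a bundle directory back into a :class:`PlanRecord`.

    Raises :class:`BundleError` naming any missing or geometry-mismatched
    file.
    """
    path = Path(path)
    meta_path = path / _META
    if not meta_path.exists():
        raise BundleError(f"missing metadata file {meta_path}")
    meta = json.loads(meta_path.read_text())
    dose_path = path / _DOSE
    if not dose_path.exists():
        raise BundleError(f"missing dose volume {dose_path}")
    values, spacing, origin = _read_volume(dose_path)
    dose = DoseGrid(values, spacing, origin)
    structures = StructureSet()
    for name, fname in meta.get("structure_files", {}).items():
        mpath = path / "masks" / fname
        if not mpath.exists():
            raise BundleError(f"missing mask volume {mpath} for structure '{name}'")
        occ, msp, morig = _read_volume(mpath)
        if occ.shape != values.shape or not np.allclose(msp, spacing):
            raise BundleError(
                f"mask '{name}' geometry {occ.shape}@{msp} does not match "
                f"dose {values.shape}@{spacing}"
            )
        structures.add(StructureMask(name, occ.astype(np.float64), msp, morig))
    return PlanRecord(
        plan_id=str(meta.get("plan_id", path.name)),
        rx_gy=float(meta["rx_gy"]),
        fractions=int(meta.get("fractions", 0)),
        dose=dose,
        structures=structures,
        aliases=dict(meta.get("aliases", {})),
    )


# ---------------------------------------------------------------------------
# DVH tables


def export_dvh_csv(dvhs: dict[str, DVHCurve], path) -> None:
    """Write cumulative DVHs as ``structure, dose_gy, cum_volume_cc`` rows."""
    frames = [
        pd.DataFrame(
            {
                "structure": name,
                "dose_gy": curve.dose_edges,
                "cum_volume_cc": curve.cum_volume_cc,
            }
        )
        for name, curve in dvhs.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def import_dvh_csv(path) -> dict[str, DVHCurve]:
    """Read a cumulative DVH table back into curves (one per structure).

    Edges must be ascending per structure and start at 0 Gy; summary
    statistics fall back to curve-derived values.
    """
    df = pd.read_csv(path)
    required = {"structure", "dose_gy", "cum_volume_cc"}
    if not required.issubset(df.columns):
        raise BundleError(
            f"DVH table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    out: dict[str, DVHCurve] = {}
    for name, grp in df.groupby("structure", sort=False):
        edges = grp["dose_gy"].to_numpy(dtype=float)
        cum = grp["cum_volume_cc"].to_numpy(dtype=float)
        widths = np.diff(edges)
        out[str(name)] = DVHCurve(
            dose_edges=edges,
            cum_volume_cc=cum,
            total_volume_cc=float(cum[0]),
            bin_width=float(np.median(widths)),
            structure=str(name),
        )
    return out


def plan_from_dvh_csv(path, plan_id: str, rx_gy: float, fractions: int = 0) -> PlanRecord:
    """A DVH-only plan from a TPS cumulative-DVH export."""
    return PlanRecord(
        plan_id=plan_id, rx_gy=rx_gy, fractions=fractions,
        dvhs=import_dvh_csv(path),
    )
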