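"""Dose grids, structure masks, and cumulative dose-volume histograms.

The cumulative DVH is the substrate of every plan-quality metric in this
package: ``D_x%`` / ``D_xcc`` (minimum dose to the hottest x percent / x cc
of a structure), ``V_d`` (volume receiving at least dose ``d``), mean/max/min
dose, the homogeneity index ``HI = (D1% - D99%) / Rx`` and the van't Riet
conformation number ``CN = (TV_D / TV) * (TV_D / V_D)``.

Conventions (fixed, to avoid silent transposition bugs):

* grids are indexed ``(z, y, x)``, 0-based;
* ``spacing`` is per-axis voxel size in mm, ``origin`` the position of the
  center of voxel ``(0, 0, 0)`` in mm;
* volumes are reported in cc (mm^3 / 1000);
* cumulative curves are tabulated on ascending dose-bin edges (default bin
  width 0.05 Gy) and linearly interpolated in both inversion directions;
* for a request sitting on a plateau of the cumulative curve, ``D_x`` is the
  *largest* dose whose cumulative volume still meets the request.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyStructure, GeometryMismatch, VolumeExceedsStructure

log = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH_GY = 0.05


@dataclass(frozen=True)
class DoseGrid:
    """A 3-D grid of absorbed dose.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Absorbed dose per voxel, Gy. Must be finite and non-negative.
    spacing : 3-tuple of float
        Voxel size per axis (z, y, x), mm; strictly positive.
    origin : 3-tuple of float
        Position of the center of voxel (0, 0, 0), mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3 or min(values.shape) < 1:
            raise ValueError("dose grid must be 3-D with >= 1 voxel per axis")
        if not np.all(np.isfinite(values)) or values.min() < 0:
            raise ValueError("dose values must be finite and non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or min(spacing) <= 0:
            raise ValueError("spacing must be three strictly positive values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def scaled(self, factor: float) -> "DoseGrid":
        """Return a copy with every dose multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("dose scaling factor must be positive")
        return DoseGrid(self.values * factor, self.spacing, self.origin)


@dataclass(frozen=True)
class StructureMask:
    """A named structure as per-voxel occupancy weights in [0, 1].

    Occupancy is binary (voxel center in/out) in all shipped generators;
    fractional weights from supersampled rasterization are accepted
    everywhere volumes or DVHs are computed.
    """

    name: str
    occupancy: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        occ = np.asarray(self.occupancy)
        if occ.dtype == bool:
            occ = occ.astype(np.float64)
        else:
            occ = occ.astype(np.float64)
            if occ.size and (occ.min() < 0 or occ.max() > 1):
                raise ValueError("occupancy weights must lie in [0, 1]")
        if occ.ndim != 3:
            raise ValueError("occupancy must be a 3-D array")
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def volume_cc(self) -> float:
        return float(self.occupancy.sum()) * self.voxel_volume_cc

    def same_geometry(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def _check_aligned(dose: DoseGrid, mask: StructureMask) -> None:
    if dose.shape != mask.shape or not np.allclose(dose.spacing, mask.spacing):
        raise GeometryMismatch(
            f"dose grid {dose.shape}@{dose.spacing} vs mask '{mask.name}' "
            f"{mask.shape}@{mask.spacing}"
        )


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume curve of one structure.

    ``cum_volume_cc[i]`` is the absolute volume receiving at least
    ``dose_edges[i]`` Gy. The curve starts at (0 Gy, total volume), is
    non-increasing, and reaches 0 beyond the maximum structure dose.
    ``min/mean/max_dose_gy`` carry voxel-exact statistics when the curve was
    computed from a dose grid; curves imported from TPS DVH tables fall back
    to curve-derived values.
    """

    dose_edges: np.ndarray
    cum_volume_cc: np.ndarray
    total_volume_cc: float
    bin_width: float
    min_dose_gy: float | None = None
    mean_dose_gy: float | None = None
    max_dose_gy: float | None = None
    structure: str = field(default="", compare=False)

    def __post_init__(self):
        edges = np.asarray(self.dose_edges, dtype=np.float64)
        cum = np.asarray(self.cum_volume_cc, dtype=np.float64)
        if edges.ndim != 1 or edges.size < 2 or cum.shape != edges.shape:
            raise ValueError("dose_edges/cum_volume_cc must be matching 1-D arrays")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("dose_edges must be strictly ascending")
        if np.any(np.diff(cum) > 1e-9 * max(1.0, cum[0])):
            raise ValueError("cumulative volume must be non-increasing")
        object.__setattr__(self, "dose_edges", edges)
        object.__setattr__(self, "cum_volume_cc", np.maximum(cum, 0.0))

    # -- curve-derived summary statistics (exact values preferred when set) --

    @property
    def max_dose(self) -> float:
        """Maximum structure dose, Gy (voxel max when available)."""
        if self.max_dose_gy is not None:
            return self.max_dose_gy
        nz = np.nonzero(self.cum_volume_cc > 0)[0]
        if nz.size == 0:
            return 0.0
        i = nz[-1]
        if i + 1 < self.dose_edges.size:
            return float(self.dose_edges[i + 1])
        return float(self.dose_edges[i])

    @property
    def min_dose(self) -> float:
        """Minimum structure dose, Gy (voxel min when available)."""
        if self.min_dose_gy is not None:
            return self.min_dose_gy
        return dose_at_volume(self, 100.0, "percent")

    @property
    def mean_dose(self) -> float:
        """Mean structure dose, Gy (voxel-weighted mean when available)."""
        if self.mean_dose_gy is not None:
            return self.mean_dose_gy
        # differential volume per bin x bin-center dose
        diff = -np.diff(self.cum_volume_cc)
        centers = 0.5 * (self.dose_edges[:-1] + self.dose_edges[1:])
        if self.total_volume_cc <= 0:
            return 0.0
        return float((diff * centers).sum() / self.total_volume_cc)

    def scaled(self, factor: float) -> "DVHCurve":
        """The curve of the same plan with all doses multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("dose scaling factor must be positive")
        return DVHCurve(
            self.dose_edges * factor,
            self.cum_volume_cc.copy(),
            self.total_volume_cc,
            self.bin_width * factor,
            None if self.min_dose_gy is None else self.min_dose_gy * factor,
            None if self.mean_dose_gy is None else self.mean_dose_gy * factor,
            None if self.max_dose_gy is None else self.max_dose_gy * factor,
            self.structure,
        )


def compute_dvh(
    dose: DoseGrid, mask: StructureMask, bin_width: float = DEFAULT_BIN_WIDTH_GY
) -> DVHCurve:
    """Cumulative DVH of ``mask`` on ``dose``.

    Builds a differential histogram on edges ``0, h, 2h, ...`` (h =
    ``bin_width``) extending one bin past the maximum structure dose, then
    accumulates from the top. The value at edge ``d`` is exactly the
    occupancy-weighted volume with dose >= ``d``; between edges the curve is
    interpolated linearly by the query functions.

    Raises
    ------
    EmptyStructure
        if the mask has zero total volume.
    GeometryMismatch
        if mask and dose are not on the same grid.
    """
    _check_aligned(dose, mask)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sel = mask.occupancy > 0
    weights = mask.occupancy[sel] * mask.voxel_volume_cc
    if weights.size == 0 or weights.sum() <= 0:
        raise EmptyStructure(f"structure '{mask.name}' has zero volume")
    doses = dose.values[sel]
    dmax = float(doses.max())
    n_bins = int(np.floor(dmax / bin_width)) + 2
    edges = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(doses, bins=edges, weights=weights)
    cum = np.concatenate([np.cumsum(hist[::-1])[::-1], [0.0]])
    total = float(weights.sum())
    # guard against fp accumulation drift at the 0-Gy edge
    cum[0] = total
    return DVHCurve(
        dose_edges=edges,
        cum_volume_cc=cum,
        total_volume_cc=total,
        bin_width=float(bin_width),
        min_dose_gy=float(doses.min()),
        mean_dose_gy=float(np.average(doses, weights=weights)),
        max_dose_gy=dmax,
        structure=mask.name,
    )


def dose_at_volume(dvh: DVHCurve, volume: float, unit: str = "percent") -> float:
    """``D_x``: the largest dose at which the cumulative volume still meets
    the request (linear interpolation between bin edges).

    Parameters
    ----------
    volume : float
        Requested volume; percent of the structure volume in (0, 100] when
        ``unit == "percent"``, absolute cc when ``unit == "cc"``.

    ``D100%`` returns the minimum structure dose. A cc request larger than
    the structure (e.g. D0.03cc on a 0.02 cc structure) degrades to the
    maximum dose with a warning, for batch robustness.
    """
    if unit == "percent":
        if not 0 < volume <= 100:
            raise VolumeExceedsStructure(
                f"percent volume must be in (0, 100], got {volume}"
            )
        v_cc = volume / 100.0 * dvh.total_volume_cc
    elif unit == "cc":
        if volume <= 0:
            raise VolumeExceedsStructure(f"cc volume must be positive, got {volume}")
        v_cc = volume
        if v_cc > dvh.total_volume_cc:
            warnings.warn(
                f"requested {volume:g} cc exceeds structure "
                f"'{dvh.structure}' volume {dvh.total_volume_cc:.4g} cc; "
                "reporting maximum dose",
                stacklevel=2,
            )
            return dvh.max_dose
    else:
        raise ValueError(f"unknown volume unit {unit!r}")

    edges, cum = dvh.dose_edges, dvh.cum_volume_cc
    meets = cum >= v_cc - 1e-12 * max(1.0, dvh.total_volume_cc)
    idx = np.nonzero(meets)[0]
    if idx.size == 0:  # v_cc > total within fp noise
        return float(edges[0])
    i = int(idx[-1])
    if i == edges.size - 1:
        return float(edges[i])
    c0, c1 = cum[i], cum[i + 1]
    if c0 <= c1:  # flat segment, cannot interpolate
        return float(edges[i])
    frac = (c0 - v_cc) / (c0 - c1)
    frac = min(max(frac, 0.0), 1.0)
    return float(edges[i] + frac * (edges[i + 1] - edges[i]))


def volume_at_dose(dvh: DVHCurve, dose_level: float, out_unit: str = "percent") -> float:
    """``V_d``: cumulative volume at ``dose_level`` Gy, linearly interpolated.

    ``out_unit`` is ``"percent"`` (of the structure's own volume) or ``"cc"``.
    """
    if dose_level < 0:
        raise ValueError("dose level must be non-negative")
    edges, cum = dvh.dose_edges, dvh.cum_volume_cc
    if dose_level >= edges[-1]:
        v_cc = 0.0
    else:
        v_cc = float(np.interp(dose_level, edges, cum))
    if out_unit == "cc":
        return v_cc
    if out_unit == "percent":
        if dvh.total_volume_cc <= 0:
            return 0.0
        return 100.0 * v_cc / dvh.total_volume_cc
    raise ValueError(f"unknown volume unit {out_unit!r}")


def homogeneity_index(dvh: DVHCurve, rx: float) -> float:
    """Homogeneity index ``HI = (D1% - D99%) / Rx``; 0 for a uniform target."""
    if rx <= 0:
        raise ValueError("prescription dose must be positive")
    d1 = dose_at_volume(dvh, 1.0, "percent")
    d99 = dose_at_volume(dvh, 99.0, "percent")
    return max(d1 - d99, 0.0) / rx


def conformation_number(
    dose: DoseGrid,
    target: StructureMask,
    body: StructureMask,
    dose_level: float,
) -> float:
    """van't Riet conformation number of the ``dose_level`` isodose.

    ``CN = (TV_D / TV) * (TV_D / V_D)`` with ``TV`` the target volume,
    ``TV_D`` the target volume receiving >= ``dose_level`` and ``V_D`` the
    body volume receiving >= ``dose_level``. 1 iff the isodose surface
    coincides exactly with the target; 0 if nothing receives the dose level.
    Evaluated voxel-exactly (no DVH binning).
    """
    _check_aligned(dose, target)
    _check_aligned(dose, body)
    if dose_level <= 0:
        raise ValueError("dose level must be positive")
    tv = target.occupancy.sum()
    if tv <= 0:
        raise EmptyStructure(f"target '{target.name}' is empty")
    if body.occupancy.sum() <= 0:
        raise EmptyStructure(f"body '{body.name}' is empty")
    hot = dose.values >= dose_level
    tv_d = float(target.occupancy[hot].sum())
    v_d = float(body.occupancy[hot].sum())
    if v_d <= 0:
        return 0.0
    return (tv_d / float(tv)) * (tv_d / v_d)
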