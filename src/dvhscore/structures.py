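"""Boolean and margin operations on structure masks.

Scorecards reference derived evaluation structures that a treatment-planning
system generates on the fly — e.g. ``_Brain&BODY`` (brain clipped to the
body), ``_Eyes&BODY`` (both eyes clipped to the body) or the hippocampal
avoidance region (hippocampi expanded by 5 mm). This module provides the
primitive operations and a small, serializable recipe language for them.

Margin expansion uses an exact Euclidean distance transform on voxel
centers with anisotropic spacing respected: a voxel belongs to the expanded
structure iff its center lies within ``margin_mm`` of any structure voxel
center. Deterministic and directly checkable against a brute-force
pairwise-distance oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import GeometryMismatch, MissingStructure
from .dvh import StructureMask

BOOLEAN_OPS = ("union", "intersection", "difference")


def boolean_combine(a: StructureMask, b: StructureMask, op: str) -> StructureMask:
    """Voxelwise union (max), intersection (min) or difference (max(a-b, 0)).

    On binary masks these coincide with the set operations; on fractional
    occupancies they are the standard fuzzy-set forms.
    """
    if not a.same_geometry(b):
        raise GeometryMismatch(f"'{a.name}' and '{b.name}' are on different grids")
    if op == "union":
        occ = np.maximum(a.occupancy, b.occupancy)
        name = f"{a.name}|{b.name}"
    elif op == "intersection":
        occ = np.minimum(a.occupancy, b.occupancy)
        name = f"{a.name}&{b.name}"
    elif op == "difference":
        occ = np.maximum(a.occupancy - b.occupancy, 0.0)
        name = f"{a.name}-{b.name}"
    else:
        raise ValueError(f"unknown boolean op {op!r}; expected one of {BOOLEAN_OPS}")
    return StructureMask(name, occ, a.spacing, a.origin)


def expand_margin(mask: StructureMask, margin_mm: float) -> StructureMask:
    """Isotropic outward expansion by ``margin_mm`` (Euclidean, in mm).

    The result contains every voxel whose center is within ``margin_mm`` of
    the center of an occupied voxel; it is always a superset of the input
    and monotone in the margin. Fractional occupancies are thresholded at
    0.5 before the distance transform.
    """
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    inside = mask.occupancy >= 0.5
    if margin_mm == 0 or not inside.any():
        return StructureMask(mask.name, mask.occupancy.copy(), mask.spacing, mask.origin)
    dist = ndimage.distance_transform_edt(~inside, sampling=mask.spacing)
    occ = (dist <= margin_mm + 1e-9).astype(np.float64)
    return StructureMask(f"{mask.name}+{margin_mm:g}mm", occ, mask.spacing, mask.origin)


@dataclass(frozen=True)
class StructureRecipe:
    """One derived-structure rule: a boolean of two operands or an expansion.

    Recipes are evaluated in order, so a recipe may consume the output of an
    earlier one (e.g. ``_Eyes = Eye_L | Eye_R`` then
    ``_Eyes&BODY = _Eyes & BODY``).
    """

    output_name: str
    operation: str  # union | intersection | difference | expand
    operands: tuple[str, ...]
    margin_mm: float = 0.0

    def __post_init__(self):
        if self.operation == "expand":
            if len(self.operands) != 1:
                raise ValueError("expand takes exactly one operand")
            if self.margin_mm < 0:
                raise ValueError("margin_mm must be non-negative")
        elif self.operation in BOOLEAN_OPS:
            if len(self.operands) != 2:
                raise ValueError(f"{self.operation} takes exactly two operands")
        else:
            raise ValueError(f"unknown recipe operation {self.operation!r}")
        object.__setattr__(self, "operands", tuple(self.operands))

    def to_dict(self) -> dict:
        d = {
            "output_name": self.output_name,
            "operation": self.operation,
            "operands": list(self.operands),
        }
        if self.operation == "expand":
            d["margin_mm"] = self.margin_mm
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StructureRecipe":
        return cls(
            output_name=d["output_name"],
            operation=d["operation"],
            operands=tuple(d["operands"]),
            margin_mm=float(d.get("margin_mm", 0.0)),
        )


# Default derived-structure set shipped with the built-in scorecards.
# ``_BrainStem#Hi`` (scored by a D95% coverage metric) is interpreted as the
# brainstem portion inside the PTV; the recipe is data and can be overridden
# per scorecard file.
DEFAULT_RECIPES: tuple[StructureRecipe, ...] = (
    StructureRecipe("HippoAvoid", "expand", ("Hippocampi",), margin_mm=5.0),
    StructureRecipe("PTV_WB", "difference", ("Brain", "HippoAvoid")),
    StructureRecipe("_Brain&BODY", "intersection", ("Brain", "BODY")),
    StructureRecipe("_Eyes", "union", ("Eye_L", "Eye_R")),
    StructureRecipe("_Eyes&BODY", "intersection", ("_Eyes", "BODY")),
    StructureRecipe("_BrainStem#Hi", "intersection", ("BrainStem", "PTV_WB")),
)


@dataclass
class StructureSet:
    """An ordered mapping of structure name -> mask on one grid geometry."""

    masks: dict[str, StructureMask] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> StructureMask:
        try:
            return self.masks[name]
        except KeyError:
            raise MissingStructure(name) from None

    def __iter__(self):
        return iter(self.masks)

    def names(self) -> list[str]:
        return list(self.masks)

    def add(self, mask: StructureMask) -> None:
        self.masks[mask.name] = mask

    def apply_recipes(
        self, recipes: "tuple[StructureRecipe, ...] | list[StructureRecipe]",
        overwrite: bool = False,
    ) -> "StructureSet":
        """Evaluate recipes in order, adding outputs to this set (in place).

        Recipes whose output already exists are skipped unless ``overwrite``;
        recipes with a missing operand raise :class:`MissingStructure`.
        """
        for r in recipes:
            if r.output_name in self.masks and not overwrite:
                continue
            if r.operation == "expand":
                out = expand_margin(self[r.operands[0]], r.margin_mm)
            else:
                out = boolean_combine(self[r.operands[0]], self[r.operands[1]], r.operation)
            self.masks[r.output_name] = StructureMask(
                r.output_name, out.occupancy, out.spacing, out.origin
            )
        return self
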