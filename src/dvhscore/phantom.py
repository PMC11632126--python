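"""Seeded synthetic cranial phantom: anatomy masks + parametric dose fields.

Stands in for patient plans: a desk-scale head (ellipsoidal BODY and brain,
bilateral hippocampi as curved tubes, anterior eyes/lenses/lacrimal glands,
optic nerves and chiasm, brainstem and inferior spinal cord) plus a
whole-brain dose field with a controllable hippocampal sparing dip,
coverage level, hotspot and falloff. The dose model is deliberately crude —
Gaussian-blurred indicators, no beam physics — but spans the
coverage-vs-sparing trade-off the scorecards measure, with every knob
mapped to a named clinical quantity:

* ``coverage`` — fraction of the PTV receiving at least the prescription
  (the V100% the plan is normalized to);
* ``dip_depth`` — fractional dose reduction at the hippocampal center;
* ``dip_sigma_mm`` — width of the sparing dip: a small sigma confines the
  low dose to the hippocampal core (steep interior gradient, higher
  near-max hippocampal dose), a large sigma spares the whole structure;
* ``hotspot_pct`` — approximate global maximum as percent of prescription;
* ``falloff_mm`` — dose shoulder width outside the brain (conformity).

All randomness comes from one ``numpy`` generator seeded by ``cfg.seed``;
identical config -> voxel-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .dvh import DoseGrid, StructureMask
from .errors import ConfigError
from .structures import DEFAULT_RECIPES, StructureSet

HIPPO_AVOID_MARGIN_MM = 5.0


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry + dose parameters of one synthetic plan."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    rx_gy: float = 20.0
    fractions: int = 5
    coverage: float = 0.98
    dip_depth: float = 0.70
    dip_sigma_mm: float = 6.0
    hotspot_pct: float = 105.0
    dip_exponent: float = 4.0
    falloff_mm: float = 6.0
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.coverage <= 1.0 and 0.0 <= self.dip_depth <= 1.0):
            raise ConfigError("coverage and dip_depth must lie in [0, 1]")
        if min(self.dip_sigma_mm, self.falloff_mm) <= 0:
            raise ConfigError("dip_sigma_mm and falloff_mm must be positive")
        if self.dip_exponent < 2:
            raise ConfigError("dip_exponent must be >= 2")
        if self.rx_gy <= 0 or self.hotspot_pct < 100:
            raise ConfigError("rx_gy must be > 0 and hotspot_pct >= 100")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


def _coords_mm(shape, spacing):
    """Voxel-center coordinate grids (z, y, x) in mm, origin at grid center."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(z, y, x, center, semi):
    cz, cy, cx = center
    az, ay, ax_ = semi
    return ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax_) ** 2 <= 1.0


def _tube(z, y, x, points, radius):
    """Union of spheres along a polyline sample — a curved tube."""
    out = np.zeros(z.shape, dtype=bool)
    for pz, py, px in points:
        out |= (z - pz) ** 2 + (y - py) ** 2 + (x - px) ** 2 <= radius**2
    return out


def build_phantom(cfg: PhantomConfig) -> StructureSet:
    """The structure set of the cranial phantom.

    Conventions: +y is anterior (eyes at negative... eyes sit at the
    *anterior* margin, placed at positive y here), +z is superior. All
    masks are binary, on the ``(z, y, x)`` grid of the config. Raises
    :class:`ConfigError` if any structure rasterizes to zero voxels at the
    requested resolution.
    """
    shape, spacing = cfg.grid_shape, cfg.spacing_mm
    z, y, x = _coords_mm(shape, spacing)
    s = StructureSet()

    def add(name, occ):
        if not occ.any():
            raise ConfigError(
                f"structure '{name}' is empty at grid {shape} / spacing {spacing}"
            )
        s.add(StructureMask(name, occ.astype(np.float64), spacing))

    # head: BODY ellipsoid; brain inside with ~8 mm scalp/skull gap
    add("BODY", _ellipsoid(z, y, x, (0, 0, 0), (58, 66, 54)))
    add("Brain", _ellipsoid(z, y, x, (2, -2, 0), (46, 50, 42)))

    # bilateral hippocampi: curved tubes in the medial temporal region
    t = np.linspace(0, 1, 12)
    for side, sign in (("_L", -1), ("_R", 1)):
        pz = -10 + 14 * t
        py = -26 + 34 * t
        px = sign * (22 - 6 * np.sin(np.pi * t))
        pts = np.stack([pz, py, px], axis=1)
        if side == "_L":
            hippo = _tube(z, y, x, pts, 4.5)
        else:
            hippo |= _tube(z, y, x, pts, 4.5)
    add("Hippocampi", hippo)

    # anterior-inferior optic apparatus, clear of the brain ellipsoid
    eye_c = {"_L": (-26, 45, -16), "_R": (-26, 45, 16)}
    for side, c in eye_c.items():
        add(f"Eye{side}", (z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2 <= 8**2)
        add(
            f"Lens{side}",
            (z - c[0]) ** 2 + (y - (c[1] + 6.5)) ** 2 + (x - c[2]) ** 2 <= 3.0**2,
        )
        lg = (c[0] + 6, c[1] - 2, c[2] + (8 if side == "_R" else -8))
        add(
            f"LacrimalGland{side}",
            (z - lg[0]) ** 2 + (y - lg[1]) ** 2 + (x - lg[2]) ** 2 <= 4.5**2,
        )
        n0 = np.array([c[0], c[1] - 8, c[2]], dtype=float)
        n1 = np.array([-4.0, 6.0, 0.0])  # toward the chiasm
        pts = n0[None, :] + (n1 - n0)[None, :] * t[:, None]
        add(f"OpticNerve{side}", _tube(z, y, x, pts, 2.5))

    add("OpticChiasm", (z + 4) ** 2 + ((y - 6) / 1.4) ** 2 + (x / 1.8) ** 2 <= 4**2)

    # brainstem: inferior-central cylinder; cord continues below the brain
    add("BrainStem", (((y + 8) ** 2 + x**2) <= 9**2) & (z >= -40) & (z <= -6))
    add("SpinalCord", (((y + 8) ** 2 + x**2) <= 5**2) & (z < -40))

    # derived: 5 mm avoidance region and the whole-brain PTV
    s.apply_recipes(
        [r for r in DEFAULT_RECIPES if r.output_name in ("HippoAvoid", "PTV_WB")]
    )
    if not s["PTV_WB"].occupancy.any():
        raise ConfigError("PTV_WB is empty")
    return s


def simulate_dose(phantom: StructureSet, cfg: PhantomConfig) -> DoseGrid:
    """Parametric whole-brain dose with a hippocampal sparing dip.

    ``dose = s * Rx * B * (1 - dip_depth * H) * (1 + hotspot bump) * (1 + noise)``
    with three ingredients:

    * ``B`` — the coverage plateau: the brain indicator blurred with
      ``falloff_mm`` and clipped so the plateau value 1 extends to the
      brain surface and the Gaussian shoulder lies *outside* the target;
    * ``H`` — the sparing dip ``exp(-(D / dip_sigma)^p)`` where ``D`` is
      the Euclidean distance (mm) to the hippocampal center line
      (recovered from the mask via distance transforms): 1 on the center
      line, falling through the hippocampus and the 5 mm avoidance margin.
      The exponent ``p = dip_exponent`` sets the gradient steepness: a
      supergaussian (p = 4) confines the sparing gradient to the 5 mm
      avoidance margin (high coverage, higher near-max hippocampal dose),
      a Gaussian (p = 2) skirt bleeds into the PTV, trading target
      coverage for deeper sparing of the whole structure — the coverage
      deficit is then geometric, exactly like the penumbra around a real
      avoidance region, and cannot be bought back by a small global dose
      upscale; ``dip_sigma_mm`` scales the dip width;
    * ``s`` — a global factor fixing the (1 - coverage) quantile of the
      noisy dose over the PTV to exactly Rx, so PTV V100% equals
      ``coverage`` by construction.

    Deterministic per seed.
    """
    spacing = np.asarray(cfg.spacing_mm)
    hippo = phantom["Hippocampi"].occupancy >= 0.5
    brain = phantom["Brain"].occupancy
    ptv = phantom["PTV_WB"].occupancy > 0.5

    # plateau: blurred brain renormalized so the 0.5-level (the brain
    # surface for a blurred indicator) maps to 1, then clipped; the
    # Gaussian shoulder of width falloff_mm lies outside the target
    b = ndimage.gaussian_filter(brain, sigma=cfg.falloff_mm / spacing)
    b = np.clip(b / 0.45, 0.0, 1.0)

    # distance to the hippocampal center line: depth inside + radius outside
    depth_in = ndimage.distance_transform_edt(hippo, sampling=spacing)
    radius = float(depth_in.max())
    dist_out = ndimage.distance_transform_edt(~hippo, sampling=spacing)
    d_center = np.where(hippo, radius - depth_in, radius + dist_out)
    h = np.exp(-((d_center / cfg.dip_sigma_mm) ** cfg.dip_exponent))

    zz, yy, xx = _coords_mm(cfg.grid_shape, cfg.spacing_mm)
    idx = np.argwhere(ptv)
    c_mm = (idx.mean(axis=0) - (np.asarray(cfg.grid_shape) - 1) / 2.0) * spacing
    r2 = (zz - c_mm[0]) ** 2 + (yy - c_mm[1]) ** 2 + (xx - c_mm[2]) ** 2
    bump = 1.0 + (cfg.hotspot_pct / 100.0 - 1.0) * np.exp(-r2 / (2 * 22.0**2))

    pre = b * (1.0 - cfg.dip_depth * h) * bump
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        pre = pre * (1.0 + cfg.noise_sd * rng.standard_normal(pre.shape))
    ref = np.quantile(pre[ptv], 1.0 - cfg.coverage) if cfg.coverage > 0 else pre[ptv].max()
    if ref <= 0:
        raise ConfigError("degenerate dose field: coverage quantile is zero")
    dose = cfg.rx_gy * pre / ref
    return DoseGrid(np.maximum(dose, 0.0), cfg.spacing_mm)


# -- study presets -----------------------------------------------------------
# Three intent archetypes mirroring the clinical trade-off the cards encode,
# parametrized from the published validation-plan dose levels (hippocampal
# Dmin/Dmean/D0.03cc and PTV coverage as fractions of Rx): an aggressive- or
# deep-sparing plan accepts ~95% coverage for a deep, wide hippocampal dip; a
# moderate-sparing plan keeps ~98.5% coverage with a slightly narrower dip;
# a limited-sparing plan maximizes coverage (99%) and homogeneity with a
# narrow dip whose near-max hippocampal dose stays high.

STUDY_PLAN_CONFIGS: dict[str, PhantomConfig] = {
    "deep_sparing": PhantomConfig(
        coverage=0.951, dip_depth=0.81, dip_sigma_mm=6.0, dip_exponent=2.0,
        hotspot_pct=104.0, falloff_mm=6.0, noise_sd=0.01,
    ),
    "moderate_sparing": PhantomConfig(
        coverage=0.985, dip_depth=0.76, dip_sigma_mm=3.6, dip_exponent=3.0,
        hotspot_pct=107.0, falloff_mm=6.0, noise_sd=0.01,
    ),
    "limited_sparing": PhantomConfig(
        coverage=0.990, dip_depth=0.76, dip_sigma_mm=3.0, dip_exponent=4.0,
        hotspot_pct=103.5, falloff_mm=5.0, noise_sd=0.01,
    ),
}

#: which built-in scorecard each study plan is tuned toward
STUDY_PLAN_CARDS = {
    "deep_sparing": "HSWBv2",
    "moderate_sparing": "HMS-EC-WB",
    "limited_sparing": "HLS-EC-WB",
}


def study_plan(name: str, seed: int = 0):
    """Build one of the preset intent-archetype plans as a PlanRecord."""
    from .scoring import PlanRecord

    cfg = replace(STUDY_PLAN_CONFIGS[name], seed=seed)
    structures = build_phantom(cfg)
    dose = simulate_dose(structures, cfg)
    return PlanRecord(
        plan_id=name, rx_gy=cfg.rx_gy, fractions=cfg.fractions,
        dose=dose, structures=structures,
    )
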