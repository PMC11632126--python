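"""Shared fixtures and independent oracles for the dvhscore test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dvhscore import (
    DoseGrid,
    PhantomConfig,
    PlanRecord,
    StructureMask,
    build_phantom,
    simulate_dose,
)


# ---------------------------------------------------------------------------
# independent oracles (voxel enumeration / brute force — no DVH binning)


def sorted_dose_oracle(doses, weights):
    """Voxel-sort state for exact D_v / V_d queries (no binning)."""
    order = np.argsort(doses)[::-1]
    return doses[order], np.cumsum(weights[order])


def oracle_dose_at_volume(doses, weights, v_cc):
    """Exact D_v: the largest dose d with (volume at >= d) >= v_cc."""
    d_sorted, cum = sorted_dose_oracle(doses, weights)
    idx = np.searchsorted(cum, v_cc - 1e-12)
    idx = min(idx, len(d_sorted) - 1)
    return float(d_sorted[idx])


def oracle_volume_at_dose(doses, weights, level):
    """Exact V_d as absolute volume."""
    return float(weights[doses >= level].sum())


def golden_max(f, a, b, iters=90):
    """Golden-section maximum of f on [a, b] (for oracle refinement)."""
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        if fc < fd:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = f(d)
        else:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = f(c)
    x = 0.5 * (a + b)
    return f(x)


def dense_grid_max(total, lo=0.90, hi=1.10, step=1e-4, refine_top=3):
    """Dense-grid maximum of a score-vs-factor objective, polished by a
    golden-section pass around the best grid points (grid sampling alone
    under-reports a kinked maximum by O(step x slope))."""
    rs = np.arange(lo, hi + 1e-12, step)
    vals = np.array([total(float(r)) for r in rs])
    best = float(vals.max())
    for i in np.argsort(vals)[-refine_top:]:
        a = float(rs[max(i - 1, 0)])
        b = float(rs[min(i + 1, len(rs) - 1)])
        best = max(best, golden_max(total, a, b))
    return best


@pytest.fixture(scope="session")
def oracles():
    return {
        "dose_at_volume": oracle_dose_at_volume,
        "volume_at_dose": oracle_volume_at_dose,
        "dense_grid_max": dense_grid_max,
    }


# ---------------------------------------------------------------------------
# small synthetic inputs


@pytest.fixture
def uniform_plan():
    """100 voxels of 1 mm^3 at exactly 10 Gy inside the mask."""
    dose = np.zeros((5, 5, 8))
    occ = np.zeros((5, 5, 8))
    occ[1:5, 0:5, 0:5] = 1.0  # 100 voxels
    dose[occ > 0] = 10.0
    grid = DoseGrid(dose, (1.0, 1.0, 1.0))
    mask = StructureMask("uniform", occ, (1.0, 1.0, 1.0))
    return grid, mask


@pytest.fixture
def two_level_plan():
    """Half the mask at 4 Gy, half at 8 Gy; 0.1 cc total."""
    dose = np.zeros((2, 5, 10))
    occ = np.ones((2, 5, 10))
    dose[:, :, :5] = 4.0
    dose[:, :, 5:] = 8.0
    grid = DoseGrid(dose, (1.0, 1.0, 1.0))
    mask = StructureMask("two_level", occ, (1.0, 1.0, 1.0))
    return grid, mask


def random_plan(seed, shape=(10, 11, 12), spacing=(1.5, 2.0, 1.0)):
    """Seeded random dose on a seeded random mask."""
    rng = np.random.default_rng(seed)
    dose = DoseGrid(rng.uniform(0, 25, size=shape), spacing)
    occ = (rng.random(shape) < 0.4).astype(float)
    occ.flat[0] = 1.0  # never empty
    mask = StructureMask(f"rand{seed}", occ, spacing)
    return dose, mask


@pytest.fixture(scope="session")
def phantom_plan():
    """Default 64^3 cranial phantom as a scoreable plan (session-cached)."""
    cfg = PhantomConfig(seed=0)
    structures = build_phantom(cfg)
    dose = simulate_dose(structures, cfg)
    return PlanRecord(plan_id="phantom-0", rx_gy=cfg.rx_gy,
                      fractions=cfg.fractions, dose=dose, structures=structures)
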