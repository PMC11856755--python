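"""Binary suitability maps, latitude-weighted area budgets, change maps,
multi-GCM combination, and replicate agreement/variability layers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Grid, cell_area_km2

__all__ = [
    "ChangeMap",
    "binarize",
    "area_budget",
    "change_map",
    "multi_gcm_combine",
    "consistency_map",
    "sd_map",
]

# change-map class codes
UNCHANGED_UNSUITABLE = 0
UNCHANGED_SUITABLE = 1
GAINED = 2
LOST = 3


@dataclass
class ChangeMap:
    """Four-class suitability change map with per-class km^2 budgets."""

    classes: Grid  # codes 0..3 per cell
    unchanged_suitable_km2: float
    unchanged_unsuitable_km2: float
    gained_km2: float
    lost_km2: float


def _check_aligned(*grids: Grid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not g.aligned_with(first):
            raise ValueError("grids are not aligned")


def binarize(suitability: Grid, threshold: float) -> Grid:
    """1 where suitability >= threshold, 0 otherwise; mask preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    v = np.where(suitability.mask, np.nan, (suitability.values >= threshold).astype(float))
    return Grid(v, suitability.mask.copy(), suitability.x_origin, suitability.y_origin, suitability.cell_size)


def area_budget(binary: Grid, areas: Grid | None = None) -> dict[str, float]:
    """Suitable / unsuitable area totals (km^2, spherical cell areas) and the
    suitable percentage of total unmasked area."""
    if areas is None:
        areas = cell_area_km2(binary)
    _check_aligned(binary, areas)
    ok = ~binary.mask
    a = areas.values[ok]
    suit = binary.values[ok] >= 0.5
    total = float(a.sum())
    s = float(a[suit].sum())
    return {
        "suitable_km2": s,
        "unsuitable_km2": total - s,
        "total_km2": total,
        "suitable_pct": 100.0 * s / total if total > 0 else np.nan,
    }


def change_map(current: Grid, future: Grid, areas: Grid | None = None) -> ChangeMap:
    """Classify each unmasked cell as unchanged-suitable / unchanged-unsuitable
    / gained / lost between two binary maps, with km^2 per class.

    Accounting identities: unchanged_suitable + lost = current suitable area;
    unchanged_suitable + gained = future suitable area.
    """
    _check_aligned(current, future)
    if areas is None:
        areas = cell_area_km2(current)
    _check_aligned(current, areas)
    if not np.array_equal(current.mask, future.mask):
        raise ValueError("binary maps have different nodata masks")
    cur = current.values >= 0.5
    fut = future.values >= 0.5
    codes = np.full(current.values.shape, np.nan)
    ok = ~current.mask
    cls = np.where(
        cur & fut, UNCHANGED_SUITABLE,
        np.where(~cur & ~fut, UNCHANGED_UNSUITABLE, np.where(fut, GAINED, LOST)),
    )
    codes[ok] = cls[ok]
    a = areas.values

    def area_of(code):
        return float(a[ok & (cls == code)].sum())

    return ChangeMap(
        classes=Grid(codes, current.mask.copy(), current.x_origin, current.y_origin, current.cell_size),
        unchanged_suitable_km2=area_of(UNCHANGED_SUITABLE),
        unchanged_unsuitable_km2=area_of(UNCHANGED_UNSUITABLE),
        gained_km2=area_of(GAINED),
        lost_km2=area_of(LOST),
    )


def multi_gcm_combine(per_gcm: list[Grid], threshold: float) -> dict[str, Grid]:
    """Combine per-GCM suitability grids into a per-cell mean layer and an
    agreement layer (fraction of GCMs whose binarized map is suitable)."""
    import warnings

    if len(per_gcm) != 5:
        warnings.warn(f"expected 5 GCM grids, got {len(per_gcm)}", stacklevel=2)
    _check_aligned(*per_gcm)
    t = per_gcm[0]
    arr = np.stack([g.values for g in per_gcm])
    mean_v = np.where(t.mask, np.nan, arr.mean(axis=0))
    agree_v = np.where(t.mask, np.nan, (arr >= threshold).mean(axis=0))
    return {
        "mean": Grid(mean_v, t.mask.copy(), t.x_origin, t.y_origin, t.cell_size),
        "agreement": Grid(agree_v, t.mask.copy(), t.x_origin, t.y_origin, t.cell_size),
    }


def consistency_map(
    replicates: list[Grid], threshold: float, agreement_level: float = 0.95
) -> dict[str, object]:
    """Cells where at least ``agreement_level`` of replicates agree on the
    binary class are 'consistent'.  Returns the consistency map (1 consistent,
    0 inconsistent) and class percentages of the unmasked area."""
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    _check_aligned(*replicates)
    t = replicates[0]
    arr = np.stack([g.values >= threshold for g in replicates])
    frac_suitable = arr.mean(axis=0)
    agree = np.maximum(frac_suitable, 1.0 - frac_suitable)
    consistent = agree >= agreement_level
    ok = ~t.mask
    areas = cell_area_km2(t).values
    total = areas[ok].sum()
    cons_pct = 100.0 * areas[ok & consistent].sum() / total
    v = np.where(t.mask, np.nan, consistent.astype(float))
    return {
        "map": Grid(v, t.mask.copy(), t.x_origin, t.y_origin, t.cell_size),
        "consistent_pct": float(cons_pct),
        "inconsistent_pct": float(100.0 - cons_pct),
    }


def sd_map(replicates: list[Grid]) -> Grid:
    """Per-cell sample standard deviation across replicate suitability grids."""
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    _check_aligned(*replicates)
    t = replicates[0]
    arr = np.stack([g.values for g in replicates])
    v = np.where(t.mask, np.nan, arr.std(axis=0, ddof=1))
    return Grid(v, t.mask.copy(), t.x_origin, t.y_origin, t.cell_size)
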