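"""Occurrence curation: dataset partition, cell deduplication, Moran's-I
spatial thinning, and range-boundary summaries.

Occurrence tables are plain :class:`pandas.DataFrame` objects with columns
``lon, lat, year, elevation, greenhouse, summer_only, source`` (and, after
:func:`partition_datasets`, a ``partition`` column).  Records flagged as
greenhouse or summer-only populations are excluded from modeling because they
persist outside the climate envelope; the remaining natural records are split
into a *basic* window (1981-2010, matching the climatology baseline) and an
*expanded* window that adds 2011-2024 records from the ongoing spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._distance import pairwise_km
from .grids import Grid, GridStack

__all__ = [
    "REQUIRED_COLUMNS",
    "BASIC_YEARS",
    "EXPANDED_YEARS",
    "SpatialStats",
    "ThinningError",
    "partition_datasets",
    "modeling_records",
    "dedupe_to_cells",
    "morans_i",
    "thin_by_morans",
    "boundary_summary",
]

REQUIRED_COLUMNS = ("lon", "lat", "year", "greenhouse", "summer_only")
BASIC_YEARS = (1981, 2010)
EXPANDED_YEARS = (2011, 2024)


class ThinningError(RuntimeError):
    """Raised when spatial thinning cannot reach the target autocorrelation."""


@dataclass
class SpatialStats:
    """Moran's I of one variable over a point set."""

    morans_i: float
    n_points: int
    weighting: str


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"occurrence table lacks column(s): {', '.join(missing)}")
    lon = records["lon"].to_numpy(dtype=float)
    lat = records["lat"].to_numpy(dtype=float)
    if np.any((lon < -180) | (lon > 180)) or np.any((lat < -90) | (lat > 90)):
        raise ValueError("coordinates outside [-180,180] x [-90,90]")
    yr = records["year"].to_numpy(dtype=float)
    has_year = ~np.isnan(yr)
    if np.any((yr[has_year] < 1900) | (yr[has_year] > 2100)):
        raise ValueError("year outside 1900-2100")
    return records


def partition_datasets(records: pd.DataFrame) -> pd.DataFrame:
    """Label each record ``basic``, ``expanded_only`` or ``excluded``.

    Flagged (greenhouse / summer-only) records are excluded regardless of
    year; natural records go to *basic* (1981-2010) or *expanded_only*
    (2011-2024).  Natural records with a missing year or a year outside both
    windows are excluded with a warning, keeping the partition exhaustive.
    """
    records = _validate(records).copy()
    yr = records["year"].to_numpy(dtype=float)
    flagged = records["greenhouse"].to_numpy(bool) | records["summer_only"].to_numpy(bool)
    basic = ~flagged & (yr >= BASIC_YEARS[0]) & (yr <= BASIC_YEARS[1])
    expanded = ~flagged & (yr >= EXPANDED_YEARS[0]) & (yr <= EXPANDED_YEARS[1])
    part = np.where(flagged, "excluded", np.where(basic, "basic", np.where(expanded, "expanded_only", "excluded")))
    n_oddyear = int(np.sum((part == "excluded") & ~flagged))
    if n_oddyear:
        warnings.warn(
            f"{n_oddyear} natural record(s) outside both year windows were excluded",
            stacklevel=2,
        )
    records["partition"] = part
    return records


def modeling_records(partitioned: pd.DataFrame, dataset: str = "expanded") -> pd.DataFrame:
    """The record subset used for modeling: ``basic`` or ``expanded`` (= basic
    plus the 2011-2024 extension)."""
    if dataset == "basic":
        keep = partitioned["partition"] == "basic"
    elif dataset == "expanded":
        keep = partitioned["partition"].isin(["basic", "expanded_only"])
    else:
        raise ValueError("dataset must be 'basic' or 'expanded'")
    return partitioned.loc[keep].reset_index(drop=True)


def dedupe_to_cells(records: pd.DataFrame, grid: Grid) -> pd.DataFrame:
    """Keep at most one record per grid cell (earliest year; ties keep the
    first in input order).  Records outside the grid extent are dropped with
    a warning."""
    records = _validate(records).reset_index(drop=True)
    row, col = grid.rowcol(records["lon"].to_numpy(float), records["lat"].to_numpy(float))
    inside = (row >= 0) & (col >= 0)
    n_out = int((~inside).sum())
    if n_out:
        warnings.warn(f"{n_out} record(s) outside the grid extent were dropped", stacklevel=2)
    df = records.loc[inside].copy()
    df["_cell"] = row[inside] * grid.n_cols + col[inside]
    # stable sort by year keeps input order within ties; NaN years sort last
    df = df.sort_values("year", kind="stable")
    df = df.drop_duplicates("_cell", keep="first")
    return df.sort_index().drop(columns="_cell").reset_index(drop=True)


def morans_i(
    lons,
    lats,
    values,
    weighting: str = "inverse_distance",
    k_neighbors: int = 8,
    max_weight: float = 1e6,
) -> SpatialStats:
    """Moran's I spatial autocorrelation of ``values`` at the given points.

    I = (n / sum_ij w_ij) * sum_ij w_ij z_i z_j / sum_i z_i^2 with
    z = value - mean and, by default, w_ij = 1 / great-circle distance (km).
    Coincident points would give infinite weight; their weight is capped at
    ``max_weight`` with a warning.  ``weighting="knn"`` uses binary
    k-nearest-neighbor weights instead.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("Moran's I needs at least 2 points")
    z = values - values.mean()
    denom = float(np.sum(z**2))
    if denom == 0:
        raise ValueError("Moran's I is undefined for constant values")
    d = pairwise_km(lons, lats)
    if weighting == "inverse_distance":
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        np.fill_diagonal(w, 0.0)
        if np.any(np.isinf(w)):
            warnings.warn("coincident points: inverse-distance weight capped", stacklevel=2)
            w = np.minimum(w, max_weight)
    elif weighting == "knn":
        w = np.zeros_like(d)
        k = min(k_neighbors, n - 1)
        order = np.argsort(d, axis=1)
        rows = np.repeat(np.arange(n), k)
        w[rows, order[:, 1 : k + 1].ravel()] = 1.0
        w = np.maximum(w, w.T)  # symmetrize
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    s0 = float(w.sum())
    num = float(z @ w @ z)
    i_val = (n / s0) * num / denom
    return SpatialStats(morans_i=i_val, n_points=n, weighting=weighting)


def _max_morans(lons, lats, value_matrix: np.ndarray, names, weighting: str) -> dict[str, float]:
    return {
        name: morans_i(lons, lats, value_matrix[:, j], weighting=weighting).morans_i
        for j, name in enumerate(names)
    }


def thin_by_morans(
    records: pd.DataFrame,
    stack: GridStack,
    target: float = 0.2,
    min_records: int = 30,
    weighting: str = "inverse_distance",
) -> tuple[pd.DataFrame, dict[str, float], list[str]]:
    """Thin an already cell-deduplicated occurrence set until the maximum
    Moran's I across the stack's variables (evaluated at the occurrence
    cells) falls below ``target``.

    At each step the current closest pair of records is located and the
    member whose removal lowers the max Moran's I most is dropped (ties drop
    the later-year record).  Returns the thinned table, the final per-variable
    Moran's I, and a plain-text log of removals.

    Raises
    ------
    ThinningError
        If the record count would fall below ``min_records`` before reaching
        the target.
    """
    df = records.reset_index(drop=True)
    lons = df["lon"].to_numpy(float)
    lats = df["lat"].to_numpy(float)
    env = stack.values_at(lons, lats)
    if np.any(np.isnan(env)):
        raise ValueError("some records fall on masked or out-of-extent cells")
    names = stack.names
    keep = np.ones(len(df), dtype=bool)
    log: list[str] = []

    def stats(mask):
        return _max_morans(lons[mask], lats[mask], env[mask], names, weighting)

    current = stats(keep)
    log.append(f"start: n={keep.sum()} max I={max(current.values()):.4f}")
    while max(current.values()) >= target:
        n_now = int(keep.sum())
        if n_now <= min_records:
            raise ThinningError(
                f"cannot reach Moran's I < {target}: {n_now} records left "
                f"(floor {min_records}), current I={max(current.values()):.4f}"
            )
        idx = np.flatnonzero(keep)
        d = pairwise_km(lons[idx], lats[idx])
        np.fill_diagonal(d, np.inf)
        a, b = np.unravel_index(np.argmin(d), d.shape)
        cand = [idx[a], idx[b]]
        best = None
        for c in cand:
            trial = keep.copy()
            trial[c] = False
            s = stats(trial)
            m = max(s.values())
            if best is None or m < best[0] - 1e-15:
                best = (m, c, s)
            elif abs(m - best[0]) <= 1e-15:
                # tie: drop the later-year record
                yr_c = df.loc[c, "year"]
                yr_b = df.loc[best[1], "year"]
                if (yr_c if np.isfinite(yr_c) else np.inf) > (yr_b if np.isfinite(yr_b) else np.inf):
                    best = (m, c, s)
        _, drop, current = best
        keep[drop] = False
        log.append(
            f"removed record {drop} (lon={lons[drop]:.4f}, lat={lats[drop]:.4f}); "
            f"n={keep.sum()} max I={max(current.values()):.4f}"
        )
    log.append(f"done: n={keep.sum()} max I={max(current.values()):.4f}")
    return df.loc[keep].reset_index(drop=True), current, log


def boundary_summary(a: pd.DataFrame, b: pd.DataFrame) -> dict[str, float]:
    """Shift of the occupied range envelope from dataset ``a`` to ``b``:
    deltas of min/max longitude and latitude (degrees) and of the maximum
    elevation (meters; NaN when either set lacks elevations)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("boundary_summary needs non-empty datasets")

    def env(df):
        elev = df["elevation"].to_numpy(float) if "elevation" in df.columns else np.array([np.nan])
        return {
            "min_lon": df["lon"].min(),
            "max_lon": df["lon"].max(),
            "min_lat": df["lat"].min(),
            "max_lat": df["lat"].max(),
            "max_elevation": np.nanmax(elev) if np.any(np.isfinite(elev)) else np.nan,
        }

    ea, eb = env(a), env(b)
    return {f"delta_{k}": eb[k] - ea[k] for k in ea}
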