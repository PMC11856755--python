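"""Great-circle distance helpers (haversine on a spherical Earth)."""

from __future__ import annotations

import numpy as np

from .grids import EARTH_RADIUS_KM


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between coordinate arrays (broadcasting)."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_km(lons, lats) -> np.ndarray:
    """Symmetric n x n great-circle distance matrix in km."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])


def cross_km(lons1, lats1, lons2, lats2) -> np.ndarray:
    """n x m distance matrix between two point sets, km."""
    lons1 = np.asarray(lons1, dtype=float)[:, None]
    lats1 = np.asarray(lats1, dtype=float)[:, None]
    return haversine_km(lons1, lats1, np.asarray(lons2, dtype=float)[None, :], np.asarray(lats2, dtype=float)[None, :])
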