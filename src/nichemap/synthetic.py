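"""Synthetic study system with known truth.

Generates spatially autocorrelated, cross-correlated climate layers over a
geographic grid, a known suitability surface, presence records sampled from
it (optionally contaminated with greenhouse / summer-only records placed
outside the climate envelope), and five perturbed future layer stacks whose
warming magnitudes mirror the equilibrium-climate-sensitivity spread of a
five-member GCM ensemble.

The layer synthesis smooths white noise with a Gaussian kernel, empirically
whitens the fields, and mixes them through the Cholesky factor of the target
correlation matrix, so the realized pairwise Pearson correlations match the
target closely even on modest grids.  A latitudinal gradient is added to the
first temperature layer only (pre-orthogonalized fields keep the remaining
pairwise correlations on target).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grids import Grid, GridStack

__all__ = ["WorldRecipe", "make_layers", "make_truth", "sample_occurrences", "make_future"]


def _default_kinds(names):
    kinds = []
    for n in names:
        if n.startswith(("tas", "tmax", "tmin")):
            kinds.append("temperature")
        elif n.startswith(("prec", "pr")):
            kinds.append("precipitation")
        else:
            kinds.append("other")
    return tuple(kinds)


def _default_correlation() -> np.ndarray:
    # tas1, tas2, prec1, prec2, bio15, elev: a redundant temperature pair and
    # a redundant precipitation pair for the collinearity screen to act on
    r = np.eye(6)
    pairs = {(0, 1): 0.9, (2, 3): 0.85, (2, 4): 0.4, (3, 4): 0.4,
             (0, 2): 0.1, (0, 3): 0.1, (0, 4): 0.1, (1, 2): 0.1, (1, 3): 0.1, (1, 4): 0.1}
    for (i, j), v in pairs.items():
        r[i, j] = r[j, i] = v
    return r


@dataclass
class WorldRecipe:
    """All knobs of the synthetic world.

    The defaults define the study conditions: a 100 x 100 half-degree grid
    (a 50-degree square window), six layers with one collinear pair in each
    of temperature and precipitation, a unimodal-temperature truth, 1000
    presences with 10% contaminant records, and five future stacks whose
    relative warming follows the ECS ladder 5.4 / 4.6 / 3.1 / 3.0 / 2.7.
    """

    layer_names: tuple[str, ...] = ("tas1", "tas2", "prec1", "prec2", "bio15", "elev")
    layer_kinds: tuple[str, ...] | None = None
    n_rows: int = 100
    n_cols: int = 100
    x_origin: float = -25.0
    y_origin: float = -25.0
    cell_size: float = 0.5
    spatial_range: float = 3.0  # autocorrelation length, degrees
    cross_correlation: np.ndarray | None = None
    gradient_weight: float = 0.35
    mask_fraction: float = 0.15
    truth_coefficients: dict[str, float] = field(
        default_factory=lambda: {"tas1": 2.0, "tas1^2": -1.0, "prec1": 1.0}
    )
    truth_gain: float = 2.0
    n_presences: int = 1000
    contamination_fraction: float = 0.10
    contamination_floor: float = 0.05
    recent_fraction: float = 0.35  # natural records falling in 2011-2024
    gcm_shift_scales: tuple[float, ...] = (5.4, 4.6, 3.1, 3.0, 2.7)
    warming_per_unit: float = 0.5  # degrees C per unit of shift scale
    precip_change_per_unit: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.layer_kinds is None:
            self.layer_kinds = _default_kinds(self.layer_names)
        if self.cross_correlation is None and len(self.layer_names) == 6:
            self.cross_correlation = _default_correlation()
        elif self.cross_correlation is None:
            self.cross_correlation = np.eye(len(self.layer_names))
        self.cross_correlation = np.asarray(self.cross_correlation, dtype=float)
        k = len(self.layer_names)
        if self.cross_correlation.shape != (k, k):
            raise ValueError("cross_correlation shape must match the number of layers")
        if not np.allclose(self.cross_correlation, self.cross_correlation.T):
            raise ValueError("cross_correlation must be symmetric")
        if not np.allclose(np.diag(self.cross_correlation), 1.0):
            raise ValueError("cross_correlation must have a unit diagonal")
        if not 0 <= self.contamination_fraction < 1:
            raise ValueError("contamination_fraction must be in [0, 1)")


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells, mode="reflect")
    return (f - f.mean()) / f.std()


def make_layers(recipe: WorldRecipe) -> GridStack:
    """Generate the cross-correlated climate layer stack."""
    rng = np.random.default_rng([recipe.seed, 1])
    k = len(recipe.layer_names)
    shape = (recipe.n_rows, recipe.n_cols)
    sigma = recipe.spatial_range / recipe.cell_size
    try:
        lt = np.linalg.cholesky(recipe.cross_correlation)
    except np.linalg.LinAlgError as exc:
        raise ValueError("cross_correlation target is not positive semi-definite") from exc

    # latitudinal gradient, standardized over cells
    lat = np.linspace(1.0, -1.0, recipe.n_rows)[:, None] * np.ones((1, recipe.n_cols))
    grad = ((lat - lat.mean()) / lat.std()).ravel()

    raw_fields = np.stack([_smooth_field(rng, shape, sigma).ravel() for _ in range(k)])
    mask_field = _smooth_field(rng, shape, sigma)
    if recipe.mask_fraction > 0:
        thresh = np.quantile(mask_field, recipe.mask_fraction)
        mask = mask_field < thresh
    else:
        mask = np.zeros(shape, dtype=bool)
    ok = ~mask.ravel()

    # orthogonalize against the gradient and whiten, both estimated on the
    # unmasked cells, so the realized correlations there hit the target
    g_ok = grad[ok]
    fields = np.empty_like(raw_fields)
    for i in range(k):
        f = raw_fields[i]
        f = f - (f[ok] @ g_ok) / (g_ok @ g_ok) * grad
        fields[i] = (f - f[ok].mean()) / f[ok].std()
    cov = np.cov(fields[:, ok])
    fields = np.linalg.solve(np.linalg.cholesky(cov), fields)
    mixed = lt @ fields

    # gradient on the first temperature layer (others stay on target)
    g = recipe.gradient_weight
    for i, kind in enumerate(recipe.layer_kinds):
        if kind == "temperature":
            mixed[i] = np.sqrt(1 - g**2) * mixed[i] + g * grad
            break

    layers = {}
    for i, (name, kind) in enumerate(zip(recipe.layer_names, recipe.layer_kinds)):
        z = mixed[i].reshape(shape)
        if kind == "temperature":
            v = 12.0 + 7.0 * z
        elif kind == "precipitation":
            v = np.maximum(60.0 + 20.0 * z, 1.0)
        else:
            v = 100.0 + 50.0 * z
        v = np.where(mask, np.nan, v)
        layers[name] = Grid(v, mask.copy(), recipe.x_origin, recipe.y_origin, recipe.cell_size)
    return GridStack(layers)


def make_truth(stack: GridStack, coefficients: dict[str, float], gain: float = 2.0) -> Grid:
    """Known suitability surface: logistic link of the standardized linear
    predictor built from layer terms (``"name"`` linear, ``"name^2"``
    quadratic in the standardized layer)."""
    t = stack.template
    ok = ~stack.mask
    eta = np.zeros(ok.sum())
    for key, coef in coefficients.items():
        name, _, power = key.partition("^")
        if name not in stack:
            raise ValueError(f"unknown layer {name!r} in truth coefficients")
        v = stack[name].values[ok]
        z = (v - v.mean()) / v.std()
        eta += coef * (z**2 if power == "2" else z)
    sd = eta.std()
    if sd > 0:
        eta = (eta - eta.mean()) / sd
    out = np.full((t.n_rows, t.n_cols), np.nan)
    out[ok] = expit(gain * eta)
    return Grid(out, stack.mask.copy(), t.x_origin, t.y_origin, t.cell_size)


def sample_occurrences(truth: Grid, recipe: WorldRecipe) -> pd.DataFrame:
    """Presence records drawn with probability proportional to the truth
    surface (multiple records may share a cell; coordinates are jittered
    within the cell).  A ``contamination_fraction`` of records is flagged
    greenhouse or summer-only and placed where truth < the contamination
    floor, emulating populations persisting outside the climate envelope."""
    rng = np.random.default_rng([recipe.seed, 2])
    ok = ~truth.mask
    n_cells = int(ok.sum())
    if n_cells == 0:
        raise ValueError("truth surface has no unmasked cells")
    rows, cols = np.where(ok)
    w = np.clip(truth.values[rows, cols], 0.0, 1.0)
    if w.sum() <= 0:
        raise ValueError("truth surface has no positive suitability")
    p = w / w.sum()
    n_con = int(round(recipe.contamination_fraction * recipe.n_presences))
    n_nat = recipe.n_presences - n_con

    def coords(cell_idx):
        lat = truth.lat_centers[rows[cell_idx]] + rng.uniform(-0.4, 0.4, len(cell_idx)) * truth.cell_size
        lon = truth.lon_centers[cols[cell_idx]] + rng.uniform(-0.4, 0.4, len(cell_idx)) * truth.cell_size
        return lon, lat

    nat_cells = rng.choice(n_cells, size=n_nat, replace=True, p=p)
    lon_n, lat_n = coords(nat_cells)
    recent = rng.random(n_nat) < recipe.recent_fraction
    years_n = np.where(recent, rng.integers(2011, 2025, n_nat), rng.integers(1981, 2011, n_nat))

    low = np.flatnonzero(w < recipe.contamination_floor)
    if len(low) == 0:
        low = np.argsort(w)[: max(n_cells // 10, 1)]
    con_cells = rng.choice(low, size=n_con, replace=True)
    lon_c, lat_c = coords(con_cells)
    years_c = rng.integers(1981, 2025, n_con)
    greenhouse = np.zeros(n_con, dtype=bool)
    greenhouse[::2] = True

    df = pd.DataFrame(
        {
            "lon": np.concatenate([lon_n, lon_c]),
            "lat": np.concatenate([lat_n, lat_c]),
            "year": np.concatenate([years_n, years_c]).astype(int),
            "elevation": np.round(rng.uniform(0, 2500, recipe.n_presences), 1),
            "greenhouse": np.concatenate([np.zeros(n_nat, dtype=bool), greenhouse]),
            "summer_only": np.concatenate([np.zeros(n_nat, dtype=bool), ~greenhouse]),
            "source": "synthetic",
        }
    )
    return df.sample(frac=1.0, random_state=recipe.seed).reset_index(drop=True)


def make_future(stack: GridStack, recipe: WorldRecipe) -> list[GridStack]:
    """Five perturbed future stacks.

    Temperature layers are shifted by ``scale * warming_per_unit`` degrees
    plus smooth scale-proportional noise; precipitation layers are rescaled
    multiplicatively; other layers are untouched.  All-zero scales reproduce
    the input exactly.
    """
    if len(recipe.gcm_shift_scales) != 5:
        raise ValueError("gcm_shift_scales must have exactly 5 entries")
    rng = np.random.default_rng([recipe.seed, 3])
    t = stack.template
    sigma = recipe.spatial_range / t.cell_size
    shape = (t.n_rows, t.n_cols)
    futures = []
    for scale in recipe.gcm_shift_scales:
        layers = {}
        for name, kind in zip(stack.names, recipe.layer_kinds):
            g = stack[name]
            noise = _smooth_field(rng, shape, sigma)  # drawn for every layer/GCM: seed-stable
            if kind == "temperature":
                v = g.values + scale * recipe.warming_per_unit * (1.0 + 0.1 * noise)
            elif kind == "precipitation":
                factor = 1.0 + scale * (recipe.precip_change_per_unit + 0.005 * noise)
                v = g.values * np.maximum(factor, 0.0)
            else:
                v = g.values.copy()
            v = np.where(g.mask, np.nan, v)
            layers[name] = Grid(v, g.mask.copy(), g.x_origin, g.y_origin, g.cell_size)
        futures.append(GridStack(layers))
    return futures
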