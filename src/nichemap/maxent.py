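"""Presence-background maximum-entropy suitability model.

The model estimates the least-informative probability distribution over
background cells whose feature expectations match the presence sample, with
an L1 penalty per feature (lasso-regularized maxent).  Raw covariates are
expanded into linear (L), quadratic (Q), product (P), hinge (H) and threshold
(T) features scaled to [0, 1] over the background; the penalized objective

    ln Z(lambda) - mean_presence eta(x) + sum_j beta_j |lambda_j|

(eta = lambda . f(x), Z = sum over background of e^eta) is minimized by
accelerated proximal gradient descent.  The per-feature penalty is
beta_j = rm * class_default(n_presences) * s_j / sqrt(n_presences), where
``rm`` is the regularization multiplier, the class defaults follow the
published per-class tables interpolated on presence count, and s_j is the
feature's standard deviation over presences.

Suitability is reported on the cloglog scale, 1 - exp(-e^H * raw(x)), where
H is the entropy of the fitted raw distribution over the background; a model
with all-zero coefficients is uniform and scores 1 - e^{-1} everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax
from sklearn.base import BaseEstimator, clone

from ._distance import cross_km
from .grids import Grid, GridStack

__all__ = [
    "FEATURE_CLASSES",
    "MaxentModel",
    "BackgroundSample",
    "ReplicateResult",
    "ConvergenceError",
    "sample_background",
    "response_curve",
    "percent_contribution",
    "jackknife_gain",
    "replicate_runs",
]

FEATURE_CLASSES = "lqpht"


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries the tail of the objective trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


# per-class default regularization, interpolated on presence count
_LQP_BREAKS = np.array([0.0, 10.0, 30.0, 100.0])
_LQP_BETAS = np.array([1.0, 1.0, 0.2, 0.05])
_TH_BREAKS = np.array([0.0, 100.0])
_TH_BETAS = np.array([2.0, 1.0])
_HINGE_BETA = 0.5


def _class_default_beta(cls: str, n_presences: int) -> float:
    if cls in ("l", "q", "p"):
        return float(np.interp(n_presences, _LQP_BREAKS, _LQP_BETAS))
    if cls == "h":
        return _HINGE_BETA
    if cls == "t":
        return float(np.interp(n_presences, _TH_BREAKS, _TH_BETAS))
    raise ValueError(f"unknown feature class {cls!r}")


def _canon_classes(classes: str) -> str:
    c = "".join(sorted(set(classes.lower()), key=FEATURE_CLASSES.index))
    if not c or any(ch not in FEATURE_CLASSES for ch in classes.lower()):
        raise ValueError(f"feature classes must be a non-empty subset of {FEATURE_CLASSES!r}")
    return c


class _FeatureBuilder:
    """Expands raw covariates into scaled maxent features.

    Bounds and knots come from the background sample: linear features are
    min-max scaled, hinge knots sit at background quantiles j/n_knots
    (j = 0..n_knots-1), threshold knots at interior quantiles
    (j+1)/(n_knots+1).
    """

    def __init__(self, classes: str, hinge_knots: int, threshold_knots: int):
        self.classes = _canon_classes(classes)
        self.hinge_knots = hinge_knots
        self.threshold_knots = threshold_knots

    def fit(self, X_bg: np.ndarray, names: list[str]) -> "_FeatureBuilder":
        X_bg = np.asarray(X_bg, dtype=float)
        self.variable_names_ = list(names)
        self.mins_ = X_bg.min(axis=0)
        self.maxs_ = X_bg.max(axis=0)
        self.ranges_ = np.maximum(self.maxs_ - self.mins_, 1e-12)
        nv = X_bg.shape[1]
        if "h" in self.classes:
            qs = np.arange(self.hinge_knots) / self.hinge_knots
            self.hinge_knots_ = np.quantile(X_bg, qs, axis=0)  # (knots, nv)
        if "t" in self.classes:
            qs = (np.arange(self.threshold_knots) + 1) / (self.threshold_knots + 1)
            self.threshold_knots_ = np.quantile(X_bg, qs, axis=0)
        names_out: list[str] = []
        classes_out: list[str] = []
        for cls in self.classes:
            if cls == "l":
                names_out += [f"l:{n}" for n in names]
                classes_out += ["l"] * nv
            elif cls == "q":
                names_out += [f"q:{n}" for n in names]
                classes_out += ["q"] * nv
            elif cls == "p":
                for i in range(nv):
                    for j in range(i + 1, nv):
                        names_out.append(f"p:{names[i]}*{names[j]}")
                        classes_out.append("p")
            elif cls == "h":
                for j in range(nv):
                    names_out += [f"h:{names[j]}:{k}" for k in range(self.hinge_knots)]
                    classes_out += ["h"] * self.hinge_knots
            elif cls == "t":
                for j in range(nv):
                    names_out += [f"t:{names[j]}:{k}" for k in range(self.threshold_knots)]
                    classes_out += ["t"] * self.threshold_knots
        self.feature_names_ = names_out
        self.feature_classes_ = np.array(classes_out)
        return self

    def transform(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if clamp:
            X = np.clip(X, self.mins_, self.maxs_)
        scaled = (X - self.mins_) / self.ranges_
        blocks: list[np.ndarray] = []
        nv = X.shape[1]
        for cls in self.classes:
            if cls == "l":
                blocks.append(scaled)
            elif cls == "q":
                blocks.append(scaled**2)
            elif cls == "p":
                cols = [scaled[:, i] * scaled[:, j] for i in range(nv) for j in range(i + 1, nv)]
                if cols:
                    blocks.append(np.column_stack(cols))
            elif cls == "h":
                for j in range(nv):
                    k = self.hinge_knots_[:, j]  # (knots,)
                    denom = np.maximum(self.maxs_[j] - k, 1e-12)
                    blocks.append(np.clip((X[:, j][:, None] - k[None, :]) / denom[None, :], 0.0, 1.0))
            elif cls == "t":
                for j in range(nv):
                    k = self.threshold_knots_[:, j]
                    blocks.append((X[:, j][:, None] > k[None, :]).astype(float))
        return np.concatenate([b for b in blocks], axis=1) if blocks else np.empty((len(X), 0))


def _prox_fit(Fp, Fb, beta, tol, max_iter):
    """Minimize lnZ - mean_presence(eta) + beta.|lambda| by FISTA with
    backtracking and adaptive restart.  Returns (lambda, trace)."""
    pbar = Fp.mean(axis=0)
    k = Fb.shape[1]

    def smooth(lam, eta=None):
        eta = Fb @ lam if eta is None else eta
        return logsumexp(eta) - pbar @ lam

    def grad(lam):
        w = softmax(Fb @ lam)
        return Fb.T @ w - pbar

    lam = np.zeros(k)
    yv = lam.copy()
    t = 1.0
    L = 1.0
    f_x = smooth(lam) + beta @ np.abs(lam)
    trace = [f_x]
    for _ in range(max_iter):
        g = grad(yv)
        s_y = smooth(yv)
        while True:
            step = yv - g / L
            x_new = np.sign(step) * np.maximum(np.abs(step) - beta / L, 0.0)
            diff = x_new - yv
            s_new = smooth(x_new)
            if s_new <= s_y + g @ diff + 0.5 * L * (diff @ diff) + 1e-12:
                break
            L *= 2.0
        f_new = s_new + beta @ np.abs(x_new)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        yv = x_new + ((t - 1.0) / t_new) * (x_new - lam)
        if f_new > f_x:  # lost monotonicity: restart momentum
            yv = x_new.copy()
            t_new = 1.0
        converged = f_new <= f_x and (f_x - f_new) < tol * (1.0 + abs(f_new))
        lam, t = x_new, t_new
        f_x = min(f_x, f_new)
        trace.append(f_new)
        L *= 0.9  # allow the step size to grow back
        if converged:
            return lam, trace
    raise ConvergenceError(
        f"maxent optimizer did not converge in {max_iter} iterations "
        f"(last objective change {abs(trace[-2] - trace[-1]):.3e})",
        trace[-50:],
    )


class MaxentModel(BaseEstimator):
    """Scikit-learn style maximum-entropy presence-background model.

    Parameters
    ----------
    feature_classes : str
        Subset of ``"lqpht"``.
    rm : float
        Regularization multiplier; ``rm=1`` reproduces the per-class default
        penalties, larger values give sparser, smoother models.
    hinge_knots, threshold_knots : int
        Knots per variable for hinge / threshold features.
    clamp : bool
        Clamp projection covariates to the training (background) bounds.
    tol, max_iter : optimizer controls (objective-change convergence).

    The estimator is fit on a design matrix ``X`` (rows = cells, columns =
    environmental variables; DataFrame columns become variable names) and a
    label vector ``y`` with 1 = presence, 0 = background.
    """

    def __init__(
        self,
        feature_classes: str = "lqh",
        rm: float = 1.0,
        hinge_knots: int = 50,
        threshold_knots: int = 20,
        clamp: bool = True,
        tol: float = 1e-7,
        max_iter: int = 20000,
        s_floor: float = 1e-3,
    ):
        self.feature_classes = feature_classes
        self.rm = rm
        self.hinge_knots = hinge_knots
        self.threshold_knots = threshold_knots
        self.clamp = clamp
        self.tol = tol
        self.max_iter = max_iter
        self.s_floor = s_floor

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(Xv.shape[1])]
        y = np.asarray(y)
        if Xv.ndim != 2 or len(Xv) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("y must contain only 0 (background) and 1 (presence)")
        if self.rm < 0:
            raise ValueError("rm must be >= 0")
        Xp, Xb = Xv[y == 1], Xv[y == 0]
        n, m = len(Xp), len(Xb)
        if n < 2:
            raise ValueError("need at least 2 presences")
        if m < 2:
            raise ValueError("need at least 2 background cells")
        builder = _FeatureBuilder(self.feature_classes, self.hinge_knots, self.threshold_knots)
        builder.fit(Xb, names)
        Fb = builder.transform(Xb, clamp=False)
        Fp = builder.transform(Xp, clamp=self.clamp)
        class_beta = np.array([_class_default_beta(c, n) for c in builder.feature_classes_])
        s = np.maximum(Fp.std(axis=0), self.s_floor)
        beta = self.rm * class_beta * s / np.sqrt(n)
        lam, trace = _prox_fit(Fp, Fb, beta, self.tol, self.max_iter)

        self.builder_ = builder
        self.variable_names_ = names
        self.n_features_in_ = Xv.shape[1]
        self.feature_names_ = builder.feature_names_
        self.coef_ = lam
        self.beta_ = beta
        self.n_iter_ = len(trace) - 1
        self.objective_trace_ = trace
        eta_bg = Fb @ lam
        self.log_z_ = float(logsumexp(eta_bg))
        p = softmax(eta_bg)
        self.background_raw_ = p
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        self.entropy_ = float(-plogp.sum())
        self.background_means_ = Xb.mean(axis=0)
        self.n_presences_ = n
        self.n_background_ = m
        self._raw_sorted_ = np.sort(p)
        self._raw_cumsum_ = np.cumsum(self._raw_sorted_)
        return self

    # -- prediction ---------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[self.variable_names_].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("wrong number of variables")
        return X

    def eta(self, X) -> np.ndarray:
        """Linear predictor lambda . f(x) (projection clamped if configured)."""
        self._check_fitted()
        F = self.builder_.transform(self._as_matrix(X), clamp=self.clamp)
        return F @ self.coef_

    def predict(self, X, output: str = "cloglog") -> np.ndarray:
        """Suitability predictions: ``raw`` (normalized over the training
        background), ``cumulative`` (percent of background raw mass at or
        below each cell), or ``cloglog`` (default, in (0,1))."""
        self._check_fitted()
        raw = np.exp(self.eta(X) - self.log_z_)
        if output == "raw":
            return raw
        if output == "cloglog":
            return 1.0 - np.exp(-np.exp(self.entropy_) * raw)
        if output == "cumulative":
            idx = np.searchsorted(self._raw_sorted_, raw, side="right")
            cum = np.concatenate([[0.0], self._raw_cumsum_])
            return 100.0 * cum[idx]
        raise ValueError(f"unknown output mode {output!r}")

    def predict_grid(self, stack: GridStack, output: str = "cloglog") -> Grid:
        """Project the model over a grid stack (layers matched by name)."""
        self._check_fitted()
        missing = [v for v in self.variable_names_ if v not in stack]
        if missing:
            raise ValueError(f"stack lacks layer(s): {', '.join(missing)}")
        rows, cols = stack.unmasked_cells()
        X = np.column_stack([stack[v].values[rows, cols] for v in self.variable_names_])
        preds = self.predict(X, output=output)
        t = stack.template
        out = np.full((t.n_rows, t.n_cols), np.nan)
        out[rows, cols] = preds
        return Grid(out, stack.mask.copy(), t.x_origin, t.y_origin, t.cell_size)

    def training_gain(self, X_presence) -> float:
        """Mean presence log-likelihood relative to the uniform model:
        mean(eta) - ln Z + ln m."""
        self._check_fitted()
        return float(np.mean(self.eta(X_presence)) - self.log_z_ + np.log(self.n_background_))


# -- background sampling ----------------------------------------------------


@dataclass
class BackgroundSample:
    """Background (pseudo-absence) cells drawn within a buffer of presences."""

    rows: np.ndarray
    cols: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    X: pd.DataFrame
    buffer_km: float
    seed: int


def sample_background(
    records: pd.DataFrame,
    stack: GridStack,
    buffer_km: float = 500.0,
    m: int = 10000,
    seed: int = 0,
) -> BackgroundSample:
    """Draw ``m`` background cells uniformly (without replacement) from the
    unmasked cells whose centers lie within ``buffer_km`` great-circle
    distance of any presence record.  If fewer than ``m`` cells are eligible,
    all of them are returned with a warning."""
    if buffer_km <= 0:
        raise ValueError("buffer_km must be positive")
    rows, cols = stack.unmasked_cells()
    t = stack.template
    cell_lon = t.lon_centers[cols]
    cell_lat = t.lat_centers[rows]
    plon = records["lon"].to_numpy(float)
    plat = records["lat"].to_numpy(float)
    within = np.zeros(len(rows), dtype=bool)
    chunk = 200000 // max(len(plon), 1) + 1
    for start in range(0, len(rows), chunk):
        sl = slice(start, start + chunk)
        d = cross_km(cell_lon[sl], cell_lat[sl], plon, plat)
        within[sl] = (d <= buffer_km).any(axis=1)
    eligible = np.flatnonzero(within)
    if len(eligible) == 0:
        raise ValueError("no unmasked cells within the buffer")
    rng = np.random.default_rng(seed)
    if len(eligible) < m:
        warnings.warn(
            f"only {len(eligible)} eligible background cells (< requested {m})",
            stacklevel=2,
        )
        take = eligible
    else:
        take = rng.choice(eligible, size=m, replace=False)
    take = np.sort(take)
    r, c = rows[take], cols[take]
    X = pd.DataFrame(stack.to_matrix(r, c), columns=stack.names)
    return BackgroundSample(
        rows=r, cols=c, lon=t.lon_centers[c], lat=t.lat_centers[r], X=X, buffer_km=buffer_km, seed=seed
    )


# -- interpretation ---------------------------------------------------------


def response_curve(model: MaxentModel, variable: str, n_points: int = 100, output: str = "cloglog"):
    """Marginal response: sweep one variable over its background range with
    all others at their background means.  Returns (sweep values, predictions).
    """
    model._check_fitted()
    if variable not in model.variable_names_:
        raise ValueError(f"unknown variable {variable!r}")
    j = model.variable_names_.index(variable)
    sweep = np.linspace(model.builder_.mins_[j], model.builder_.maxs_[j], n_points)
    X = np.tile(model.background_means_, (n_points, 1))
    X[:, j] = sweep
    return sweep, model.predict(X, output=output)


def percent_contribution(
    model: MaxentModel, X_presence, X_background, seed: int = 0, n_repeats: int = 2
) -> pd.Series:
    """Permutation importance per variable, rescaled to sum to 100.

    Each variable's column is permuted over the combined presence/background
    rows and the drop in training AUC (presence vs background) is recorded;
    drops are averaged over ``n_repeats`` permutations, floored at zero, and
    normalized.
    """
    from .evaluation import auc_score

    model._check_fitted()
    Xp = model._as_matrix(X_presence)
    Xb = model._as_matrix(X_background)
    comb = np.vstack([Xp, Xb])
    n = len(Xp)
    base = auc_score(model.predict(Xp), model.predict(Xb))
    rng = np.random.default_rng(seed)
    drops = {}
    for j, name in enumerate(model.variable_names_):
        d = 0.0
        for _ in range(n_repeats):
            perm = comb.copy()
            perm[:, j] = rng.permutation(perm[:, j])
            d += base - auc_score(model.predict(perm[:n]), model.predict(perm[n:]))
        drops[name] = max(d / n_repeats, 0.0)
    total = sum(drops.values())
    if total == 0:
        warnings.warn("no variable affects the model; contributions set equal", stacklevel=2)
        return pd.Series({k: 100.0 / len(drops) for k in drops})
    return pd.Series({k: 100.0 * v / total for k, v in drops.items()})


def jackknife_gain(model: MaxentModel, X_presence: pd.DataFrame, X_background: pd.DataFrame) -> pd.DataFrame:
    """Jackknife variable importance: training gain of a model fitted with
    only each variable, and with all variables but that one.  Returns a
    DataFrame indexed by variable with columns ``with_only`` / ``without``
    plus the full-model gain as ``.attrs['full_gain']``."""
    model._check_fitted()
    names = model.variable_names_
    if len(names) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    Xp = pd.DataFrame(model._as_matrix(X_presence), columns=names)
    Xb = pd.DataFrame(model._as_matrix(X_background), columns=names)

    def fit_gain(cols):
        sub = clone(model)
        y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xb))])
        X = pd.concat([Xp[cols], Xb[cols]], ignore_index=True)
        sub.fit(X, y)
        return sub.training_gain(Xp[cols])

    rows = {}
    for v in names:
        rows[v] = {"with_only": fit_gain([v]), "without": fit_gain([c for c in names if c != v])}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.attrs["full_gain"] = model.training_gain(X_presence)
    return out


# -- replicate averaging ----------------------------------------------------


@dataclass
class ReplicateResult:
    """Mean/SD suitability over random-split replicates plus per-rep records."""

    mean_grid: Grid
    sd_grid: Grid
    grids: list[Grid]
    metrics: pd.DataFrame
    models: list[MaxentModel]
    test_indices: list[np.ndarray]
    thresholds: list[float] = field(default_factory=list)


def replicate_runs(
    model: MaxentModel,
    X_presence: pd.DataFrame,
    background: BackgroundSample,
    stack: GridStack,
    n_reps: int = 20,
    test_fraction: float = 0.25,
    base_seed: int = 0,
) -> ReplicateResult:
    """Run ``n_reps`` replicates, each on a fresh random train/test presence
    split (seed = base_seed + rep), and average the cloglog projections.

    Per-replicate metrics: test AUC vs background and the two omission rates
    (minimum-training-presence and 10th-percentile).
    """
    from .tuning import omission_rates

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n = len(X_presence)
    n_test = int(round(test_fraction * n))
    if n_test < 1 or n - n_test < 2:
        raise ValueError("too few presences for the requested split")
    y = np.concatenate([np.ones(n - n_test), np.zeros(len(background.X))])
    grids, models, test_idx, rows = [], [], [], []
    for rep in range(n_reps):
        rng = np.random.default_rng(base_seed + rep)
        perm = rng.permutation(n)
        test = perm[:n_test]
        train = perm[n_test:]
        Xtr = X_presence.iloc[train]
        Xte = X_presence.iloc[test]
        rep_model = clone(model)
        rep_model.fit(pd.concat([Xtr, background.X], ignore_index=True), y)
        g = rep_model.predict_grid(stack, output="cloglog")
        train_preds = rep_model.predict(Xtr)
        test_preds = rep_model.predict(Xte)
        bg_preds = rep_model.predict(background.X)
        from .evaluation import auc_score

        or_mtp, or_10 = omission_rates(train_preds, test_preds)
        rows.append(
            {
                "rep": rep,
                "auc_bg": auc_score(test_preds, bg_preds),
                "or_mtp": or_mtp,
                "or_10": or_10,
                "n_train": len(train),
                "n_test": len(test),
            }
        )
        grids.append(g)
        models.append(rep_model)
        test_idx.append(test)
    arr = np.stack([g.values for g in grids])
    t = stack.template
    mean_v = arr.mean(axis=0)
    sd_v = arr.std(axis=0, ddof=1) if n_reps > 1 else np.zeros_like(mean_v)
    mask = stack.mask.copy()
    mean_v = np.where(mask, np.nan, mean_v)
    sd_v = np.where(mask, np.nan, sd_v)
    return ReplicateResult(
        mean_grid=Grid(mean_v, mask, t.x_origin, t.y_origin, t.cell_size),
        sd_grid=Grid(sd_v, mask.copy(), t.x_origin, t.y_origin, t.cell_size),
        grids=grids,
        metrics=pd.DataFrame(rows),
        models=models,
        test_indices=test_idx,
    )
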