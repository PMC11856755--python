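"""Candidate-model tuning: regularization-multiplier x feature-class grid,
AICc, omission rates, partial-ROC significance, and champion selection.

Candidates are ranked by first filtering to partial-ROC p < 0.05, then to a
10th-percentile omission rate at or below a cap (default 0.1), then taking
the lowest AICc; each filter is relaxed with a warning if it would empty the
pool.  AICc uses the ecological-niche-modeling convention: parameters k =
nonzero coefficients, likelihood = raw suitability renormalized over the full
projection grid and evaluated at the presence cells.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import clone

from .grids import GridStack
from .maxent import FEATURE_CLASSES, BackgroundSample, MaxentModel

__all__ = [
    "CandidateScore",
    "candidate_space",
    "maxent_log_lik",
    "aicc",
    "omission_rates",
    "partial_roc",
    "select_champion",
    "tune",
]


@dataclass
class CandidateScore:
    """Per-candidate tuning record."""

    rm: float
    fc: str
    k: int = 0
    log_lik: float = np.nan
    aicc: float = np.nan
    or_mtp: float = np.nan
    or_10: float = np.nan
    proc_ratio: float = np.nan
    proc_p: float = np.nan


def candidate_space(
    rm_min: float = 0.1,
    rm_max: float = 5.0,
    rm_step: float = 0.1,
    classes: str = FEATURE_CLASSES,
) -> list[tuple[float, str]]:
    """Cartesian product of the RM ladder with all non-empty feature-class
    subsets (31 for the five classes; the default ladder has 50 rungs for
    1550 candidates)."""
    if rm_step <= 0:
        raise ValueError("rm_step must be positive")
    n = int(round((rm_max - rm_min) / rm_step)) + 1
    if n < 1 or rm_max < rm_min:
        raise ValueError("empty RM ladder")
    rms = np.round(rm_min + rm_step * np.arange(n), 10)
    fcs = [
        "".join(combo)
        for r in range(1, len(classes) + 1)
        for combo in itertools.combinations(classes, r)
    ]
    return [(float(rm), fc) for rm in rms for fc in fcs]


def maxent_log_lik(model: MaxentModel, X_presence, stack: GridStack) -> float:
    """Presence log-likelihood with the raw distribution renormalized over
    every unmasked cell of the projection grid."""
    rows, cols = stack.unmasked_cells()
    X_grid = pd.DataFrame(stack.to_matrix(rows, cols), columns=stack.names)
    eta_grid = model.eta(X_grid)
    log_z = logsumexp(eta_grid)
    eta_p = model.eta(X_presence)
    return float(np.sum(eta_p - log_z))


def aicc(log_lik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: 2k - 2 lnL + 2k(k+1)/(n-k-1); NaN when
    n <= k + 1 (the candidate is disqualified)."""
    if n <= k + 1:
        return np.nan
    aic = 2 * k - 2 * log_lik
    return aic + 2 * k * (k + 1) / (n - k - 1)


def omission_rates(train_preds, test_preds) -> tuple[float, float]:
    """(OR_mtp, OR_10): fraction of test presences predicted strictly below
    the minimum / the nearest-rank 10th percentile of training predictions."""
    tr = np.sort(np.asarray(train_preds, dtype=float))
    te = np.asarray(test_preds, dtype=float)
    if len(tr) == 0 or len(te) == 0:
        raise ValueError("both prediction sets must be non-empty")
    mtp = tr[0]
    rank = max(int(np.ceil(0.1 * len(tr))) - 1, 0)  # nearest-rank percentile
    p10 = tr[rank]
    return float(np.mean(te < mtp)), float(np.mean(te < p10))


def _partial_auc_ratio(pres: np.ndarray, bg_sorted: np.ndarray, e: float) -> float:
    """AUC ratio of one sample: partial area of the sensitivity vs
    proportion-of-area curve restricted to sensitivity >= 1 - E, divided by
    the same partial area under the chance diagonal."""
    m = len(bg_sorted)
    cand = np.unique(np.concatenate([pres, bg_sorted]))
    # descending thresholds trace the curve from (0,0) to (1,1)
    thr = cand[::-1]
    x = (m - np.searchsorted(bg_sorted, thr, side="left")) / m  # proportion of area >= t
    ps = np.sort(pres)
    y = (len(ps) - np.searchsorted(ps, thr, side="left")) / len(ps)  # sensitivity
    x = np.concatenate([[0.0], x, [1.0]])
    y = np.concatenate([[0.0], y, [1.0]])
    keep = y >= 1.0 - e
    if keep.sum() < 2:
        return np.nan
    xs, ys = x[keep], y[keep]
    model_area = float(np.trapezoid(ys, xs))
    null_area = float((xs[-1] ** 2 - xs[0] ** 2) / 2.0)
    if null_area <= 0:
        return np.nan
    return model_area / null_area


def partial_roc(
    test_presence_preds,
    background_preds,
    e: float = 0.05,
    n_boot: int = 500,
    boot_frac: float = 0.5,
    seed: int = 0,
) -> tuple[float, float]:
    """Partial-ROC test: bootstrap the test presences (``boot_frac`` of them
    with replacement), compute the AUC ratio at error rate ``e`` for each
    resample, and report (mean ratio, p) where p is the fraction of resamples
    with ratio <= 1 (chance performance)."""
    if not 0 < e < 0.5:
        raise ValueError("E must be in (0, 0.5)")
    pres = np.asarray(test_presence_preds, dtype=float)
    if len(pres) < 5:
        raise ValueError("partial ROC needs at least 5 test presences")
    bg = np.sort(np.asarray(background_preds, dtype=float))
    rng = np.random.default_rng(seed)
    n_take = max(int(round(boot_frac * len(pres))), 2)
    ratios = np.empty(n_boot)
    for i in range(n_boot):
        sample = rng.choice(pres, size=n_take, replace=True)
        ratios[i] = _partial_auc_ratio(sample, bg, e)
    ok = np.isfinite(ratios)
    if not ok.any():
        return np.nan, np.nan
    ratios = ratios[ok]
    return float(ratios.mean()), float(np.mean(ratios <= 1.0))


def select_champion(
    scores: list[CandidateScore],
    or_cap: float = 0.1,
    alpha: float = 0.05,
) -> CandidateScore:
    """Champion selection: significant partial ROC (p < alpha), then
    OR_10 <= or_cap, then minimum AICc; ties prefer fewer parameters, then a
    smaller regularization multiplier.  A filter that would eliminate every
    candidate is relaxed with a warning."""
    if not scores:
        raise ValueError("no candidates")
    pool = [s for s in scores if np.isfinite(s.aicc)]
    if not pool:
        warnings.warn("no candidate has a defined AICc; falling back to log-likelihood", stacklevel=2)
        pool = sorted(scores, key=lambda s: (-s.log_lik, s.k, s.rm))
        return pool[0]
    sig = [s for s in pool if np.isfinite(s.proc_p) and s.proc_p < alpha]
    if sig:
        pool = sig
    else:
        warnings.warn("no candidate passes the partial-ROC significance filter; relaxed", stacklevel=2)
    low_or = [s for s in pool if np.isfinite(s.or_10) and s.or_10 <= or_cap]
    if low_or:
        pool = low_or
    else:
        warnings.warn("no candidate passes the omission-rate filter; relaxed", stacklevel=2)
    return min(pool, key=lambda s: (s.aicc, s.k, s.rm))


def tune(
    model: MaxentModel,
    X_presence: pd.DataFrame,
    background: BackgroundSample,
    stack: GridStack,
    candidates: list[tuple[float, str]] | None = None,
    test_fraction: float = 0.25,
    seed: int = 0,
    proc_boot: int = 200,
) -> tuple[CandidateScore, pd.DataFrame]:
    """Score every (rm, fc) candidate on one fixed train/test presence split
    and select the champion.  Returns (champion, candidate table)."""
    if candidates is None:
        candidates = candidate_space()
    n = len(X_presence)
    n_test = max(int(round(test_fraction * n)), 5)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test, train = perm[:n_test], perm[n_test:]
    Xtr, Xte = X_presence.iloc[train], X_presence.iloc[test]
    y = np.concatenate([np.ones(len(Xtr)), np.zeros(len(background.X))])
    Xfit = pd.concat([Xtr, background.X], ignore_index=True)
    scores: list[CandidateScore] = []
    for rm, fc in candidates:
        cand = clone(model)
        cand.set_params(rm=rm, feature_classes=fc)
        cand.fit(Xfit, y)
        k = int(np.sum(cand.coef_ != 0))
        ll = maxent_log_lik(cand, Xtr, stack)
        tr_pred = cand.predict(Xtr)
        te_pred = cand.predict(Xte)
        bg_pred = cand.predict(background.X)
        or_mtp, or_10 = omission_rates(tr_pred, te_pred)
        ratio, p = partial_roc(te_pred, bg_pred, n_boot=proc_boot, seed=seed)
        scores.append(
            CandidateScore(
                rm=rm, fc=fc, k=k, log_lik=ll, aicc=aicc(ll, k, len(Xtr)),
                or_mtp=or_mtp, or_10=or_10, proc_ratio=ratio, proc_p=p,
            )
        )
    champion = select_champion(scores)
    table = pd.DataFrame([vars(s) for s in scores])
    table["selected"] = [(s.rm == champion.rm and s.fc == champion.fc) for s in scores]
    return champion, table
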