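"""Presence / pseudo-absence evaluation panel.

Threshold-dependent metrics (TSS, Kappa, Jaccard, Sorensen) are computed at
the threshold that maximizes the true skill statistic, on a confusion table
built from held-out presence predictions and an equal number of random
pseudo-absences (prevalence 0.5).  Threshold-free metrics are the rank AUC
and the continuous Boyce index.  Note that at exactly 0.5 prevalence and a
common threshold, Kappa and TSS coincide algebraically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, spearmanr

from .grids import Grid

__all__ = [
    "ConfusionTable",
    "EvaluationReport",
    "confusion_at",
    "tss",
    "kappa",
    "jaccard",
    "sorensen",
    "auc_score",
    "max_tss_threshold",
    "boyce",
    "pseudo_absences_for_eval",
    "evaluate_predictions",
]


@dataclass
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ValueError("empty confusion table")


@dataclass
class EvaluationReport:
    """Seven-metric panel plus omission rates, the max-TSS threshold and its
    confusion table.  ``proc_ratio`` is filled by the tuning stage when a
    partial-ROC test is run; otherwise NaN."""

    auc: float
    tss: float
    kappa: float
    boyce: float
    jaccard: float
    sorensen: float
    threshold: float
    confusion: ConfusionTable
    or_mtp: float = np.nan
    or_10: float = np.nan
    proc_ratio: float = np.nan

    def as_dict(self) -> dict[str, float]:
        d = {
            k: getattr(self, k)
            for k in ("auc", "proc_ratio", "tss", "kappa", "boyce", "jaccard", "sorensen", "or_mtp", "or_10", "threshold")
        }
        return d


def confusion_at(threshold: float, presence_preds, absence_preds) -> ConfusionTable:
    """Confusion table with 'suitable' meaning prediction >= threshold."""
    p = np.asarray(presence_preds, dtype=float)
    a = np.asarray(absence_preds, dtype=float)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return ConfusionTable(
        tp=int((p >= threshold).sum()),
        fn=int((p < threshold).sum()),
        fp=int((a >= threshold).sum()),
        tn=int((a < threshold).sum()),
    )


def tss(conf: ConfusionTable) -> float:
    """True skill statistic: sensitivity + specificity - 1."""
    if conf.tp + conf.fn == 0 or conf.tn + conf.fp == 0:
        return np.nan
    return conf.tp / (conf.tp + conf.fn) + conf.tn / (conf.tn + conf.fp) - 1.0


def kappa(conf: ConfusionTable) -> float:
    """Cohen's kappa from the confusion table marginals."""
    n = conf.tp + conf.fp + conf.fn + conf.tn
    po = (conf.tp + conf.tn) / n
    pe = ((conf.tp + conf.fn) * (conf.tp + conf.fp) + (conf.tn + conf.fp) * (conf.tn + conf.fn)) / n**2
    if pe == 1.0:
        return np.nan
    return (po - pe) / (1.0 - pe)


def jaccard(conf: ConfusionTable) -> float:
    denom = conf.tp + conf.fn + conf.fp
    return np.nan if denom == 0 else conf.tp / denom


def sorensen(conf: ConfusionTable) -> float:
    denom = 2 * conf.tp + conf.fn + conf.fp
    return np.nan if denom == 0 else 2 * conf.tp / denom


def auc_score(presence_preds, absence_preds) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    p = np.asarray(presence_preds, dtype=float)
    a = np.asarray(absence_preds, dtype=float)
    if len(p) == 0 or len(a) == 0:
        raise ValueError("both prediction sets must be non-empty")
    ranks = rankdata(np.concatenate([p, a]))
    u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2
    return float(u / (len(p) * len(a)))


def max_tss_threshold(presence_preds, absence_preds, step: float = 0.001) -> tuple[float, float]:
    """Threshold maximizing TSS over all observed prediction values plus a
    uniform step ladder on [0, 1]; ties return the lowest threshold."""
    p = np.sort(np.asarray(presence_preds, dtype=float))
    a = np.sort(np.asarray(absence_preds, dtype=float))
    if len(p) == 0 or len(a) == 0:
        raise ValueError("both prediction sets must be non-empty")
    cand = np.unique(np.concatenate([p, a, np.arange(0.0, 1.0 + step / 2, step)]))
    tp = len(p) - np.searchsorted(p, cand, side="left")
    fp = len(a) - np.searchsorted(a, cand, side="left")
    tss_vals = tp / len(p) + (len(a) - fp) / len(a) - 1.0
    best = int(np.argmax(tss_vals))  # argmax returns the first (lowest) maximizer
    return float(cand[best]), float(tss_vals[best])


def boyce(
    presence_preds,
    background_preds,
    n_windows: int = 101,
    window_frac: float = 0.1,
) -> float:
    """Continuous Boyce index.

    Moving windows of width ``window_frac`` times the background prediction
    range slide across that range; in each, the predicted-to-expected ratio
    P/E = (presence fraction) / (background fraction) is computed, and the
    index is the Spearman correlation of P/E with the window midpoints
    (windows with no background are skipped).
    """
    p = np.asarray(presence_preds, dtype=float)
    b = np.asarray(background_preds, dtype=float)
    if len(p) < 10:
        raise ValueError("Boyce index needs at least 10 presences")
    lo, hi = b.min(), b.max()
    if hi <= lo:
        return np.nan
    width = window_frac * (hi - lo)
    mids = np.linspace(lo + width / 2, hi - width / 2, n_windows)
    pe, kept = [], []
    for m in mids:
        lo_w, hi_w = m - width / 2, m + width / 2
        nb = np.sum((b >= lo_w) & (b <= hi_w))
        if nb == 0:
            continue
        np_ = np.sum((p >= lo_w) & (p <= hi_w))
        pe.append((np_ / len(p)) / (nb / len(b)))
        kept.append(m)
    if len(pe) < 3 or len(set(pe)) < 2:
        return np.nan
    rho, _ = spearmanr(pe, kept)
    return float(rho)


def pseudo_absences_for_eval(
    n_presences: int,
    region: Grid,
    seed: int = 0,
    exclude_rows=None,
    exclude_cols=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample exactly ``n_presences`` pseudo-absence cells uniformly from the
    region's unmasked cells, excluding presence cells, so the evaluation set
    has 50% prevalence.  Returns (rows, cols)."""
    if n_presences == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    rows, cols = np.where(~region.mask)
    flat = rows * region.n_cols + cols
    if exclude_rows is not None and len(exclude_rows):
        occupied = np.asarray(exclude_rows) * region.n_cols + np.asarray(exclude_cols)
        flat = np.setdiff1d(flat, occupied)
    if len(flat) < n_presences:
        raise ValueError("not enough unmasked non-presence cells for pseudo-absences")
    rng = np.random.default_rng(seed)
    take = rng.choice(flat, size=n_presences, replace=False)
    return take // region.n_cols, take % region.n_cols


def evaluate_predictions(
    pred_grid: Grid,
    test_lon,
    test_lat,
    seed: int = 0,
    or_rates: tuple[float, float] | None = None,
    proc_ratio: float = np.nan,
) -> EvaluationReport:
    """Full evaluation panel of a suitability grid against held-out presences.

    Pseudo-absences are drawn at 0.5 prevalence from unmasked non-presence
    cells; the Boyce background is the whole unmasked grid.
    """
    p_preds = pred_grid.values_at(test_lon, test_lat)
    if np.any(np.isnan(p_preds)):
        raise ValueError("some test presences fall outside the prediction grid")
    prow, pcol = pred_grid.rowcol(np.asarray(test_lon, float), np.asarray(test_lat, float))
    arow, acol = pseudo_absences_for_eval(len(p_preds), pred_grid, seed=seed, exclude_rows=prow, exclude_cols=pcol)
    a_preds = pred_grid.values[arow, acol]
    thr, t = max_tss_threshold(p_preds, a_preds)
    conf = confusion_at(thr, p_preds, a_preds)
    bg_all = pred_grid.values[~pred_grid.mask]
    report = EvaluationReport(
        auc=auc_score(p_preds, a_preds),
        tss=t,
        kappa=kappa(conf),
        boyce=boyce(p_preds, bg_all),
        jaccard=jaccard(conf),
        sorensen=sorensen(conf),
        threshold=thr,
        confusion=conf,
        proc_ratio=proc_ratio,
    )
    if or_rates is not None:
        report.or_mtp, report.or_10 = or_rates
    return report
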