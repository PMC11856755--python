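"""Predictor screening: Pearson correlation, variance inflation factors, and
contribution-ranked elimination of collinear variables.

A candidate set is screened iteratively: while any pair has |r| >= ``r_max``
(default 0.8) or any variable has VIF >= ``vif_max`` (default 10), the
violating variable with the lowest model percent contribution is dropped and
the diagnostics are recomputed.  Contributions may be a fixed mapping or a
callable that refits the suitability model on the surviving candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = ["VariableScreen", "ScreeningError", "pearson_matrix", "vif", "screen_variables"]


class ScreeningError(RuntimeError):
    pass


@dataclass
class VariableScreen:
    """Outcome of collinearity screening."""

    candidates: list[str]
    retained: list[str]
    pearson: pd.DataFrame
    vif: pd.Series
    contribution: pd.Series
    trail: list[str] = field(default_factory=list)


def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Product-moment correlation matrix of the table's columns."""
    if len(table) < 3:
        raise ValueError("need at least 3 observations")
    sd = table.std(ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s): {', '.join(constant)}")
    r = np.corrcoef(table.to_numpy(float), rowvar=False)
    r = np.atleast_2d(r)
    return pd.DataFrame(r, index=table.columns, columns=table.columns)


def vif(table: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1-R^2_j) from regressing each column on
    all others with an intercept.  Perfect collinearity yields +inf."""
    X = table.to_numpy(float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than variables")
    out = {}
    for j, name in enumerate(table.columns):
        if p == 1:
            out[name] = 1.0
            continue
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            raise ValueError(f"constant column {name!r}")
        r2 = 1 - np.sum(resid**2) / ss_tot
        out[name] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def screen_variables(
    table: pd.DataFrame,
    contributions: Mapping[str, float] | Callable[[list[str]], Mapping[str, float]],
    r_max: float = 0.8,
    vif_max: float = 10.0,
) -> VariableScreen:
    """Iteratively eliminate collinear variables, keeping high contributors.

    Parameters
    ----------
    table : DataFrame
        Variable values over the screening domain (background cells).
    contributions : mapping or callable
        Percent contribution per variable; a callable receives the current
        candidate list and returns refreshed contributions (model refit).
    """
    candidates = list(table.columns)
    trail: list[str] = []

    def get_contrib(names):
        c = contributions(names) if callable(contributions) else contributions
        return pd.Series({n: float(c[n]) for n in names})

    current = candidates
    while True:
        if not current:
            raise ScreeningError("all variables were eliminated")
        sub = table[current]
        r = pearson_matrix(sub)
        v = vif(sub) if len(current) > 1 else pd.Series({current[0]: 1.0})
        contrib = get_contrib(current)
        ra = r.to_numpy().copy()
        np.fill_diagonal(ra, 0.0)
        bad_i, bad_j = np.where(np.abs(ra) >= r_max)
        pair_bad = {current[i] for i in np.concatenate([bad_i, bad_j])}
        vif_bad = set(v[v >= vif_max].index)
        violators = sorted(pair_bad | vif_bad)
        if not violators:
            return VariableScreen(
                candidates=candidates,
                retained=current,
                pearson=r,
                vif=v,
                contribution=contrib,
                trail=trail,
            )
        if len(current) == 1:
            raise ScreeningError("single remaining variable still violates thresholds")
        # drop lowest contribution; ties -> higher VIF, then variable code
        def sort_key(name):
            vv = v[name]
            return (contrib[name], -(np.inf if np.isinf(vv) else vv), name)

        drop = min(violators, key=sort_key)
        trail.append(
            f"dropped {drop}: contribution={contrib[drop]:.2f}%, VIF={v[drop]:.2f}, "
            f"max|r|={np.abs(ra)[current.index(drop)].max():.3f}"
        )
        current = [c for c in current if c != drop]
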