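"""Module-trait association: eigengene vs phenotype correlation.

Each module eigengene is correlated (Pearson) with each adjusted trait;
significance comes from the exact t transform

    t = r * sqrt((n - 2) / (1 - r^2)),   p two-sided with n - 2 df.

Cells are computed pairwise-complete (missing phenotype values drop the
sample for that cell only) and report their exact n, since missingness makes
n vary by trait.  No multiple-testing correction is applied at this stage;
the full (r, p, n) matrix is emitted so users can apply their own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PhenotypeTable, ValidationError, log

_TINY = np.finfo(float).tiny


def pearson_r_to_p(r, n):
    """Two-sided p for a Pearson correlation via the t transform.

    |r| = 1 underflows the t distribution; the p-value is clamped to the
    smallest positive representable double rather than reported as 0.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 0.0))
    p = np.where(np.isinf(t) | (np.abs(r) >= 1.0), 0.0,
                 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1)))
    p = np.where(n < 3, np.nan, p)
    return np.maximum(p, _TINY)


def pearson_pairwise(X: np.ndarray, Y: np.ndarray):
    """All cross-pairs Pearson r, p and n between rows of X and rows of Y.

    Rows are variables, columns are (aligned) samples.  NaNs trigger a
    pairwise-complete path; otherwise a single matrix product computes all
    correlations.  Returns (r, p, n) arrays of shape (X rows, Y rows).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] != Y.shape[1]:
        raise ValidationError("sample dimensions are misaligned")
    ns = X.shape[1]
    if not (np.isnan(X).any() or np.isnan(Y).any()):
        Xs = X - X.mean(axis=1, keepdims=True)
        Ys = Y - Y.mean(axis=1, keepdims=True)
        Xn = Xs / np.sqrt((Xs ** 2).sum(axis=1, keepdims=True))
        Yn = Ys / np.sqrt((Ys ** 2).sum(axis=1, keepdims=True))
        r = np.clip(Xn @ Yn.T, -1.0, 1.0)
        n = np.full(r.shape, ns)
        return r, pearson_r_to_p(r, n), n
    r = np.full((X.shape[0], Y.shape[0]), np.nan)
    n = np.zeros(r.shape, dtype=int)
    for i in range(X.shape[0]):
        xi = X[i]
        ok_x = ~np.isnan(xi)
        for j in range(Y.shape[0]):
            yj = Y[j]
            ok = ok_x & ~np.isnan(yj)
            cnt = int(ok.sum())
            n[i, j] = cnt
            if cnt >= 3:
                xv, yv = xi[ok], yj[ok]
                if xv.std() == 0 or yv.std() == 0:
                    continue
                r[i, j] = np.clip(np.corrcoef(xv, yv)[0, 1], -1.0, 1.0)
    return r, pearson_r_to_p(r, n), n


@dataclass
class ModuleTraitMatrix:
    """Modules x traits grid of (r, two-sided p, n per cell)."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    @property
    def modules(self) -> list[str]:
        return list(self.r.index)

    @property
    def traits(self) -> list[str]:
        return list(self.r.columns)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.modules:
            for t in self.traits:
                rows.append({"module": m, "trait": t, "r": self.r.loc[m, t],
                             "p": self.p.loc[m, t], "n": self.n.loc[m, t]})
        return pd.DataFrame(rows)


@dataclass
class TraitAssociatedModules:
    """Modules with at least one trait cell below the significance threshold."""

    alpha: float
    cells: pd.DataFrame          # module, trait, r, p (all passing cells)
    best_per_module: pd.DataFrame  # one row per module: its most significant cell

    @property
    def modules(self) -> list[str]:
        return list(self.best_per_module["module"])


def module_trait_correlation(eigengenes: pd.DataFrame,
                             ph: PhenotypeTable) -> ModuleTraitMatrix:
    """Correlate each eigengene (modules x samples) with each trait."""
    shared = [s for s in eigengenes.columns if s in ph.data.index]
    if len(shared) < 3:
        raise ValidationError("module-trait correlation needs >= 3 shared samples")
    E = eigengenes.loc[:, shared].to_numpy(dtype=float)
    T = ph.data.loc[shared].to_numpy(dtype=float).T
    r, p, n = pearson_pairwise(E, T)
    low_n = n < 3
    if low_n.any():
        log.warning("%d module-trait cell(s) have n < 3 and are reported missing",
                    int(low_n.sum()))
        r = np.where(low_n, np.nan, r)
        p = np.where(low_n, np.nan, p)
    idx, cols = eigengenes.index, ph.data.columns
    return ModuleTraitMatrix(pd.DataFrame(r, idx, cols),
                             pd.DataFrame(p, idx, cols),
                             pd.DataFrame(n, idx, cols))


def select_trait_modules(mtm: ModuleTraitMatrix, alpha: float = 0.05,
                         traits: list[str] | None = None) -> TraitAssociatedModules:
    """All (module, trait) cells with p < alpha, optionally over a trait subset.

    Each passing module is also listed once with its single best cell.
    """
    if not 0 <= alpha <= 1:
        raise ValidationError("alpha must be in [0, 1]")
    traits = list(mtm.traits) if traits is None else list(traits)
    rows = []
    for m in mtm.modules:
        for t in traits:
            p = mtm.p.loc[m, t]
            if pd.notna(p) and p < alpha:
                rows.append({"module": m, "trait": t,
                             "r": mtm.r.loc[m, t], "p": p, "n": mtm.n.loc[m, t]})
    cells = pd.DataFrame(rows, columns=["module", "trait", "r", "p", "n"])
    if len(cells):
        best = (cells.sort_values(["p", "trait"], kind="mergesort")
                .groupby("module", sort=True).first().reset_index())
    else:
        best = pd.DataFrame(columns=["module", "trait", "r", "p", "n"])
    return TraitAssociatedModules(alpha, cells, best)
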