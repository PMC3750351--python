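"""Adjustment of expression and phenotypes for systematic effects.

Expression intensities and trait measurements both carry systematic,
non-biological structure (sex, ryanodine-receptor genotype, sire, slaughter
day, carcass weight).  Downstream correlation-based analyses therefore run
on *residuals* from a linear adjustment.  Two adjusters are provided:

* ``fixed_ols`` (default) — per-probe ordinary least squares against the full
  design with every categorical term dummy-coded; residuals are exactly
  orthogonal to the design's column space, which makes the adjustment
  idempotent and directly testable.
* ``reml_one_random`` — a single-random-intercept linear mixed model fitted
  by restricted maximum likelihood; residuals subtract both the fixed-effect
  fit and the predicted random effects (BLUPs).

Between-chip quantile normalization and dendrogram-based removal of extreme
outlier samples complete the stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .io_formats import (CovariateTable, ExpressionMatrix, PhenotypeTable,
                         ValidationError, log)


@dataclass
class DesignSpec:
    """Which covariates enter the adjustment, and how.

    ``fixed_effects`` are always-categorical fixed terms; ``group_effects``
    are grouping factors (treated as fixed dummies under ``fixed_ols``, or
    one of them as a random intercept under ``reml_one_random``);
    ``numeric_covariates`` enter linearly.
    """

    fixed_effects: tuple[str, ...] = ("sex", "ryr")
    group_effects: tuple[str, ...] = ("sire", "slaughter_day")
    numeric_covariates: tuple[str, ...] = ("carcass_weight",)

    def all_columns(self) -> tuple[str, ...]:
        return (*self.fixed_effects, *self.group_effects, *self.numeric_covariates)


def build_design_matrix(cov: CovariateTable, design: DesignSpec,
                        samples: list[str],
                        exclude: tuple[str, ...] = ()) -> pd.DataFrame:
    """Intercept + reference-coded dummies + centered numeric covariates.

    Raises a validation error listing aliased columns if the result is rank
    deficient.
    """
    missing = [c for c in design.all_columns() if c not in cov.data.columns]
    if missing:
        raise ValidationError(f"covariate column(s) not found: {', '.join(missing)}")
    absent = [s for s in samples if s not in cov.data.index]
    if absent:
        raise ValidationError(f"sample(s) missing from covariate table: {absent[:5]}")
    df = cov.data.loc[samples]
    parts = [pd.DataFrame({"Intercept": 1.0}, index=df.index)]
    for col in (*design.fixed_effects, *design.group_effects):
        if col in exclude:
            continue
        dummies = pd.get_dummies(df[col].astype(str), prefix=col, drop_first=True,
                                 dtype=float)
        dummies = dummies[sorted(dummies.columns)]
        parts.append(dummies)
    for col in design.numeric_covariates:
        vals = pd.to_numeric(df[col])
        parts.append(pd.DataFrame({col: vals - vals.mean()}, index=df.index))
    X = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR: small trailing R diagonal
        from scipy.linalg import qr
        _, R, piv = qr(X.to_numpy(), mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [X.columns[piv[k]] for k in range(len(diag)) if diag[k] <= tol]
        raise ValidationError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased column(s): {', '.join(map(str, aliased))}")
    return X


def _ols_residuals(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Rows of Y regressed on columns of X; Y is variables x samples."""
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return Y - (X @ beta).T


def quantile_normalize(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column to share the per-rank column-mean distribution.

    Ties within a column receive the mean of the reference values at the
    ranks the tied group occupies, so permuted columns map to permuted
    identical outputs and within-column rank order is preserved.
    """
    if mat.data.shape[1] < 2:
        raise ValidationError("quantile normalization requires >= 2 samples")
    vals = mat.values
    order = np.argsort(vals, axis=0, kind="stable")
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    n = vals.shape[0]
    for c in range(vals.shape[1]):
        col = vals[:, c]
        idx = order[:, c]
        assigned = np.empty(n)
        i = 0
        while i < n:
            j = i
            while j + 1 < n and col[idx[j + 1]] == col[idx[i]]:
                j += 1
            assigned[idx[i:j + 1]] = ref[i:j + 1].mean()
            i = j + 1
        out[:, c] = assigned
    return ExpressionMatrix(pd.DataFrame(out, index=mat.data.index,
                                         columns=mat.data.columns),
                            layer_tag="normalized")


def adjust_for_effects(mat: ExpressionMatrix, cov: CovariateTable,
                       design: DesignSpec, mode: str = "fixed_ols",
                       random_effect: str = "sire") -> ExpressionMatrix:
    """Per-probe residuals of expression against the systematic-effect design."""
    if mode not in {"fixed_ols", "reml_one_random"}:
        raise ValidationError(f"unknown adjustment mode {mode!r}")
    samples = mat.sample_ids
    if mode == "fixed_ols":
        X = build_design_matrix(cov, design, samples)
        resid = _ols_residuals(mat.values, X.to_numpy())
    else:
        if random_effect not in design.group_effects:
            raise ValidationError(
                f"random effect {random_effect!r} must be one of the design's "
                f"group effects {design.group_effects}")
        X = build_design_matrix(cov, design, samples, exclude=(random_effect,))
        groups = cov.data.loc[samples, random_effect].astype(str).to_numpy()
        resid = np.empty_like(mat.values)
        from statsmodels.regression.mixed_linear_model import MixedLM
        Xa = X.to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k, probe in enumerate(mat.probe_ids):
                y = mat.values[k]
                model = MixedLM(y, Xa, groups=groups)
                fit = None
                for method in (None, "powell"):
                    try:
                        fit = model.fit(reml=True, **({} if method is None
                                                      else {"method": method}))
                        break
                    except (np.linalg.LinAlgError, ValueError):
                        continue
                if fit is None:
                    # zero-variance random effect: the REML fit degenerates to
                    # the fixed-effects model with group dummies
                    log.warning("REML failed for probe %s; using fixed-effects "
                                "limit", probe)
                    Xg = pd.get_dummies(pd.Series(groups), drop_first=True,
                                        dtype=float).to_numpy()
                    resid[k] = _ols_residuals(y[None, :],
                                              np.hstack([Xa, Xg]))[0]
                    continue
                blup = np.zeros_like(y)
                for g, b in fit.random_effects.items():
                    blup[groups == g] = np.asarray(b)[0]
                resid[k] = y - Xa @ fit.fe_params - blup
    return ExpressionMatrix(pd.DataFrame(resid, index=mat.data.index,
                                         columns=mat.data.columns),
                            layer_tag="residual")


def adjust_phenotypes(ph: PhenotypeTable, cov: CovariateTable,
                      design: DesignSpec, mode: str = "fixed_ols",
                      random_effect: str = "sire") -> PhenotypeTable:
    """Residualize each trait case-wise (missing values dropped per trait)."""
    out = pd.DataFrame(np.nan, index=ph.data.index, columns=ph.data.columns)
    for trait in ph.trait_names:
        y = ph.data[trait]
        ok = y.notna()
        if not ok.any():
            raise ValidationError(f"trait {trait!r} has no observed values")
        sub = ExpressionMatrix(pd.DataFrame([y[ok].to_numpy()], index=[trait],
                                            columns=list(y.index[ok])),
                               layer_tag="raw")
        res = adjust_for_effects(sub, cov, design, mode=mode,
                                 random_effect=random_effect)
        out.loc[ok, trait] = res.values[0]
    return PhenotypeTable(out)


def remove_outlier_samples(mat: ExpressionMatrix,
                           cut_z: float = 4.0) -> tuple[ExpressionMatrix, list[str]]:
    """Flag extreme samples from an average-linkage Euclidean dendrogram.

    A sample is removed when the height at which it first merges into the
    tree exceeds median + ``cut_z`` * MAD of all first-merge heights.  The
    procedure is applied once (no iteration).
    """
    if cut_z <= 0:
        raise ValidationError("cut_z must be > 0")
    n = mat.data.shape[1]
    if n < 3:
        raise ValidationError("outlier screening requires >= 3 samples")
    D = pdist(mat.values.T, metric="euclidean")
    Z = linkage(D, method="average")
    first_merge = np.full(n, np.nan)
    members: list[list[int]] = [[i] for i in range(n)]
    for a, b, height, _ in Z:
        merged = members[int(a)] + members[int(b)]
        for leaf in merged:
            if np.isnan(first_merge[leaf]):
                first_merge[leaf] = height
        members.append(merged)
    med = np.nanmedian(first_merge)
    mad = 1.4826 * np.nanmedian(np.abs(first_merge - med))  # consistency-scaled
    if mad == 0:
        cut = med + cut_z * np.finfo(float).eps
    else:
        cut = med + cut_z * mad
    removed = [mat.sample_ids[i] for i in range(n) if first_merge[i] > cut]
    if removed:
        log.warning("removing %d outlier sample(s): %s", len(removed), removed)
    kept = [s for s in mat.sample_ids if s not in removed]
    return mat.subset_samples(kept), removed
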