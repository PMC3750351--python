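"""miRNA-mRNA expression integration and the regulatory-link filter.

Every miRNA probe is correlated with every mRNA probe (Pearson, on
residualized profiles), multiplicity is controlled by q-values, and a
regulatory link to the organismal phenotype is suspected when

1. the mRNA belongs to a co-expression module associated with the traits,
2. mRNA abundance is significantly negatively correlated with the miRNA
   (q at or below the FDR level), and
3. the mRNA is predicted as a target of the miRNA by seed complementarity
   or by hybridization energy.

Criteria 1 and 2 define the candidate edge set; criterion 3 marks the fully
confirmed subset.  miRNA probes are collapsed to their family for reporting
(the family row carries its most negative probe-level pair), with all
probe-level rows retained in a companion table.

q-values follow the Storey estimator with the pi0 smoother replaced by a
deterministic monotone-median rule over the lambda grid; ``bh`` mode fixes
pi0 = 1 and reduces to Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coexpression import GREY, ModuleDecomposition
from .io_formats import ExpressionMatrix, ValidationError
from .module_trait import TraitAssociatedModules, pearson_pairwise


@dataclass
class PairCorrelationTable:
    """Long-format cross-pair records plus the total test count m.

    ``m_total`` always reflects the full miRNA x mRNA grid even when the
    correlation pass ran on a probe subset, so FDR control refers to the
    full family of tests.
    """

    records: pd.DataFrame        # columns: miRNA, mRNA, r, p, [q], n
    m_total: int
    implied_p_cutoff: float | None = None

    def __len__(self) -> int:
        return len(self.records)


def all_pairs_correlation(mirna: ExpressionMatrix, mrna: ExpressionMatrix,
                          mirna_subset: list[str] | None = None,
                          mrna_subset: list[str] | None = None
                          ) -> PairCorrelationTable:
    """Pearson r and two-sided p for every miRNA-probe x mRNA-probe pair.

    ``m_total`` is the number of tests implied by the full probe lists;
    the optional subsets restrict only which correlations are materialized.
    """
    if mirna.sample_ids != mrna.sample_ids:
        shared = [s for s in mirna.sample_ids if s in set(mrna.sample_ids)]
        if len(shared) < 3 or len(shared) != len(mirna.sample_ids) or \
                len(shared) != len(mrna.sample_ids):
            raise ValidationError("miRNA and mRNA matrices are not sample-aligned")
        mrna = mrna.subset_samples(mirna.sample_ids)
    m_total = len(mirna.probe_ids) * len(mrna.probe_ids)
    mi = mirna if mirna_subset is None else ExpressionMatrix(
        mirna.data.loc[list(mirna_subset)], layer_tag=mirna.layer_tag)
    mr = mrna if mrna_subset is None else ExpressionMatrix(
        mrna.data.loc[list(mrna_subset)], layer_tag=mrna.layer_tag)
    r, p, n = pearson_pairwise(mi.values, mr.values)
    mi_ids = np.repeat(mi.probe_ids, len(mr.probe_ids))
    mr_ids = np.tile(mr.probe_ids, len(mi.probe_ids))
    records = pd.DataFrame({"miRNA": mi_ids, "mRNA": mr_ids,
                            "r": r.ravel(), "p": p.ravel(), "n": n.ravel()})
    return PairCorrelationTable(records, m_total)


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

DEFAULT_LAMBDA_GRID = tuple(round(0.05 * i, 2) for i in range(1, 20))


def estimate_pi0(p: np.ndarray, lambda_grid=DEFAULT_LAMBDA_GRID) -> float:
    """Null-proportion estimate by the monotone-median rule.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the grid,
    forced monotone non-increasing in lambda by a running minimum, and the
    median of the monotone sequence is taken, clipped to [1/m, 1].
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    grid = np.asarray(sorted(lambda_grid), dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValidationError("lambda grid values must lie in (0, 1)")
    raw = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    monotone = np.minimum.accumulate(raw)
    pi0 = float(np.median(monotone))
    return min(1.0, max(pi0, 1.0 / m))


def qvalues(p, method: str = "storey", lambda_grid=DEFAULT_LAMBDA_GRID,
            m: int | None = None, pi0: float | None = None) -> np.ndarray:
    """FDR q-values for a list of p-values.

    ``storey`` estimates pi0 from the data (monotone-median rule); ``bh``
    fixes pi0 = 1 (Benjamini-Hochberg).  ``m`` overrides the total test
    count when only a subset of p-values is materialized; untested p-values
    are then implicitly treated as non-significant (conservative).
    q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    if method not in {"storey", "bh"}:
        raise ValidationError(f"unknown q-value method {method!r}")
    if p.size == 0:
        return np.array([])
    m_eff = len(p) if m is None else int(m)
    if m_eff < len(p):
        raise ValidationError("m cannot be smaller than the number of p-values")
    if pi0 is None:
        pi0 = 1.0 if method == "bh" else estimate_pi0(p, lambda_grid)
    if not 0 < pi0 <= 1:
        raise ValidationError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, len(p) + 1)
    q_sorted = pi0 * m_eff * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def attach_qvalues(table: PairCorrelationTable, method: str = "storey",
                   lambda_grid=DEFAULT_LAMBDA_GRID,
                   pi0: float | None = None) -> PairCorrelationTable:
    """Add a q column over the table's full test count m_total."""
    q = qvalues(table.records["p"].to_numpy(), method, lambda_grid,
                m=table.m_total, pi0=pi0)
    rec = table.records.copy()
    rec["q"] = q
    return PairCorrelationTable(rec, table.m_total, table.implied_p_cutoff)


def filter_negative_pairs(table: PairCorrelationTable,
                          fdr: float = 0.1) -> PairCorrelationTable:
    """Keep pairs with r < 0 and q <= fdr; record the implied p cutoff."""
    if "q" not in table.records.columns:
        raise ValidationError("q-values must be attached before filtering")
    rec = table.records
    keep = rec[(rec["r"] < 0) & (rec["q"] <= fdr)].reset_index(drop=True)
    cutoff = float(keep["p"].max()) if len(keep) else None
    return PairCorrelationTable(keep, table.m_total, cutoff)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate(neg_pairs: PairCorrelationTable, decomp: ModuleDecomposition,
              trait_mods: TraitAssociatedModules,
              predictions: pd.DataFrame | None,
              families: dict[str, str],
              gene_map: dict[str, str] | None = None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the three-criterion regulatory-link filter.

    Returns ``(probe_level, family_level)`` edge tables for the criterion
    1-and-2 set, with prediction flags marking the fully confirmed
    1-and-2-and-3 subset.  The family row of each (family, gene) group
    carries the most negative probe-level pair.
    """
    known = set(decomp.labels.index)
    module_of = decomp.labels
    selected = set(trait_mods.modules)
    pred_idx: dict[tuple[str, str], tuple[bool, bool, str, float]] = {}
    if predictions is not None and len(predictions):
        for row in predictions.itertuples(index=False):
            pred_idx[(row.miRNA, row.target)] = (
                bool(row.seed_hit), bool(row.duplex_hit),
                row.site_types, row.best_mfe)
    rows = []
    for rec in neg_pairs.records.itertuples(index=False):
        if rec.mRNA not in known:
            raise ValidationError(f"mRNA probe {rec.mRNA!r} has no module label")
        module = module_of[rec.mRNA]
        if module == GREY or module not in selected:
            continue
        gene = gene_map.get(rec.mRNA, rec.mRNA) if gene_map else rec.mRNA
        seed_hit, duplex_hit, sites, mfe = pred_idx.get(
            (rec.miRNA, rec.mRNA), (False, False, "", np.nan))
        rows.append({
            "miRNA_family": families.get(rec.miRNA, rec.miRNA),
            "miRNA_probe": rec.miRNA, "gene": gene, "mRNA_probe": rec.mRNA,
            "module": module, "r": rec.r, "p": rec.p, "q": rec.q,
            "site_types": sites, "duplex_mfe": mfe,
            "module_hit": True, "negative_fdr_hit": True,
            "predicted_seed": seed_hit, "predicted_duplex": duplex_hit,
        })
    cols = ["miRNA_family", "miRNA_probe", "gene", "mRNA_probe", "module",
            "r", "p", "q", "site_types", "duplex_mfe",
            "module_hit", "negative_fdr_hit", "predicted_seed", "predicted_duplex"]
    probe_level = pd.DataFrame(rows, columns=cols)
    if len(probe_level):
        probe_level = probe_level.sort_values(
            ["module", "gene", "miRNA_family", "miRNA_probe", "mRNA_probe"],
            kind="mergesort").reset_index(drop=True)
        grouped = probe_level.sort_values("r", kind="mergesort").groupby(
            ["miRNA_family", "gene"], sort=True)
        family_level = grouped.first().reset_index()
        flags = grouped[["predicted_seed", "predicted_duplex"]].any().reset_index()
        family_level["predicted_seed"] = flags["predicted_seed"]
        family_level["predicted_duplex"] = flags["predicted_duplex"]
        family_level = family_level[cols].sort_values(
            ["module", "gene", "miRNA_family"], kind="mergesort").reset_index(drop=True)
    else:
        family_level = pd.DataFrame(columns=cols)
    return probe_level, family_level


def confirmed_subset(edges: pd.DataFrame) -> pd.DataFrame:
    """The fully confirmed 1-and-2-and-3 edges (either prediction method)."""
    if not len(edges):
        return edges
    mask = edges["predicted_seed"].astype(bool) | edges["predicted_duplex"].astype(bool)
    return edges[mask].reset_index(drop=True)
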