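"""Term enrichment, gene-overlap term clustering and enrichment scores.

Per-term significance is the one-sided hypergeometric upper-tail
probability of the observed overlap between a gene set (e.g. a module) and
an annotation term, both restricted to a declared background universe.
Related terms are grouped by Cohen's kappa agreement of their binary
gene-membership vectors (single linkage at a kappa threshold), and each
cluster is scored

    ES = -log10(geometric mean of the member terms' unadjusted p-values),

so ES 2 means the typical member term is enriched at p = 0.01.  The
clustering is a deterministic replacement for interactive fuzzy heuristics
found in annotation web services, with the same inputs and outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import ModuleDecomposition
from .io_formats import AnnotationMap, ValidationError, log


@dataclass
class TermEnrichmentResult:
    term_id: str
    term_name: str
    overlap: int            # genes shared by the set and the term
    annotated: int          # genes of the set covered by any term
    term_size: int          # term genes within the background
    background: int
    percent_count: float    # overlap / annotated * 100
    p: float


def term_enrichment(genes: set[str], annotation: AnnotationMap,
                    background: set[str]) -> list[TermEnrichmentResult]:
    """Hypergeometric upper-tail enrichment of each term in a gene set.

    Terms and the gene set are restricted to the background; results are
    ordered by (p, term id) for determinism.
    """
    if not background:
        raise ValidationError("background universe is empty")
    genes = set(genes)
    if not genes <= set(background):
        extra = sorted(genes - set(background))
        raise ValidationError(f"gene(s) outside the background: {extra[:5]}")
    ann = annotation.restrict(frozenset(background))
    universe = frozenset().union(*ann.terms.values()) if ann.terms else frozenset()
    annotated = len(genes & universe)
    N = len(background)
    results = []
    for tid in ann.term_ids:
        term_genes = ann.terms[tid]
        K = len(term_genes)
        k = len(genes & term_genes)
        # P(X >= k) with X ~ Hypergeom(N, K, n=|genes|)
        p = float(stats.hypergeom.sf(k - 1, N, K, len(genes)))
        pct = 100.0 * k / annotated if annotated else 0.0
        results.append(TermEnrichmentResult(tid, ann.names[tid], k, annotated,
                                            K, N, pct, min(max(p, 0.0), 1.0)))
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def cohens_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected agreement of two binary membership vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    n = len(a)
    po = (a == b).mean()
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 1.0
    return float((po - pe) / (1.0 - pe))


@dataclass
class FunctionalCluster:
    member_terms: list[str]
    es: float                   # -log10 geometric mean of member p-values

    @property
    def size(self) -> int:
        return len(self.member_terms)


def enrichment_score(pvalues) -> float:
    """ES = -log10 of the geometric mean of unadjusted p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValidationError("enrichment score needs >= 1 p-value")
    return float(-np.mean(np.log10(np.maximum(p, np.finfo(float).tiny))))


def cluster_terms(results: list[TermEnrichmentResult], annotation: AnnotationMap,
                  background: set[str],
                  kappa_threshold: float = 0.35) -> list[FunctionalCluster]:
    """Single-linkage clusters of terms at kappa >= threshold; singletons kept.

    Kappa is computed between the terms' binary gene-membership vectors over
    the background.  Clusters are returned by decreasing ES (ties: first
    member id).
    """
    if not results:
        raise ValidationError("no enrichment results to cluster")
    bg = sorted(background)
    idx = {g: i for i, g in enumerate(bg)}
    term_ids = [r.term_id for r in results]
    p_of = {r.term_id: r.p for r in results}
    vectors = {}
    for tid in term_ids:
        v = np.zeros(len(bg), dtype=bool)
        for g in annotation.terms[tid] & frozenset(bg):
            v[idx[g]] = True
        vectors[tid] = v
    # connected components of the kappa >= threshold graph = single linkage
    parent = {t: t for t in term_ids}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for i, a in enumerate(term_ids):
        for b in term_ids[i + 1:]:
            if cohens_kappa(vectors[a], vectors[b]) >= kappa_threshold:
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for t in term_ids:
        groups.setdefault(find(t), []).append(t)
    clusters = [FunctionalCluster(sorted(members),
                                  enrichment_score([p_of[t] for t in members]))
                for members in groups.values()]
    clusters.sort(key=lambda c: (-c.es, c.member_terms[0]))
    return clusters


def module_enrichment_report(decomp: ModuleDecomposition,
                             annotation: AnnotationMap,
                             background: set[str] | None = None,
                             kappa_threshold: float = 0.35) -> pd.DataFrame:
    """Per-module top functional cluster and its top term.

    Background defaults to all probes in the decomposition (all analyzed
    genes, not the genome).  The grey module is reported like any other;
    modules with no annotated genes yield an empty row with a warning.
    """
    if background is None:
        background = set(decomp.labels.index)
    ann = annotation.restrict(frozenset(background))
    universe = frozenset().union(*ann.terms.values()) if ann.terms else frozenset()
    modules = decomp.modules + (["grey"] if (decomp.labels == "grey").any() else [])
    rows = []
    for module in modules:
        members = set(decomp.members(module)) & set(background)
        annotated = members & universe
        if not annotated:
            log.warning("module %s has no annotated genes; empty report row", module)
            rows.append({"module": module, "top_cluster_es": np.nan,
                         "cluster_size": 0, "top_term": "", "top_term_name": "",
                         "top_term_p": np.nan, "overlap": 0, "percent_count": np.nan})
            continue
        results = term_enrichment(members, ann, background)
        clusters = cluster_terms(results, ann, background, kappa_threshold)
        top = clusters[0]
        by_p = {r.term_id: r for r in results}
        top_term = min(top.member_terms, key=lambda t: (by_p[t].p, t))
        r = by_p[top_term]
        rows.append({"module": module, "top_cluster_es": top.es,
                     "cluster_size": top.size, "top_term": r.term_id,
                     "top_term_name": r.term_name, "top_term_p": r.p,
                     "overlap": r.overlap, "percent_count": r.percent_count})
    return pd.DataFrame(rows)


def random_set_pvalues(annotation: AnnotationMap, background: set[str],
                       set_size: int, n_sets: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Calibration device: best enrichment p of random gene sets.

    Draws ``n_sets`` random sets of matched size from the background and
    returns the minimum term p of each, giving an empirical null for
    judging observed module enrichment.
    """
    bg = sorted(background)
    if set_size > len(bg):
        raise ValidationError("set size exceeds the background")
    out = np.empty(n_sets)
    for i in range(n_sets):
        picked = set(rng.choice(bg, size=set_size, replace=False))
        results = term_enrichment(picked, annotation, background)
        out[i] = min((r.p for r in results), default=1.0)
    return out
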