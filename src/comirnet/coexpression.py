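"""Weighted co-expression network construction and module decomposition.

The network is built from the Pearson correlation matrix of residualized
expression profiles.  Correlations are soft-thresholded into an adjacency

    unsigned:  a_ij = |r_ij| ** beta
    signed:    a_ij = ((1 + r_ij) / 2) ** beta

with the power beta chosen as the smallest candidate whose connectivity
distribution fits a scale-free topology with R^2 above a target (default
0.9).  Pairwise similarity is then the topological overlap

    w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj,   k_i = sum_{u != i} a_iu,

which rewards shared neighborhoods on top of direct adjacency.  Modules are
clusters of the TOM dissimilarity d = 1 - w under average-linkage
hierarchical clustering with a constant-height cut; clusters below a minimum
size dissolve into the unassigned "grey" module.  Each module is summarized
by its eigengene (first principal component of the standardized member
profiles), modules with near-identical eigengenes are merged, and per-probe
statistics are the module membership MM (signed correlation with each
eigengene) and gene significance GS (absolute correlation with each trait).

Module labels follow a fixed color sequence in decreasing module size, so
runs are reproducible; the labels carry no semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_formats import ExpressionMatrix, PhenotypeTable, ValidationError, log
from .module_trait import pearson_pairwise

GREY = "grey"

#: fixed label sequence (decreasing module size); extended numerically if exhausted
COLOR_SEQUENCE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


# ---------------------------------------------------------------------------
# correlation and adjacency
# ---------------------------------------------------------------------------

def correlation_matrix(mat: ExpressionMatrix) -> pd.DataFrame:
    """All-pairs Pearson correlation of probe profiles (probes x probes)."""
    if mat.data.shape[1] < 3:
        raise ValidationError("correlation requires >= 3 samples")
    vals = mat.values
    sd = vals.std(axis=1, ddof=1)
    zero = [mat.probe_ids[i] for i in np.flatnonzero(sd == 0)]
    if zero:
        raise ValidationError(f"zero-variance probe(s): {zero[:10]}")
    if np.isnan(vals).any():
        corr = mat.data.T.corr(method="pearson")  # pairwise-complete
        return corr
    r = np.corrcoef(vals)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=mat.data.index, columns=mat.data.index)


@dataclass
class AdjacencyMatrix:
    probe_ids: list[str]
    values: np.ndarray           # symmetric, entries in [0, 1], diagonal 1
    beta: float
    signed_mode: str = "unsigned"

    def connectivity(self) -> np.ndarray:
        """k_i = sum over u != i of a_iu."""
        return self.values.sum(axis=0) - np.diag(self.values)


def adjacency(corr: pd.DataFrame, beta: float,
              signed_mode: str = "unsigned") -> AdjacencyMatrix:
    """Soft-threshold a correlation matrix into network adjacency."""
    if beta < 1:
        raise ValidationError("soft-threshold power beta must be >= 1")
    r = corr.to_numpy(dtype=float)
    if signed_mode == "unsigned":
        a = np.abs(r) ** beta
    elif signed_mode == "signed":
        a = ((1.0 + r) / 2.0) ** beta
    else:
        raise ValidationError(f"unknown signed_mode {signed_mode!r}")
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(list(corr.index), a, beta, signed_mode)


@dataclass
class SoftThresholdScan:
    betas: list[float]
    r_squared: list[float]
    mean_connectivity: list[float]
    selected_beta: float
    reached_target: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.betas, "scale_free_r2": self.r_squared,
                             "mean_connectivity": self.mean_connectivity})


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log regression of connectivity density on connectivity.

    Connectivities are split into ``n_bins`` equal-count bins; each non-empty
    bin contributes (log10 mean k, log10 frequency density), where density is
    bin count / (n * bin width).  A scale-free degree distribution makes this
    relationship linear.
    """
    k = np.asarray(k, dtype=float)
    if len(k) < n_bins:
        raise ValidationError(
            f"scale-free fit needs >= {n_bins} probes for {n_bins} bins, got {len(k)}")
    if np.all(k <= 1e-12):
        raise ValidationError("all probes are isolated (connectivity ~ 0)")
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        raise ValidationError("connectivity distribution too degenerate to bin")
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    xs, ys = [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        width = edges[b + 1] - edges[b]
        if not sel.any() or width <= 0:
            continue
        mean_k = k[sel].mean()
        density = sel.sum() / (len(k) * width)
        if mean_k > 0 and density > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(density))
    if len(xs) < 3:
        raise ValidationError("fewer than 3 usable connectivity bins")
    x, y = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return 1.0
    return float(1.0 - (resid ** 2).sum() / ss_tot)


def select_soft_threshold(corr: pd.DataFrame, betas=tuple(range(1, 13)),
                          target_r2: float = 0.9, n_bins: int = 10,
                          signed_mode: str = "unsigned") -> SoftThresholdScan:
    """Scan candidate powers; adopt the smallest with scale-free R^2 > target.

    If no candidate reaches the target, the power with maximal R^2 is
    selected and the scan is flagged (``reached_target=False``).
    """
    betas = list(betas)
    if not betas or any(b2 <= b1 for b1, b2 in zip(betas, betas[1:])):
        raise ValidationError("betas must be a non-empty ascending list")
    r2s, ks = [], []
    for b in betas:
        adj = adjacency(corr, b, signed_mode)
        k = adj.connectivity()
        r2s.append(scale_free_fit(k, n_bins))
        ks.append(float(k.mean()))
    qualifying = [b for b, r2 in zip(betas, r2s) if r2 > target_r2]
    if qualifying:
        selected, reached = qualifying[0], True
    else:
        selected, reached = betas[int(np.argmax(r2s))], False
        log.warning("no candidate beta reached scale-free R^2 > %.2f; "
                    "using beta=%s at max R^2=%.3f", target_r2, selected, max(r2s))
    return SoftThresholdScan(betas, r2s, ks, float(selected), reached)


# ---------------------------------------------------------------------------
# topological overlap
# ---------------------------------------------------------------------------

@dataclass
class TOMMatrix:
    probe_ids: list[str]
    values: np.ndarray   # symmetric, in [0, 1], diagonal 1 by convention

    def dissimilarity(self) -> np.ndarray:
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d


def tom(adj: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap of a weighted network.

    l_ij excludes u in {i, j}; k_i excludes only the self term — the
    convention under which a clique attains w = 1 exactly.
    """
    a = adj.values
    n = a.shape[0]
    L = a @ a
    # remove the u = i and u = j terms: a_ii a_ij + a_ij a_jj = 2 a_ij (diag = 1)
    L = L - 2.0 * a
    k = a.sum(axis=0) - np.diag(a)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (L + a) / denom
    w = np.where(denom <= 0, 0.0, w)
    w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return TOMMatrix(adj.probe_ids, w)


# ---------------------------------------------------------------------------
# module detection and summaries
# ---------------------------------------------------------------------------

def gap_cut_height(merge_heights: np.ndarray, lower_quantile: float = 0.25) -> float:
    """Automatic constant cut height: the midpoint of the largest gap in the
    sorted merge heights, searched above ``lower_quantile`` of the heights.

    In networks with modular structure plus an unstructured background, the
    dendrogram shows a wide empty band between the within-module merges and
    the near-1 background merges; cutting inside that band separates modules
    from grey robustly.  The lower restriction ignores spurious early gaps.
    """
    hs = np.sort(np.asarray(merge_heights, dtype=float))
    if len(hs) < 2:
        return float(hs[-1]) if len(hs) else 1.0
    i0 = int(np.searchsorted(hs, np.quantile(hs, lower_quantile)))
    i0 = min(i0, len(hs) - 2)
    gaps = np.diff(hs[i0:])
    g = int(np.argmax(gaps))
    return float((hs[i0 + g] + hs[i0 + g + 1]) / 2.0)


def detect_modules(tomm: TOMMatrix, min_module_size: int = 30,
                   cut_height: float | None = None,
                   gap_lower_quantile: float = 0.25) -> pd.Series:
    """Probe -> module label from a constant-height cut of the TOM dendrogram.

    ``cut_height=None`` places the cut automatically at the largest gap in
    the dendrogram merge heights (see :func:`gap_cut_height`).  Clusters
    smaller than ``min_module_size`` dissolve into grey; surviving clusters
    receive color labels in decreasing size (ties broken by smallest member
    index).
    """
    if min_module_size < 2:
        raise ValidationError("min_module_size must be >= 2")
    d = tomm.dissimilarity()
    Z = linkage(squareform(d, checks=False), method="average")
    if cut_height is None:
        cut_height = gap_cut_height(Z[:, 2], gap_lower_quantile)
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(GREY, index=pd.Index(tomm.probe_ids), dtype=object)
    clusters = []
    for cl in np.unique(raw):
        members = np.flatnonzero(raw == cl)
        if len(members) >= min_module_size:
            clusters.append((len(members), members[0], members))
    clusters.sort(key=lambda c: (-c[0], c[1]))
    for rank, (_, _, members) in enumerate(clusters):
        color = (COLOR_SEQUENCE[rank] if rank < len(COLOR_SEQUENCE)
                 else f"module{rank + 1}")
        labels.iloc[members] = color
    return labels


def module_eigengene(mat: ExpressionMatrix,
                     members: list[str]) -> tuple[np.ndarray, float]:
    """First principal component of a module's standardized profiles.

    Member profiles are standardized per probe (mean 0, sd 1) before the
    singular value decomposition; the eigengene is the leading right
    singular vector across samples (unit Euclidean norm) with its sign fixed
    so it correlates non-negatively with the members' average standardized
    profile.  Returns (eigengene, variance explained).
    """
    if len(members) < 2:
        raise ValidationError("a module needs >= 2 member probes")
    X = mat.data.loc[list(members)].to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    const = [members[i] for i in np.flatnonzero(sd == 0)]
    if const:
        raise ValidationError(f"constant probe(s) in module: {const[:5]}")
    Xs = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    _, s, vt = np.linalg.svd(Xs, full_matrices=False)
    me = vt[0]
    mean_profile = Xs.mean(axis=0)
    if np.corrcoef(me, mean_profile)[0, 1] < 0:
        me = -me
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    return me, var_explained


@dataclass
class ModuleDecomposition:
    """Module labels plus eigengenes and per-probe summary statistics."""

    labels: pd.Series                    # probe -> label (grey = unassigned)
    eigengenes: pd.DataFrame             # modules x samples, unit-norm rows
    var_explained: dict[str, float]
    min_module_size: int
    merge_threshold: float | None = None
    module_membership: pd.DataFrame | None = None   # probes x modules, signed r
    gene_significance: pd.DataFrame | None = None   # probes x traits, |r|

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes.index)

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def decompose(mat: ExpressionMatrix, labels: pd.Series, min_module_size: int,
              merge_threshold: float | None = None) -> ModuleDecomposition:
    """Assemble eigengenes (size-ordered modules, grey excluded) for labels."""
    sizes = labels[labels != GREY].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m],
                                               list(labels[labels == m].index)[0]))
    mes, ves = {}, {}
    for module in order:
        me, ve = module_eigengene(mat, list(labels.index[labels == module]))
        mes[module] = me
        ves[module] = ve
    eig = pd.DataFrame(mes, index=mat.data.columns).T if mes else \
        pd.DataFrame(np.empty((0, mat.data.shape[1])), columns=mat.data.columns)
    return ModuleDecomposition(labels.copy(), eig, ves, min_module_size,
                               merge_threshold)


def merge_close_modules(decomp: ModuleDecomposition, mat: ExpressionMatrix,
                        merge_threshold: float = 0.2) -> ModuleDecomposition:
    """Iteratively merge the closest module pair while eigengene
    dissimilarity 1 - cor(ME_i, ME_j) falls below the threshold.

    After each merge the combined module's eigengene is recomputed.  The
    merged module keeps the label of the larger partner (ties: label order),
    and labels are re-assigned by final size at the end.
    """
    labels = decomp.labels.copy()
    while True:
        current = decompose(mat, labels, decomp.min_module_size, merge_threshold)
        mods = current.modules
        if len(mods) < 2:
            break
        E = current.eigengenes.to_numpy()
        C = np.corrcoef(E)
        np.fill_diagonal(C, -np.inf)
        diss = 1.0 - C
        best, pair = np.inf, None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                if diss[i, j] < best - 1e-15:
                    best, pair = diss[i, j], (mods[i], mods[j])
        if pair is None or best >= merge_threshold:
            break
        a, b = pair
        sizes = labels.value_counts()
        if sizes[a] != sizes[b]:
            keep, drop = (a, b) if sizes[a] > sizes[b] else (b, a)
        else:
            keep, drop = tuple(sorted((a, b)))  # deterministic tie-break
        labels[labels == drop] = keep
    # re-label by final size using the fixed color sequence
    final = decompose(mat, labels, decomp.min_module_size, merge_threshold)
    mapping = {}
    for rank, module in enumerate(final.modules):
        mapping[module] = (COLOR_SEQUENCE[rank] if rank < len(COLOR_SEQUENCE)
                           else f"module{rank + 1}")
    relabeled = labels.map(lambda m: mapping.get(m, GREY))
    out = decompose(mat, relabeled, decomp.min_module_size, merge_threshold)
    return out


def gene_significance(mat: ExpressionMatrix, ph: PhenotypeTable) -> pd.DataFrame:
    """GS = |Pearson r| between each probe profile and each trait (pairwise-complete)."""
    shared = [s for s in mat.sample_ids if s in ph.data.index]
    if len(shared) < 3:
        raise ValidationError("gene significance needs >= 3 shared samples")
    X = mat.data.loc[:, shared].to_numpy(dtype=float)
    Y = ph.data.loc[shared].to_numpy(dtype=float)
    r, _, _ = pearson_pairwise(X, Y.T)
    return pd.DataFrame(np.abs(r), index=mat.data.index, columns=ph.trait_names)


def module_membership(mat: ExpressionMatrix,
                      decomp: ModuleDecomposition) -> pd.DataFrame:
    """MM = signed Pearson r between each probe and each module eigengene."""
    X = mat.values
    E = decomp.eigengenes.to_numpy(dtype=float)
    if E.size == 0:
        return pd.DataFrame(index=mat.data.index)
    r, _, _ = pearson_pairwise(X, E)
    return pd.DataFrame(r, index=mat.data.index, columns=decomp.modules)


def build_network(mat: ExpressionMatrix, min_module_size: int = 30,
                  betas=tuple(range(1, 13)), target_r2: float = 0.9,
                  n_bins: int = 10, signed_mode: str = "unsigned",
                  cut_height: float | None = None,
                  gap_lower_quantile: float = 0.25,
                  merge_threshold: float = 0.2,
                  phenotypes: PhenotypeTable | None = None,
                  ) -> tuple[SoftThresholdScan, ModuleDecomposition]:
    """Full network stage: correlation -> beta scan -> TOM -> modules -> merge.

    Attaches module membership (and gene significance when phenotypes are
    given) to the returned decomposition.
    """
    corr = correlation_matrix(mat)
    scan = select_soft_threshold(corr, betas, target_r2, n_bins, signed_mode)
    adj = adjacency(corr, scan.selected_beta, signed_mode)
    tomm = tom(adj)
    labels = detect_modules(tomm, min_module_size, cut_height, gap_lower_quantile)
    decomp = decompose(mat, labels, min_module_size, merge_threshold)
    decomp = merge_close_modules(decomp, mat, merge_threshold)
    decomp.module_membership = module_membership(mat, decomp)
    if phenotypes is not None:
        decomp.gene_significance = gene_significance(mat, phenotypes)
    return scan, decomp
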