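"""Sequence-based miRNA target prediction.

Two independent lines of evidence are computed for every candidate
miRNA-transcript pair:

* **Seed complementarity** — canonical site classes on the target 3'UTR.
  With the miRNA written 5'->3', the *seed* is nucleotides 2-7 and the
  extended seed 2-8.  A site on the UTR (also 5'->3') is

  - ``7mer-m8``: the reverse complement of miRNA positions 2-8,
  - ``7mer-A1``: the reverse complement of positions 2-7 followed by an A,
  - ``8mer``:    the reverse complement of positions 2-8 followed by an A.

  Each seed-match locus is reported once with the strongest applicable type
  (8mer > 7mer-m8 > 7mer-A1).  G:U wobble pairs are not accepted in seed
  matches.

* **Hybridization energy** — a dynamic program over intermolecular base
  pairing only (no intramolecular structure) that finds the most stable
  duplex a miRNA can form within a larger RNA, with bulge/internal loops
  limited to a configurable number of unpaired nucleotides per side, and an
  energy cutoff deciding the predicted flag.  The energy model is a small
  configurable stack-class table, not a full nearest-neighbor
  parameterization; its correctness is asserted against exhaustive
  enumeration over the same transition grammar.

Coordinates are 0-based, half-open, on the given UTR strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import SequenceSet, ValidationError

RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: nucleotide -> integer code (order matters for the pair-type table)
_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}

# pair-type codes: 0 = not allowed, 1 = GC/CG, 2 = AU/UA, 3 = GU/UG
_PAIR_TYPE = np.zeros((4, 4), dtype=np.int8)
_PAIR_TYPE[_CODE["G"], _CODE["C"]] = _PAIR_TYPE[_CODE["C"], _CODE["G"]] = 1
_PAIR_TYPE[_CODE["A"], _CODE["U"]] = _PAIR_TYPE[_CODE["U"], _CODE["A"]] = 2
_PAIR_TYPE[_CODE["G"], _CODE["U"]] = _PAIR_TYPE[_CODE["U"], _CODE["G"]] = 3

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")


def reverse_complement(seq: str) -> str:
    try:
        return "".join(RNA_COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:
        raise ValidationError(f"non-ACGU symbol {exc.args[0]!r} in sequence") from None


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValidationError(f"non-ACGU symbol {exc.args[0]!r} in sequence") from None


# ---------------------------------------------------------------------------
# energy model
# ---------------------------------------------------------------------------

@dataclass
class EnergyModel:
    """Stack energies by base-pair class plus a per-nucleotide loop penalty.

    ``stack_energies`` is keyed by ordered pairs of pair-class names
    ("GC", "AU", "GU"); the default table scores a stack by its weakest
    member: any GU-containing stack -1.0, else any AU-containing stack
    -2.0, else (pure GC) -3.0 kcal/mol.  Loops cost ``loop_penalty`` per
    unpaired nucleotide on either side.
    """

    stack_energies: dict[tuple[str, str], float] = field(default_factory=dict)
    loop_penalty: float = 0.5
    gc_stack: float = -3.0
    au_stack: float = -2.0
    gu_stack: float = -1.0

    def __post_init__(self) -> None:
        if not self.stack_energies:
            classes = {"GC": self.gc_stack, "AU": self.au_stack, "GU": self.gu_stack}
            rank = {"GU": 0, "AU": 1, "GC": 2}  # weakest first
            self.stack_energies = {
                (a, b): classes[min((a, b), key=lambda c: rank[c])]
                for a in classes for b in classes
            }
        for key, e in self.stack_energies.items():
            if e >= 0:
                raise ValidationError(f"stack energy for {key} must be < 0, got {e}")
        if self.loop_penalty <= 0:
            raise ValidationError("loop penalty must be > 0")

    def stack_table(self) -> np.ndarray:
        """4x4 table indexed by pair-type codes 1..3 (0 row/col unused)."""
        name = {1: "GC", 2: "AU", 3: "GU"}
        tab = np.zeros((4, 4))
        for a in (1, 2, 3):
            for b in (1, 2, 3):
                tab[a, b] = self.stack_energies[(name[a], name[b])]
        return tab


# ---------------------------------------------------------------------------
# seed-site scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedSite:
    mirna_id: str
    target_id: str
    site_type: str          # one of SITE_TYPES
    start: int              # 0-based, half-open [start, end) on the UTR
    end: int


def scan_seed_sites(mirna: str, utr: str,
                    mirna_id: str = "miRNA", target_id: str = "target") -> list[SeedSite]:
    """Find canonical seed-match sites of one miRNA on one UTR.

    Each occurrence of the reverse complement of the 6-nt seed (miRNA
    positions 2-7) anchors a candidate locus; the m8 match and the A1
    adenosine decide its final class.  Loci lacking both extensions are not
    canonical sites and are not reported.
    """
    mirna = mirna.upper().replace("T", "U")
    utr = utr.upper().replace("T", "U")
    if len(mirna) < 8:
        raise ValidationError("miRNA must be at least 8 nt for seed classification")
    core7 = reverse_complement(mirna[1:8])   # complement of positions 8..2, 5'->3' on UTR
    core6 = core7[1:]                        # complement of positions 7..2
    _ = _encode(utr)                         # alphabet check
    sites: list[SeedSite] = []
    pos = utr.find(core6)
    while pos != -1:
        has_m8 = pos >= 1 and utr[pos - 1] == core7[0]
        has_a1 = pos + 6 < len(utr) and utr[pos + 6] == "A"
        if has_m8 and has_a1:
            sites.append(SeedSite(mirna_id, target_id, "8mer", pos - 1, pos + 7))
        elif has_m8:
            sites.append(SeedSite(mirna_id, target_id, "7mer-m8", pos - 1, pos + 6))
        elif has_a1:
            sites.append(SeedSite(mirna_id, target_id, "7mer-A1", pos, pos + 7))
        pos = utr.find(core6, pos + 1)
    return sites


# ---------------------------------------------------------------------------
# duplex dynamic program
# ---------------------------------------------------------------------------

@dataclass
class DuplexResult:
    mirna_id: str
    target_id: str
    mfe: float                       # kcal/mol, <= 0 whenever any pair forms
    pairs: list[tuple[int, int]]     # (miRNA index, UTR index), both 0-based
    utr_start: int                   # half-open window on the UTR
    utr_end: int
    predicted: bool = False


def _dp_tables(mi: np.ndarray, utr_rev: np.ndarray, model: EnergyModel,
               max_loop: int, blocked: np.ndarray | None):
    """Best-energy table over (miRNA index, reversed-UTR index) end pairs."""
    n, m = len(mi), len(utr_rev)
    pt = _PAIR_TYPE[mi[:, None], utr_rev[None, :]]
    allowed = pt > 0
    if blocked is not None:
        allowed &= ~blocked[None, :]
    stab = model.stack_table()
    inf = np.inf
    best = np.full((n, m), inf)
    for i in range(n):
        row = np.where(allowed[i], 0.0, inf)      # a duplex may start at any pair
        if i > 0:
            stacked = np.full(m, inf)
            stacked[1:] = best[i - 1, :-1] + stab[pt[i - 1, :-1], pt[i, 1:]]
            row = np.minimum(row, stacked)
        for di in range(1, max_loop + 2):
            if i - di < 0:
                break
            for dj in range(1, max_loop + 2):
                if di == 1 and dj == 1:
                    continue
                pen = model.loop_penalty * ((di - 1) + (dj - 1))
                shifted = np.full(m, inf)
                shifted[dj:] = best[i - di, :-dj] + pen
                row = np.minimum(row, shifted)
        best[i] = np.where(allowed[i], row, inf)
    return best, pt, allowed


def _traceback(best: np.ndarray, pt: np.ndarray, model: EnergyModel,
               max_loop: int, i: int, j: int) -> list[tuple[int, int]]:
    """Recover one optimal chain ending at (i, j) by re-checking predecessors."""
    stab = model.stack_table()
    chain = [(i, j)]
    tol = 1e-9
    while abs(best[i, j]) > tol:
        found = False
        if i >= 1 and j >= 1 and pt[i - 1, j - 1] > 0:
            if abs(best[i - 1, j - 1] + stab[pt[i - 1, j - 1], pt[i, j]] - best[i, j]) < tol:
                i, j = i - 1, j - 1
                chain.append((i, j))
                found = True
        if not found:
            for di in range(1, max_loop + 2):
                for dj in range(1, max_loop + 2):
                    if di == 1 and dj == 1:
                        continue
                    pi, pj = i - di, j - dj
                    if pi < 0 or pj < 0 or not np.isfinite(best[pi, pj]):
                        continue
                    pen = model.loop_penalty * ((di - 1) + (dj - 1))
                    if abs(best[pi, pj] + pen - best[i, j]) < tol:
                        i, j = pi, pj
                        chain.append((i, j))
                        found = True
                        break
                if found:
                    break
        if not found:  # numerically unreachable; treat as chain start
            break
    chain.reverse()
    return chain


def best_duplex(mirna: str, utr: str, model: EnergyModel | None = None,
                max_loop: int = 4, hits: int = 1,
                mirna_id: str = "miRNA", target_id: str = "target") -> list[DuplexResult]:
    """Most energetically favourable hybridization site(s) of a miRNA on a UTR.

    Returns up to ``hits`` non-overlapping UTR windows ordered by energy.
    Ties are broken deterministically: leftmost UTR start, then shortest
    duplex.  The empty list means no allowed base pair exists.
    """
    if model is None:
        model = EnergyModel()
    if max_loop < 0:
        raise ValidationError("max_loop must be >= 0")
    mirna = mirna.upper().replace("T", "U")
    utr = utr.upper().replace("T", "U")
    mi = _encode(mirna)
    ut = _encode(utr)
    # the miRNA 5' end pairs with the 3' side of the site: reverse the UTR so
    # both indices increase along the duplex
    utr_rev = ut[::-1]
    m = len(utr_rev)
    blocked = np.zeros(m, dtype=bool)
    results: list[DuplexResult] = []
    for _ in range(max(hits, 0)):
        best, pt, allowed = _dp_tables(mi, utr_rev, model, max_loop, blocked)
        if not np.any(np.isfinite(best)):
            break
        mfe = float(best.min())
        ends = np.argwhere(np.abs(best - mfe) < 1e-12)
        candidates = []
        for i, j in ends[:64]:  # ties are rare; cap the search for safety
            chain = _traceback(best, pt, model, max_loop, int(i), int(j))
            orig = sorted(m - 1 - jj for _, jj in chain)
            start, end = orig[0], orig[-1] + 1
            pairs = [(ii, m - 1 - jj) for ii, jj in chain]
            candidates.append((start, end - start, pairs))
        start, length, pairs = min(candidates, key=lambda c: (c[0], c[1]))
        results.append(DuplexResult(mirna_id, target_id, mfe, pairs, start, start + length))
        blocked[[m - 1 - j for _, j in pairs]] = True
        blocked[m - 1 - (start + length - 1): m - start] = True  # whole window
    return results


# ---------------------------------------------------------------------------
# prediction table
# ---------------------------------------------------------------------------

def predict_targets(mirnas: SequenceSet, utrs: SequenceSet,
                    model: EnergyModel | None = None, cutoff: float = -28.5,
                    max_loop: int = 4, hits: int = 1,
                    pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Seed-match and duplex-energy evidence for (miRNA, UTR) pairs.

    ``pairs`` restricts the scan to an explicit candidate list (e.g. pairs
    already passing expression-based filters); by default all pairs are
    scanned.  Columns: miRNA, target, site_types (comma-joined, '' if none),
    best_mfe (NaN if no pair forms), seed_hit, duplex_hit, both.
    """
    if model is None:
        model = EnergyModel()
    if pairs is None:
        pairs = [(mi, t) for mi in mirnas.record_ids for t in utrs.record_ids]
    rows = []
    for mi_id, t_id in pairs:
        mi_seq, utr_seq = mirnas[mi_id], utrs[t_id]
        sites = scan_seed_sites(mi_seq, utr_seq, mi_id, t_id)
        duplexes = best_duplex(mi_seq, utr_seq, model, max_loop, hits, mi_id, t_id)
        mfe = duplexes[0].mfe if duplexes else np.nan
        seed_hit = len(sites) > 0
        duplex_hit = bool(duplexes and mfe <= cutoff)
        rows.append({
            "miRNA": mi_id, "target": t_id,
            "site_types": ",".join(s.site_type for s in sites),
            "best_mfe": mfe,
            "seed_hit": seed_hit, "duplex_hit": duplex_hit,
            "both": seed_hit and duplex_hit,
        })
    return pd.DataFrame(rows, columns=["miRNA", "target", "site_types", "best_mfe",
                                       "seed_hit", "duplex_hit", "both"])
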