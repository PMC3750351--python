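"""Domain containers, file formats, run configuration and logging.

Every external artifact of the pipeline is a plain-text format: TSV/CSV for
expression matrices and tables, FASTA for sequences, GMT for term annotation,
YAML for the run configuration and JSON for run metadata.  All writers use a
fixed float format and deterministic row ordering so that identical inputs
plus configuration produce byte-identical outputs.

Matrix orientation is fixed as probes-in-rows, samples-in-columns; algorithms
that need samples-in-rows transpose internally.  Missing phenotype values are
encoded with a single sentinel token (``NA``); handling of missingness is
delegated to consumers, which operate pairwise-complete.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

log = logging.getLogger("comirnet")
if not log.handlers:  # library default: warnings to stderr, quiet otherwise
    logging.basicConfig(level=logging.WARNING, format="%(name)s %(levelname)s: %(message)s")

#: sentinel for missing values in text tables
MISSING_TOKEN = "NA"
#: float format used by every writer; 17 significant digits round-trip doubles
FLOAT_FMT = "%.17g"

RNA_ALPHABET = frozenset("ACGU")


class ComirnetError(Exception):
    """Base class for all package errors."""


class ValidationError(ComirnetError, ValueError):
    """An input violates a documented container invariant."""


class ParseError(ComirnetError, ValueError):
    """A text file could not be parsed; the message names the offending record."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise ValidationError(f"duplicate {what} identifier(s): {', '.join(map(str, dups[:5]))}")


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of log2-scale intensities (or residuals).

    ``data`` is a pandas DataFrame with probe identifiers as the index and
    sample identifiers as columns.  All values must be finite; identifiers
    must be unique.
    """

    data: pd.DataFrame
    layer_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.layer_tag not in {"raw", "normalized", "residual"}:
            raise ValidationError(f"unknown layer_tag {self.layer_tag!r}")
        _check_unique(list(self.data.index), "probe")
        _check_unique(list(self.data.columns), "sample")
        vals = self.data.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if vals.size and not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite expression value at probe {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(samples)], layer_tag=self.layer_tag)


@dataclass
class PhenotypeTable:
    """Samples x traits table of organismal measurements; missing allowed."""

    data: pd.DataFrame  # index = sample ids, columns = trait names

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "sample")
        _check_unique(list(self.data.columns), "trait")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class CovariateTable:
    """Per-sample systematic effects: categorical factors plus numeric covariates."""

    data: pd.DataFrame  # index = sample ids
    categorical: tuple[str, ...] = ()
    numeric: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "sample")
        for col in (*self.categorical, *self.numeric):
            if col not in self.data.columns:
                raise ValidationError(f"covariate column {col!r} missing from table")
        for col in self.categorical:
            if self.data[col].isna().any() or (self.data[col].astype(str) == "").any():
                raise ValidationError(f"categorical covariate {col!r} has empty levels")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class SequenceSet:
    """Named nucleotide sequences over {A,C,G,U}; T is unified to U on entry."""

    sequences: dict[str, str]
    kind: str = "mirna_mature"  # or "utr3"

    def __post_init__(self) -> None:
        if self.kind not in {"mirna_mature", "utr3"}:
            raise ValidationError(f"unknown sequence kind {self.kind!r}")
        clean: dict[str, str] = {}
        for rid, seq in self.sequences.items():
            s = str(seq).upper().replace("T", "U")
            if not s:
                raise ValidationError(f"empty sequence for record {rid!r}")
            extra = set(s) - RNA_ALPHABET
            if extra:
                raise ValidationError(
                    f"record {rid!r} contains non-ACGU symbol(s): {''.join(sorted(extra))}"
                )
            clean[rid] = s
        self.sequences = clean

    @property
    def record_ids(self) -> list[str]:
        return list(self.sequences)

    def __getitem__(self, rid: str) -> str:
        return self.sequences[rid]

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class AnnotationMap:
    """GMT-style term -> gene-set mapping with term display names."""

    terms: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, genes in self.terms.items():
            if not genes:
                raise ValidationError(f"term {tid!r} has no genes")
        for tid in self.terms:
            self.names.setdefault(tid, tid)

    @property
    def term_ids(self) -> list[str]:
        return list(self.terms)

    def restrict(self, background: frozenset[str]) -> "AnnotationMap":
        """Intersect every term with a background universe, dropping empty terms."""
        kept = {t: g & background for t, g in self.terms.items()}
        kept = {t: g for t, g in kept.items() if g}
        return AnnotationMap(kept, {t: self.names[t] for t in kept})


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline tunables with their defaults.

    A resolved copy is serialized next to every run's outputs so any result
    can be traced back to the exact parameter set that produced it.
    """

    # preprocessing
    adjust_mode: str = "fixed_ols"          # or "reml_one_random"
    random_effect: str = "sire"             # random intercept term for REML mode
    quantile_normalize_mirna: bool = True   # between-chip normalization of miRNA arrays
    log2_transform: bool = False            # apply log2(x+1) to raw-scale inputs
    outlier_cut_z: float = 4.0              # robust z on dendrogram merge heights

    # co-expression network
    beta_grid: tuple[int, ...] = tuple(range(1, 13))
    scale_free_r2_target: float = 0.9
    n_connectivity_bins: int = 10
    signed_mode: str = "unsigned"           # or "signed"
    min_module_size_mrna: int = 30
    min_module_size_mirna: int = 10
    gap_lower_quantile: float = 0.25        # dendrogram gap-cut search restriction
    merge_threshold: float = 0.2            # eigengene dissimilarity below which modules merge

    # module-trait association
    trait_alpha: float = 0.05

    # miRNA-mRNA pair integration
    pair_fdr: float = 0.1
    qvalue_method: str = "storey"           # or "bh"
    lambda_grid: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(1, 20))

    # target prediction; the default cutoff sits at the ~1% tail of the
    # null (random-pair) duplex-energy distribution under the default
    # energy model at typical miRNA/UTR lengths, mirroring the stringency
    # a -25 kcal/mol threshold has under full nearest-neighbor parameters
    energy_cutoff: float = -28.5            # kcal/mol
    max_loop: int = 4                       # max unpaired nt per side between pairs
    hits_per_target: int = 1

    # enrichment
    kappa_threshold: float = 0.35

    # randomness
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["beta_grid"] = list(self.beta_grid)
        d["lambda_grid"] = list(self.lambda_grid)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        kwargs = dict(raw)
        for key in ("beta_grid", "lambda_grid"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_run_metadata(config: RunConfig, path: str | Path, extra: Mapping | None = None) -> None:
    """JSON run-metadata file: config hash, seed and package version."""
    from comirnet import __version__

    meta = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "config": config.to_dict(),
    }
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SEPS = {"tsv": "\t", "csv": ","}


def _sep(dialect: str) -> str:
    if dialect not in _SEPS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected tsv or csv")
    return _SEPS[dialect]


def _read_numeric_table(path: str | Path, dialect: str, allow_missing: bool) -> pd.DataFrame:
    """Parse a table with row ids in the first column, locating any bad cell."""
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    out = {}
    for col in df.columns:
        raw = df[col]
        probe = pd.to_numeric(raw.where(raw != MISSING_TOKEN), errors="coerce")
        bad = probe.isna() & raw.notna() & (raw != MISSING_TOKEN)
        if bad.any():
            row = bad.idxmax()
            raise ParseError(
                f"{path}: malformed numeric value {raw[row]!r} at row {row!r}, column {col!r}"
            )
        if not allow_missing and probe.isna().any():
            row = probe.isna().idxmax()
            raise ParseError(f"{path}: missing value at row {row!r}, column {col!r}")
        # astype(float) is correctly rounded; pd.to_numeric's fast path is not,
        # and full-precision round trips rely on exact parsing
        out[col] = raw.where(raw != MISSING_TOKEN).astype(float)
    return pd.DataFrame(out, index=df.index)


def read_expression_matrix(path: str | Path, dialect: str = "tsv",
                           layer_tag: str = "raw") -> ExpressionMatrix:
    """Read a probes-in-rows expression table (first column = probe ids)."""
    return ExpressionMatrix(_read_numeric_table(path, dialect, allow_missing=False),
                            layer_tag=layer_tag)


def write_expression_matrix(mat: ExpressionMatrix, path: str | Path,
                            dialect: str = "tsv") -> None:
    mat.data.to_csv(path, sep=_sep(dialect), float_format=FLOAT_FMT,
                    index_label="probe_id", lineterminator="\n")


def read_phenotype_table(path: str | Path, dialect: str = "tsv") -> PhenotypeTable:
    """Samples-in-rows trait table; ``NA`` marks missing measurements."""
    return PhenotypeTable(_read_numeric_table(path, dialect, allow_missing=True))


def write_phenotype_table(ph: PhenotypeTable, path: str | Path, dialect: str = "tsv") -> None:
    ph.data.to_csv(path, sep=_sep(dialect), float_format=FLOAT_FMT,
                   na_rep=MISSING_TOKEN, index_label="sample_id", lineterminator="\n")


def read_covariate_table(path: str | Path, dialect: str = "tsv",
                         categorical: Sequence[str] = ("sex", "ryr", "sire", "slaughter_day"),
                         numeric: Sequence[str] = ("carcass_weight",)) -> CovariateTable:
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0, dtype=str)
    df.index = df.index.astype(str)
    for col in numeric:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    cat = tuple(c for c in categorical if c in df.columns)
    num = tuple(c for c in numeric if c in df.columns)
    return CovariateTable(df, categorical=cat, numeric=num)


def write_covariate_table(cov: CovariateTable, path: str | Path, dialect: str = "tsv") -> None:
    cov.data.to_csv(path, sep=_sep(dialect), float_format=FLOAT_FMT,
                    index_label="sample_id", lineterminator="\n")


def read_fasta(path: str | Path, kind: str = "mirna_mature") -> SequenceSet:
    """Read FASTA; U and T both accepted, unified to U; duplicate ids rejected."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ParseError(f"{path}: no FASTA records found")
    return SequenceSet(seqs, kind=kind)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in seqs.sequences.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_gmt(path: str | Path) -> AnnotationMap:
    """GMT: one term per line — id <tab> description <tab> gene1 <tab> gene2 ..."""
    terms: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs id, description and >=1 gene")
            tid, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if tid in terms:
                raise ValidationError(f"{path}:{lineno}: duplicate term id {tid!r}")
            if not genes:
                raise ValidationError(f"{path}:{lineno}: term {tid!r} has no genes")
            terms[tid] = frozenset(genes)
            names[tid] = desc
    return AnnotationMap(terms, names)


def write_gmt(annotation: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in annotation.term_ids:
            genes = "\t".join(sorted(annotation.terms[tid]))
            fh.write(f"{tid}\t{annotation.names[tid]}\t{genes}\n")


# ---------------------------------------------------------------------------
# regulatory-edge tables
# ---------------------------------------------------------------------------

EDGE_COLUMNS = [
    "miRNA_family", "miRNA_probe", "gene", "mRNA_probe", "module",
    "r", "p", "q", "site_types", "duplex_mfe",
    "module_hit", "negative_fdr_hit", "predicted_seed", "predicted_duplex",
]


def sort_edge_table(edges: pd.DataFrame) -> pd.DataFrame:
    """Documented deterministic ordering: module, then gene, then miRNA family."""
    return edges.sort_values(
        ["module", "gene", "miRNA_family", "miRNA_probe", "mRNA_probe"],
        kind="mergesort").reset_index(drop=True)


def write_edge_table(edges: pd.DataFrame, path: str | Path) -> None:
    """Serialize regulatory edges as TSV with a stable column order and sorting."""
    df = edges.copy()
    for col in EDGE_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col in {"site_types"} else np.nan
    df = sort_edge_table(df[EDGE_COLUMNS])
    for col in ("module_hit", "negative_fdr_hit", "predicted_seed", "predicted_duplex"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(bool(v)))
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, na_rep=MISSING_TOKEN,
              index=False, lineterminator="\n")


def read_edge_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: edge table missing column(s) {', '.join(missing)}")
    for col in ("r", "p", "q", "duplex_mfe"):
        df[col] = pd.to_numeric(df[col].replace(MISSING_TOKEN, np.nan), errors="raise")
    for col in ("module_hit", "negative_fdr_hit", "predicted_seed", "predicted_duplex"):
        df[col] = df[col].map({"True": True, "False": False, "": np.nan})
    df["site_types"] = df["site_types"].fillna("")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Generic deterministic TSV writer used by the CLI stages."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, na_rep=MISSING_TOKEN,
              index=index_label is not None, index_label=index_label,
              lineterminator="\n")
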