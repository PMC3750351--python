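"""Synthetic data generator with planted ground truth.

The generator emulates the statistical structure of a paired muscle
transcriptome / miRNA / phenotype study population:

* **Co-expression modules.**  Each module is a rank-1 latent-factor block:
  a per-sample standard-normal factor f_m, gene loadings drawn from a
  configurable range, plus i.i.d. Gaussian noise.  Background genes are
  pure noise ("grey").
* **Traits.**  Each trait is a linear combination of module factors plus
  noise scaled so its population correlation with the driving factor equals
  the planted effect size r_target (default range 0.2-0.35, the magnitude
  typical of organismal-trait correlations at this scale).
* **Regulator miRNAs.**  A configurable fraction of miRNAs load
  *negatively* on a module's factor; they are grouped into families that
  share the seed sequence (miRNA positions 2-8) while varying elsewhere.
  Each family is assigned target genes inside its module, and those target
  UTRs carry an exact 8mer seed-complementary site, so every planted edge
  is jointly recoverable: negative population correlation AND a seed site
  exist by construction.
* **Nuisance effects.**  Sex, genotype (3 levels), sire, slaughter day and
  a numeric carcass weight enter additively with per-gene (and per-trait)
  level effects, so the fixed-effects linear adjustment is exactly
  correctly specified; an optional nonlinear carcass-weight term tests
  robustness to misspecification.
* **Annotation.**  One term per planted module covers most of its genes,
  so each module is enriched for exactly one planted term; random
  background terms provide nulls.

All randomness flows from a single seeded generator; identical parameters
and seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io_formats import (AnnotationMap, CovariateTable, ExpressionMatrix,
                         PhenotypeTable, SequenceSet, ValidationError)
from .target_prediction import reverse_complement

_NT = np.array(list("ACGU"))


@dataclass
class SimulationParams:
    """All generator tunables; defaults define the desk-scale study conditions."""

    n_samples: int = 120
    n_genes: int = 600
    n_mirnas: int = 60
    n_modules: int = 5
    module_size_range: tuple[int, int] = (60, 100)
    loading_range: tuple[float, float] = (0.7, 0.95)
    noise_sd: float = 0.6
    baseline_mean: float = 7.0       # log2-intensity location of probe baselines
    baseline_sd: float = 1.0

    n_traits: int = 10
    traits_per_module: int = 2
    trait_effect_range: tuple[float, float] = (0.2, 0.35)
    phenotype_missing_rate: float = 0.02

    regulator_fraction: float = 0.5
    family_size: int = 3
    targets_per_family: int = 10
    mirna_length: int = 22
    utr_length_range: tuple[int, int] = (120, 220)

    nuisance_magnitudes: dict = field(default_factory=lambda: {
        "sex": 0.3, "ryr": 0.2, "sire": 0.2, "slaughter_day": 0.2,
        "carcass_weight": 0.2})
    nonlinear_covariate: bool = False
    n_sire: int = 8
    n_slaughter_days: int = 6

    term_coverage: float = 0.7       # fraction of a module's genes in its planted term
    n_background_terms: int = 8

    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_genes", "n_mirnas", "n_modules", "n_traits",
                     "family_size", "targets_per_family", "mirna_length"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        lo, hi = self.loading_range
        if not (0 < lo <= hi < 1):
            raise ValidationError("loading range must lie within (0, 1)")
        lo, hi = self.trait_effect_range
        if not (-1 < lo <= hi < 1):
            raise ValidationError("trait effect range must lie within (-1, 1)")
        if self.module_size_range[1] * self.n_modules > self.n_genes and \
                self.module_size_range[0] * self.n_modules > self.n_genes:
            raise ValidationError(
                "module sizes exceed n_genes: "
                f"{self.n_modules} modules of >= {self.module_size_range[0]} "
                f"genes cannot fit into {self.n_genes}")
        if self.mirna_length < 8:
            raise ValidationError("miRNA length must be >= 8 for a 2-8 seed")


@dataclass
class SyntheticTruth:
    """Everything planted: the answer key for recovery testing."""

    module_assignment: pd.Series             # gene probe -> mod1..modK / grey
    module_factors: pd.DataFrame             # modules x samples latent profiles
    trait_effects: list[tuple[str, str, float]]   # (trait, module, r_target)
    regulator_edges: pd.DataFrame            # miRNA_probe, gene_probe, sign, family, site_start, site_type
    mirna_families: dict[str, str]           # miRNA probe -> family label
    nuisance_effects: dict[str, float]

    def edges_as_set(self) -> set[tuple[str, str]]:
        return set(zip(self.regulator_edges["miRNA_probe"],
                       self.regulator_edges["gene_probe"]))


class SimulatedDataset(NamedTuple):
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    phenotypes: PhenotypeTable
    covariates: CovariateTable
    mirna_seqs: SequenceSet
    utr_seqs: SequenceSet
    annotation: AnnotationMap
    truth: SyntheticTruth


def plant_seed_site(utr: str, mirna: str, site_type: str, position: int) -> str:
    """Overwrite a UTR window with an exact seed site for a miRNA.

    Site strings (UTR 5'->3') follow the canonical definitions: 8mer =
    reverse complement of miRNA positions 2-8 followed by A (8 nt);
    7mer-m8 = reverse complement of 2-8 (7 nt); 7mer-A1 = reverse
    complement of 2-7 followed by A (7 nt).  Flanking bases that would
    upgrade a 7mer to a stronger class are neutralized so the scanner
    reports exactly the requested type at the requested position.
    """
    mirna = mirna.upper().replace("T", "U")
    utr = utr.upper().replace("T", "U")
    if len(mirna) < 8:
        raise ValidationError("miRNA must be >= 8 nt to define a seed site")
    core7 = reverse_complement(mirna[1:8])
    if site_type == "8mer":
        site = core7 + "A"
    elif site_type == "7mer-m8":
        site = core7
    elif site_type == "7mer-A1":
        site = core7[1:] + "A"
    else:
        raise ValidationError(f"unknown site type {site_type!r}")
    if position < 0 or position + len(site) > len(utr):
        raise ValidationError(
            f"site of length {len(site)} does not fit at position {position} "
            f"in a UTR of length {len(utr)}")
    out = list(utr)
    out[position:position + len(site)] = site
    if site_type == "7mer-m8":
        nxt = position + len(site)
        if nxt < len(out) and out[nxt] == "A":
            out[nxt] = "C"   # an A here would make the site an 8mer
    elif site_type == "7mer-A1":
        prev = position - 1
        if prev >= 0 and out[prev] == core7[0]:
            out[prev] = "A" if core7[0] != "A" else "C"  # avoid the m8 match
    return "".join(out)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=length)])


def _nuisance_matrix(rng: np.random.Generator, cov: pd.DataFrame,
                     magnitudes: dict, n_vars: int,
                     nonlinear: bool) -> np.ndarray:
    """Additive systematic effects, n_vars x n_samples."""
    n = len(cov)
    total = np.zeros((n_vars, n))
    for col in ("sex", "ryr", "sire", "slaughter_day"):
        mag = magnitudes.get(col, 0.0)
        if mag == 0:
            continue
        levels = sorted(cov[col].unique())
        effects = rng.normal(0.0, mag, size=(n_vars, len(levels)))
        level_idx = cov[col].map({lv: i for i, lv in enumerate(levels)}).to_numpy()
        total += effects[:, level_idx]
    mag = magnitudes.get("carcass_weight", 0.0)
    if mag:
        w = cov["carcass_weight"].to_numpy(dtype=float)
        z = (w - w.mean()) / w.std()
        coef = rng.normal(0.0, mag, size=n_vars)
        total += np.outer(coef, z)
        if nonlinear:
            coef2 = rng.normal(0.0, mag, size=n_vars)
            total += np.outer(coef2, z ** 2 - 1.0)
    return total


def simulate_dataset(params: SimulationParams) -> SimulatedDataset:
    """Generate the eight pipeline inputs plus the planted-truth record."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    P = params

    samples = [f"S{i + 1:04d}" for i in range(P.n_samples)]
    genes = [f"G{i + 1:05d}" for i in range(P.n_genes)]
    mirnas = [f"M{i + 1:04d}" for i in range(P.n_mirnas)]
    modules = [f"mod{m + 1}" for m in range(P.n_modules)]

    # --- module structure -------------------------------------------------
    lo, hi = P.module_size_range
    sizes = rng.integers(lo, hi + 1, size=P.n_modules)
    while sizes.sum() > P.n_genes:
        sizes[np.argmax(sizes)] -= 1
    if sizes.min() < 2:
        raise ValidationError("infeasible module sizes")
    assignment = pd.Series("grey", index=pd.Index(genes), dtype=object)
    pos = 0
    for m, size in enumerate(sizes):
        assignment.iloc[pos:pos + size] = modules[m]
        pos += size

    factors = rng.standard_normal((P.n_modules, P.n_samples))
    F = pd.DataFrame(factors, index=modules, columns=samples)

    # --- covariates -------------------------------------------------------
    cov = pd.DataFrame(index=pd.Index(samples))
    cov["sex"] = np.where(rng.random(P.n_samples) < 0.5, "M", "F")
    cov["ryr"] = rng.choice(["NN", "Nn", "nn"], size=P.n_samples, p=[0.5, 0.4, 0.1])
    cov["sire"] = [f"sire{k + 1}" for k in rng.integers(0, P.n_sire, P.n_samples)]
    cov["slaughter_day"] = [f"day{k + 1}" for k in
                            rng.integers(0, P.n_slaughter_days, P.n_samples)]
    cov["carcass_weight"] = rng.normal(90.0, 7.0, P.n_samples)
    covariates = CovariateTable(cov, categorical=("sex", "ryr", "sire",
                                                  "slaughter_day"),
                                numeric=("carcass_weight",))

    # --- mRNA expression --------------------------------------------------
    loadings = rng.uniform(*P.loading_range, size=P.n_genes)
    expr = rng.normal(0.0, P.noise_sd, size=(P.n_genes, P.n_samples))
    for m, module in enumerate(modules):
        rows = np.flatnonzero(assignment.to_numpy() == module)
        expr[rows] += np.outer(loadings[rows], factors[m])
    bg_rows = np.flatnonzero(assignment.to_numpy() == "grey")
    # background probes carry comparable total variance, purely from noise
    extra_sd = np.sqrt(max(np.mean(loadings ** 2), 0.0))
    expr[bg_rows] += rng.normal(0.0, extra_sd, size=(len(bg_rows), P.n_samples))
    expr += rng.normal(P.baseline_mean, P.baseline_sd, size=(P.n_genes, 1))
    expr += _nuisance_matrix(rng, cov, P.nuisance_magnitudes, P.n_genes,
                             P.nonlinear_covariate)
    mrna = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=samples))

    # --- traits -----------------------------------------------------------
    traits = [f"trait{t + 1:02d}" for t in range(P.n_traits)]
    effect_of_trait: dict[str, list[tuple[str, float]]] = {t: [] for t in traits}
    trait_effects: list[tuple[str, str, float]] = []
    slot = 0
    for module in modules:
        for _ in range(P.traits_per_module):
            trait = traits[slot % P.n_traits]
            r = float(rng.uniform(*P.trait_effect_range))
            effect_of_trait[trait].append((module, r))
            trait_effects.append((trait, module, r))
            slot += 1
    ph = np.zeros((P.n_samples, P.n_traits))
    for t, trait in enumerate(traits):
        effs = effect_of_trait[trait]
        total_r2 = sum(r * r for _, r in effs)
        if total_r2 >= 1:
            raise ValidationError(f"trait {trait} effects exceed unit variance")
        y = np.zeros(P.n_samples)
        for module, r in effs:
            y += r * F.loc[module].to_numpy()
        y += np.sqrt(1.0 - total_r2) * rng.standard_normal(P.n_samples)
        ph[:, t] = y
    ph += _nuisance_matrix(rng, cov, P.nuisance_magnitudes, P.n_traits,
                           P.nonlinear_covariate).T
    miss = rng.random(ph.shape) < P.phenotype_missing_rate
    ph = np.where(miss, np.nan, ph)
    phenotypes = PhenotypeTable(pd.DataFrame(ph, index=samples, columns=traits))

    # --- regulator miRNAs and families -----------------------------------
    n_reg = int(round(P.regulator_fraction * P.n_mirnas))
    n_fam = n_reg // P.family_size
    n_reg = n_fam * P.family_size
    families: dict[str, str] = {}
    fam_module: dict[str, str] = {}
    fam_members: dict[str, list[str]] = {}
    for f in range(n_fam):
        fam = f"fam{f + 1}"
        members = mirnas[f * P.family_size:(f + 1) * P.family_size]
        fam_members[fam] = members
        fam_module[fam] = modules[f % P.n_modules]
        for mi in members:
            families[mi] = fam
    for mi in mirnas[n_reg:]:
        families[mi] = mi  # non-regulators are singleton families

    mi_expr = rng.normal(0.0, P.noise_sd, size=(P.n_mirnas, P.n_samples))
    mi_load = rng.uniform(*P.loading_range, size=P.n_mirnas)
    for fam, members in fam_members.items():
        m = modules.index(fam_module[fam])
        for mi in members:
            row = mirnas.index(mi)
            mi_expr[row] += -mi_load[row] * factors[m]
    bg_mi = np.arange(n_reg, P.n_mirnas)
    mi_expr[bg_mi] += rng.normal(0.0, extra_sd, size=(len(bg_mi), P.n_samples))
    mi_expr += rng.normal(P.baseline_mean, P.baseline_sd, size=(P.n_mirnas, 1))
    mi_expr += _nuisance_matrix(rng, cov, P.nuisance_magnitudes, P.n_mirnas,
                                P.nonlinear_covariate)
    mirna = ExpressionMatrix(pd.DataFrame(mi_expr, index=mirnas, columns=samples))

    # --- sequences --------------------------------------------------------
    mi_seqs: dict[str, str] = {}
    fam_seed_region: dict[str, str] = {}
    for fam, members in fam_members.items():
        region = _random_seq(rng, 7)  # shared miRNA positions 2-8
        fam_seed_region[fam] = region
        for mi in members:
            seq = _random_seq(rng, P.mirna_length)
            mi_seqs[mi] = seq[0] + region + seq[8:]
    for mi in mirnas[n_reg:]:
        mi_seqs[mi] = _random_seq(rng, P.mirna_length)
    mirna_seqs = SequenceSet({mi: mi_seqs[mi] for mi in mirnas},
                             kind="mirna_mature")

    ulo, uhi = P.utr_length_range
    utr_raw = {g: _random_seq(rng, int(rng.integers(ulo, uhi + 1)))
               for g in genes}

    # --- planted regulator edges -----------------------------------------
    edge_rows = []
    fams_of_module: dict[str, list[str]] = {m: [] for m in modules}
    for fam in fam_members:
        fams_of_module[fam_module[fam]].append(fam)
    for module in modules:
        fams = fams_of_module[module]
        if not fams:
            continue
        pool = [g for g in genes if assignment[g] == module]
        need = P.targets_per_family * len(fams)
        if need > len(pool):
            raise ValidationError(
                f"module {module} too small for {need} planted targets")
        picked = list(rng.choice(pool, size=need, replace=False))
        for fi, fam in enumerate(fams):
            targets = picked[fi * P.targets_per_family:(fi + 1) * P.targets_per_family]
            rep = fam_members[fam][0]   # family members share the seed
            for g in targets:
                utr = utr_raw[g]
                site_pos = int(rng.integers(0, len(utr) - 8 + 1))
                utr_raw[g] = plant_seed_site(utr, mi_seqs[rep], "8mer", site_pos)
                for mi in fam_members[fam]:
                    edge_rows.append({"miRNA_probe": mi, "gene_probe": g,
                                      "sign": -1, "family": fam,
                                      "site_start": site_pos,
                                      "site_type": "8mer"})
    regulator_edges = pd.DataFrame(
        edge_rows, columns=["miRNA_probe", "gene_probe", "sign", "family",
                            "site_start", "site_type"])
    utr_seqs = SequenceSet(utr_raw, kind="utr3")

    # --- annotation -------------------------------------------------------
    terms: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for m, module in enumerate(modules):
        members = [g for g in genes if assignment[g] == module]
        k = max(2, int(round(P.term_coverage * len(members))))
        chosen = sorted(rng.choice(members, size=min(k, len(members)),
                                   replace=False))
        tid = f"TERM:{m + 1:04d}"
        terms[tid] = frozenset(chosen)
        names[tid] = f"planted process {module}"
    for b in range(P.n_background_terms):
        size = int(rng.integers(20, 61))
        chosen = sorted(rng.choice(genes, size=size, replace=False))
        tid = f"TERM:9{b + 1:03d}"
        terms[tid] = frozenset(chosen)
        names[tid] = f"background term {b + 1}"
    annotation = AnnotationMap(terms, names)

    truth = SyntheticTruth(assignment, F, trait_effects, regulator_edges,
                           families, dict(P.nuisance_magnitudes))
    return SimulatedDataset(mrna, mirna, phenotypes, covariates, mirna_seqs,
                            utr_seqs, annotation, truth)
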