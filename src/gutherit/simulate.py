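"""Synthetic data generator for the family-tank microbiome design.

Emulates the study design the downstream analyses assume: full-sib salmon
families split over two tanks each, five fish sampled per tank across four
sampling days, family-structured biallelic SNP genotypes, OTU
log-abundances with chosen additive-genetic (h2) and tank (c2) variance
fractions, paired PMA/untreated count tables with planted dead and
contaminant OTUs, and host phenotypes with chosen regressions on the log
OTU abundances.

Breeding values are built from SNP effects (infinitesimal model: i.i.d.
normal effects over all SNPs, rescaled to the target additive variance),
so the same genotypes drive heritability, GWAS-power and association
tests.  Counts arise from the latent log-abundances by softmax to relative
abundances and multinomial sampling at a fixed depth, matching the
rarefied-count analyses downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeData, OtuTable

__all__ = [
    "StudyDesign",
    "SimTruth",
    "PHENOTYPE_NAMES",
    "simulate_pedigree_genotypes",
    "simulate_otu_phenotypes",
    "simulate_paired_pma",
]

# Table-1-style host metabolism variables: weights/growth, isotope atom-%
# enrichments in muscle/liver/adipose, and isotope-based feed conversion /
# efficiency indicators.
PHENOTYPE_NAMES = (
    "IW", "FW", "WG", "RG", "AMC", "AMN", "ALC", "ALN", "AAC",
    "IFCR_AMC", "IFCR_AMN", "IFER_AMC", "IFER_AMN",
)


@dataclass
class StudyDesign:
    """Counts and structure of the family-tank sampling design.

    Defaults mirror the experiment the pipeline targets: 23 full-sib
    families, 2 tanks per family, 5 fish sampled per tank (230 phenotyped
    fish), 4 sampling days.  ``n_genotyped_extra`` adds non-phenotyped
    full-sib relatives to enlarge the GRM population.
    """

    n_families: int = 23
    tanks_per_family: int = 2
    fish_per_tank: int = 5
    n_genotyped_extra: int = 0
    n_snps: int = 2000
    n_chromosomes: int = 29
    sampling_days: tuple = (1, 2, 3, 4)

    def __post_init__(self) -> None:
        for name in ("n_families", "tanks_per_family", "fish_per_tank",
                     "n_snps", "n_chromosomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_genotyped_extra < 0:
            raise ValueError("n_genotyped_extra must be >= 0")
        if self.n_chromosomes < 2:
            raise ValueError("need >= 2 chromosomes for leave-one-chromosome-out")
        if len(self.sampling_days) < 1:
            raise ValueError("need at least one sampling day")

    @property
    def n_phenotyped(self) -> int:
        return self.n_families * self.tanks_per_family * self.fish_per_tank

    @property
    def n_tanks(self) -> int:
        return self.n_families * self.tanks_per_family


@dataclass
class SimTruth:
    """Planted ground truth for recovery tests.

    ``h2`` and ``c2`` give per-OTU additive-genetic and tank variance
    fractions of the latent log-abundance (total variance 1).
    ``dead_folds`` / ``contam_folds`` map OTU ids to the untreated-vs-PMA
    fold inflation of planted dead (fold > 3) and contaminant (fold > 6)
    OTUs.  ``otu_effects`` is a (phenotype x OTU) coefficient table for
    regressions of host phenotypes on the log OTU abundances.
    """

    h2: np.ndarray
    c2: np.ndarray
    otu_effects: pd.DataFrame | None = None
    dead_folds: dict = field(default_factory=dict)
    contam_folds: dict = field(default_factory=dict)
    seed: int = 0
    base_log_abundance: np.ndarray | None = None
    day_effect: float = 0.2
    pheno_var_animal: float = 0.25
    pheno_var_tank: float = 0.10
    pheno_var_resid: float = 1.0

    def __post_init__(self) -> None:
        self.h2 = np.atleast_1d(np.asarray(self.h2, dtype=float))
        self.c2 = np.atleast_1d(np.asarray(self.c2, dtype=float))
        if self.h2.shape != self.c2.shape:
            raise ValueError("h2 and c2 must have one entry per OTU each")
        if ((self.h2 < 0) | (self.h2 >= 1)).any() or ((self.c2 < 0) | (self.c2 >= 1)).any():
            raise ValueError("h2 and c2 must lie in [0, 1)")
        if ((self.h2 + self.c2) >= 1).any():
            raise ValueError("h2 + c2 must be < 1 for every OTU")
        if set(self.dead_folds) & set(self.contam_folds):
            raise ValueError("dead and contaminant OTU sets must be disjoint")
        for otu, f in self.dead_folds.items():
            if not f > 3:
                raise ValueError(f"dead OTU {otu} needs fold > 3, got {f}")
        for otu, f in self.contam_folds.items():
            if not f > 6:
                raise ValueError(f"contaminant OTU {otu} needs fold > 6, got {f}")

    @property
    def n_otus(self) -> int:
        return len(self.h2)

    @property
    def otu_ids(self) -> list[str]:
        return [f"OTU{i + 1}" for i in range(self.n_otus)]


def _transmit(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per locus from a parent dosage row (Mendelian)."""
    het = parent == 1
    allele = (parent // 2).astype(float)  # 0 -> 0, 2 -> 1
    allele[het] = rng.integers(0, 2, size=int(het.sum()))
    return allele


def simulate_pedigree_genotypes(
    design: StudyDesign,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> tuple[GenotypeData, pd.DataFrame]:
    """Simulate parent and full-sib offspring genotypes plus the family map.

    Parents are drawn in Hardy-Weinberg proportions at allele frequencies
    uniform on ``maf_range``; each offspring receives one Mendelian gamete
    per parent per locus.  SNPs are assigned evenly to chromosomes.

    Returns the genotypes (parents, phenotyped offspring and extra
    genotyped sibs) and a family map with columns ``animal``, ``family``,
    ``tank``, ``day``, ``role``.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    m = design.n_snps
    p = rng.uniform(lo, hi, size=m)

    rows, ids, records = [], [], []
    extras_per_family = np.zeros(design.n_families, dtype=int)
    for i in range(design.n_genotyped_extra):
        extras_per_family[i % design.n_families] += 1

    days = list(design.sampling_days)
    day_cycle = 0
    for fam in range(design.n_families):
        sire = rng.binomial(2, p).astype(float)
        dam = rng.binomial(2, p).astype(float)
        fam_id = f"F{fam + 1:03d}"
        for role, g in (("sire", sire), ("dam", dam)):
            aid = f"{fam_id}_{role}"
            ids.append(aid)
            rows.append(g)
            records.append((aid, fam_id, pd.NA, pd.NA, role))

        n_off = design.tanks_per_family * design.fish_per_tank + extras_per_family[fam]
        off = np.empty((n_off, m))
        for j in range(n_off):
            off[j] = _transmit(sire, rng) + _transmit(dam, rng)
        k = 0
        for t in range(design.tanks_per_family):
            tank_id = f"{fam_id}_T{t + 1}"
            for _ in range(design.fish_per_tank):
                aid = f"{fam_id}_{k + 1:02d}"
                ids.append(aid)
                rows.append(off[k])
                records.append((aid, fam_id, tank_id, days[day_cycle % len(days)],
                                "phenotyped"))
                day_cycle += 1
                k += 1
        for _ in range(extras_per_family[fam]):
            aid = f"{fam_id}_x{k + 1:02d}"
            ids.append(aid)
            rows.append(off[k])
            records.append((aid, fam_id, pd.NA, pd.NA, "extra"))
            k += 1

    per_chrom = np.array_split(np.arange(m), design.n_chromosomes)
    chrom = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=int)
    for c, idx in enumerate(per_chrom):
        chrom[idx] = f"chr{c + 1}"
        pos[idx] = np.arange(1, len(idx) + 1) * 1000
    snp_map = pd.DataFrame({
        "snp": [f"snp{j + 1}" for j in range(m)],
        "chrom": chrom,
        "pos": pos,
    })

    geno = GenotypeData(dosages=np.vstack(rows), ids=ids, snp_map=snp_map)
    family_map = pd.DataFrame(
        records, columns=["animal", "family", "tank", "day", "role"])
    return geno, family_map


def _breeding_values(dosages: np.ndarray, target_var: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Genomic breeding values scaled to an exact realised variance."""
    n, m = dosages.shape
    u = rng.normal(size=m)
    Z = dosages - dosages.mean(axis=0)
    a = Z @ u
    sd = a.std(ddof=1)
    if sd == 0 or target_var == 0:
        return np.zeros(n)
    return a / sd * np.sqrt(target_var)


def simulate_otu_phenotypes(
    geno: GenotypeData,
    family_map: pd.DataFrame,
    truth: SimTruth,
    depth: int = 20000,
) -> tuple[OtuTable, pd.DataFrame, pd.DataFrame]:
    """Simulate latent OTU log-abundances, live counts, and host phenotypes.

    For each OTU ``k`` the latent log-abundance of phenotyped fish is

        ln A_k = base_k + day shift + a_k + t_k + e_k,

    with ``a_k`` genomic breeding values rescaled to realised variance
    ``h2_k``, tank effects of variance ``c2_k`` and residuals of variance
    ``1 - h2_k - c2_k`` (unit total variance).  Counts come from multinomial
    sampling of the softmax relative abundances at ``depth``.

    Phenotypes are linear in the latent log-abundances (coefficients
    from ``truth.otu_effects``) plus day, animal-genetic, tank and residual
    terms.

    Returns ``(live OtuTable, phenotype table, latent log-abundance table)``.
    """
    rng = np.random.default_rng(truth.seed)
    pheno_map = family_map[family_map["role"] == "phenotyped"].reset_index(drop=True)
    if pheno_map.empty:
        raise ValueError("family map contains no phenotyped animals")
    pos = {a: i for i, a in enumerate(geno.ids)}
    idx = np.array([pos[a] for a in pheno_map["animal"]])
    dos = np.where(np.isnan(geno.dosages[idx]), 0.0, geno.dosages[idx])
    n = len(pheno_map)
    K = truth.n_otus

    tanks = pd.Categorical(pheno_map["tank"])
    day = pheno_map["day"].to_numpy(dtype=float)
    day_shift = truth.day_effect * (day - day.mean())

    base = truth.base_log_abundance
    if base is None:
        # geometrically decreasing typical abundances, two dominant OTUs
        base = np.linspace(3.0, 0.0, K)
    base = np.asarray(base, dtype=float)
    if base.shape != (K,):
        raise ValueError("base_log_abundance must have one entry per OTU")

    ln = np.empty((n, K))
    for k in range(K):
        h2, c2 = truth.h2[k], truth.c2[k]
        a = _breeding_values(dos, h2, rng)
        t_eff = rng.normal(0.0, np.sqrt(c2), size=len(tanks.categories))
        e = rng.normal(0.0, np.sqrt(1.0 - h2 - c2), size=n)
        ln[:, k] = base[k] + day_shift + a + t_eff[tanks.codes] + e

    rel = np.exp(ln)
    rel /= rel.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, rel[i]) for i in range(n)])
    live = OtuTable(
        counts=pd.DataFrame(counts, index=pheno_map["animal"].to_numpy(),
                            columns=truth.otu_ids),
        arm="live",
    )
    ln_table = pd.DataFrame(ln, index=pheno_map["animal"].to_numpy(),
                            columns=truth.otu_ids)

    effects = truth.otu_effects
    if effects is None:
        effects = pd.DataFrame(0.0, index=list(PHENOTYPE_NAMES),
                               columns=truth.otu_ids)
    pheno = {}
    for name in effects.index:
        beta = effects.loc[name].reindex(truth.otu_ids).fillna(0.0).to_numpy()
        a_p = _breeding_values(dos, truth.pheno_var_animal, rng)
        t_p = rng.normal(0.0, np.sqrt(truth.pheno_var_tank),
                         size=len(tanks.categories))
        e_p = rng.normal(0.0, np.sqrt(truth.pheno_var_resid), size=n)
        pheno[name] = ln @ beta + truth.day_effect * day + a_p + t_p[tanks.codes] + e_p

    pheno_table = pd.DataFrame({
        "animal": pheno_map["animal"].to_numpy(),
        "family": pheno_map["family"].to_numpy(),
        "tank": pheno_map["tank"].to_numpy(),
        "day": pheno_map["day"].to_numpy(),
        **pheno,
    })
    return live, pheno_table, ln_table


def simulate_paired_pma(
    live_table: OtuTable,
    truth: SimTruth,
    depth: int = 10000,
    seed: int = 0,
) -> tuple[OtuTable, OtuTable]:
    """Derive paired PMA-treated and untreated count tables.

    The PMA arm reflects the live composition.  In the untreated arm the
    planted dead and contaminant OTUs are inflated by their fold factors
    relative to the PMA arm (free DNA and dead cells amplify only without
    the PMA dye).  Both arms are multinomially resampled to ``depth``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    rel = live_table.relative_abundance()
    folds = pd.Series(1.0, index=live_table.otu_ids)
    for otu, f in {**truth.dead_folds, **truth.contam_folds}.items():
        if otu in folds.index:
            folds[otu] = float(f)
    rel_untr = rel * folds
    rel_untr = rel_untr.div(rel_untr.sum(axis=1), axis=0)

    def _draw(relframe):
        out = np.vstack([
            rng.multinomial(depth, relframe.iloc[i].to_numpy())
            for i in range(len(relframe))
        ])
        return pd.DataFrame(out, index=relframe.index, columns=relframe.columns)

    pma = OtuTable(counts=_draw(rel), arm="pma")
    untreated = OtuTable(counts=_draw(rel_untr), arm="untreated")
    return pma, untreated
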