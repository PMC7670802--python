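"""End-to-end orchestration of the microbiome-genetics analysis stages.

Chains the stages in study order — simulate (or load), PMA screen,
log-transform + outlier QC, genotype QC + GRM, per-OTU heritability,
LOCO GWAS, and phenotype association — exchanging the documented
tab-delimited tables.  Each stage emits one RunLog record with row counts
and parameters so no exclusion happens silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import qc as qc_mod
from . import screen as screen_mod
from .datatypes import GenotypeData, Grm, OtuTable
from .grm import qc_genotypes, vanraden_grm
from .gwas import mlm_loco_scan
from .io import PipelineConfig
from .reml import AnimalModelSpec, RemlError, fit_animal_model, lr_test_genetic
from .simulate import (PHENOTYPE_NAMES, SimTruth, StudyDesign,
                       simulate_otu_phenotypes, simulate_paired_pma,
                       simulate_pedigree_genotypes)

__all__ = [
    "RunLog", "default_truth", "simulate_all", "ln_otu_responses",
    "run_h2", "run_gwas", "run_assoc", "run_all",
]


@dataclass
class RunLog:
    """One summary record per pipeline stage."""

    records: list = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int, seed: int | None = None,
            warnings: tuple = (), **params) -> None:
        self.records.append({
            "stage": stage, "n_in": n_in, "n_out": n_out,
            "seed": seed, "params": dict(params),
            "warnings": list(warnings),
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def default_truth(seed: int = 0, n_live: int = 6, n_dead: int = 1,
                  n_contam: int = 1) -> SimTruth:
    """Default planted truth: six dominant live OTUs (the first two with a
    modest genetic and tank signal), one dead-planted and one
    contaminant-planted low-abundance OTU."""
    K = n_live + n_dead + n_contam
    h2 = np.zeros(K)
    c2 = np.zeros(K)
    h2[:2] = (0.30, 0.15)
    c2[:2] = (0.10, 0.05)
    base = np.concatenate([
        np.linspace(3.0, 0.5, n_live),
        np.full(n_dead + n_contam, -1.0),
    ])
    dead = {f"OTU{n_live + i + 1}": 4.5 for i in range(n_dead)}
    contam = {f"OTU{n_live + n_dead + i + 1}": 10.0 for i in range(n_contam)}
    effects = pd.DataFrame(0.0, index=list(PHENOTYPE_NAMES),
                           columns=[f"OTU{i + 1}" for i in range(K)])
    effects.loc["WG", "OTU3"] = -1.35  # planted growth association
    effects.loc["AAC", "OTU5"] = 0.006
    return SimTruth(h2=h2, c2=c2, otu_effects=effects, dead_folds=dead,
                    contam_folds=contam, seed=seed, base_log_abundance=base)


def simulate_all(config: PipelineConfig, truth: SimTruth | None = None,
                 log: RunLog | None = None) -> dict:
    """Generate genotypes, OTU tables (live + paired arms) and phenotypes."""
    design = StudyDesign(
        n_families=config.n_families,
        tanks_per_family=config.tanks_per_family,
        fish_per_tank=config.fish_per_tank,
        n_genotyped_extra=config.n_genotyped_extra,
        n_snps=config.n_snps,
        n_chromosomes=config.n_chromosomes,
    )
    if truth is None:
        truth = default_truth(seed=config.seed)
    geno, family_map = simulate_pedigree_genotypes(design, seed=config.seed)
    live, pheno, ln_truth = simulate_otu_phenotypes(
        geno, family_map, truth, depth=2 * config.rarefaction_depth)
    pma, untreated = simulate_paired_pma(
        live, truth, depth=2 * config.rarefaction_depth,
        seed=config.seed + 1)
    if log is not None:
        log.add("simulate", n_in=0, n_out=len(pheno), seed=config.seed,
                n_snps=design.n_snps, n_families=design.n_families)
    return {
        "design": design, "truth": truth, "genotypes": geno,
        "family_map": family_map, "live": live, "phenotypes": pheno,
        "ln_truth": ln_truth, "pma": pma, "untreated": untreated,
    }


def ln_otu_responses(table: OtuTable, otus: list[str]) -> pd.DataFrame:
    """Natural-log relative abundances of the chosen OTUs.

    Samples where any chosen OTU has zero counts are dropped (the log is
    undefined there); the dominant OTUs are present in essentially all
    samples, so this removes few if any rows.
    """
    rel = table.relative_abundance()[otus]
    keep = (rel > 0).all(axis=1)
    sub = rel.loc[keep]
    return pd.DataFrame(qc_mod.ln_transform(sub.to_numpy()),
                        index=sub.index, columns=otus)


def _model_frame(pheno: pd.DataFrame, ln_otus: pd.DataFrame) -> pd.DataFrame:
    df = pheno.merge(ln_otus, left_on="animal", right_index=True, how="inner")
    return df.reset_index(drop=True)


def run_h2(table: OtuTable, pheno: pd.DataFrame, grm: Grm,
           otus: list[str] | None = None, remove_outliers: bool = True,
           log: RunLog | None = None,
           phenotype_columns: list[str] | None = None) -> pd.DataFrame:
    """Per-OTU animal-model variance components, h2, c2 and the LR test.

    Produces one row per OTU with the component estimates, their ratio
    fractions +- delta-method SE, the LR chi-square for the additive
    genetic term and its p-value, and boundary flags.
    """
    rel = table.relative_abundance()
    if otus is None:
        per_otu, high, _ = screen_mod.summarize_community(table)
        otus = high
    if phenotype_columns is None:
        phenotype_columns = [c for c in PHENOTYPE_NAMES if c in pheno.columns]

    rows = []
    for otu in otus:
        ln = ln_otu_responses(table, [otu])
        df = _model_frame(pheno, ln)
        n0 = len(df)
        if remove_outliers and phenotype_columns:
            X = np.column_stack(
                [np.ones(len(df))] +
                [df[c].to_numpy(dtype=float) for c in phenotype_columns])
            report = qc_mod.detect_outliers(
                df[otu].to_numpy(), X, sample_ids=df["animal"],
                column_names=["intercept"] + list(phenotype_columns))
            df = df[~df["animal"].isin(report.flagged)].reset_index(drop=True)
        spec = AnimalModelSpec(response=otu, data=df, grm=grm)
        try:
            fit1 = fit_animal_model(spec)
            fit0 = fit_animal_model(spec, include_genetic=False)
            lr, p = lr_test_genetic(fit1, fit0)
        except RemlError as exc:
            rows.append({"otu": otu, "error": str(exc)})
            continue
        rows.append({
            "otu": otu,
            "sigma_a2": fit1.sigma_a2,
            "sigma_t2": fit1.sigma_t2,
            "sigma_e2": fit1.sigma_e2,
            "c2": fit1.c2, "c2_se": fit1.c2_se,
            "h2": fit1.h2, "h2_se": fit1.h2_se,
            "chi2": lr, "p": p,
            "boundary_animal": fit1.boundary.get("animal", False),
            "boundary_tank": fit1.boundary.get("tank", False),
            "n": fit1.n, "n_outliers_removed": n0 - len(df),
        })
        if log is not None:
            log.add("h2", n_in=n0, n_out=len(df), otu=otu)
    return pd.DataFrame(rows)


def run_gwas(table: OtuTable, pheno: pd.DataFrame, geno: GenotypeData,
             otus: list[str], log: RunLog | None = None):
    """LOCO mixed-model scan of each requested OTU's log abundance."""
    results = {}
    for otu in otus:
        ln = ln_otu_responses(table, [otu])
        df = _model_frame(pheno, ln)
        keep = [i for i, a in enumerate(geno.ids) if a in set(df["animal"])]
        sub = geno.subset_individuals(np.array(keep))
        y = ln.loc[sub.ids, otu].to_numpy()
        res = mlm_loco_scan(y, sub)
        results[otu] = res
        if log is not None:
            log.add("gwas", n_in=len(df), n_out=len(res.table), otu=otu)
    return results


def run_assoc(table: OtuTable, pheno: pd.DataFrame, grm: Grm,
              otus: list[str] | None = None,
              phenotypes: list[str] | None = None,
              log: RunLog | None = None) -> pd.DataFrame:
    """Phenotype-on-OTUs mixed-model regressions, combined report."""
    if otus is None:
        _, otus, _ = screen_mod.summarize_community(table)
    if phenotypes is None:
        phenotypes = [c for c in PHENOTYPE_NAMES if c in pheno.columns]
    ln = ln_otu_responses(table, list(otus))
    ln = ln.rename(columns={o: f"ln_{o}" for o in otus})
    df = _model_frame(pheno, ln)
    fits = []
    for ph in phenotypes:
        fits.append(assoc_mod.fit_association(
            ph, df, grm, [f"ln_{o}" for o in otus]))
        if log is not None:
            log.add("assoc", n_in=len(df), n_out=len(fits[-1].table),
                    phenotype=ph)
    return assoc_mod.build_assoc_report(fits)


def run_all(config: PipelineConfig, truth: SimTruth | None = None,
            gwas_otus: int = 1) -> dict:
    """simulate -> screen -> qc -> grm -> h2 -> gwas -> assoc, in memory."""
    log = RunLog()
    sim = simulate_all(config, truth=truth, log=log)

    screen_res = screen_mod.screen_dataset(
        sim["pma"], sim["untreated"], depth=config.rarefaction_depth,
        dead_fold=config.dead_fold, contam_fold=config.contam_fold,
        seed=config.seed + 2)
    log.add("screen", n_in=len(sim["untreated"].counts),
            n_out=len(screen_res.qc_pass), seed=config.seed + 2,
            depth=config.rarefaction_depth)

    geno_qc = qc_genotypes(sim["genotypes"], maf_min=config.maf_min,
                           snp_call_min=config.snp_call_min,
                           ind_missing_max=config.ind_missing_max)
    log.add("genotype_qc", n_in=sim["genotypes"].n_snps,
            n_out=geno_qc.n_snps)
    grm = vanraden_grm(geno_qc)
    log.add("grm", n_in=geno_qc.n_snps, n_out=len(grm.ids))

    _, high, _ = screen_mod.summarize_community(
        screen_res.filtered, config.abundance_threshold)
    h2_table = run_h2(screen_res.filtered, sim["phenotypes"], grm,
                      otus=high, log=log)
    gwas_res = run_gwas(screen_res.filtered, sim["phenotypes"], geno_qc,
                        otus=high[:gwas_otus], log=log)
    assoc_table = run_assoc(screen_res.filtered, sim["phenotypes"], grm,
                            otus=high, log=log)
    return {
        "sim": sim, "screen": screen_res, "grm": grm,
        "high_abundance_otus": high, "h2": h2_table, "gwas": gwas_res,
        "assoc": assoc_table, "log": log,
    }
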