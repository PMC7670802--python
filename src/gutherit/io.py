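"""Readers and writers for the pipeline's tab-delimited formats and VCF.

All tables are UTF-8 tab-delimited with a mandatory header row; missing
values are written as ``NA``.  Genotypes can be read from VCF (GT field
converted to alternate-allele dosage via cyvcf2) or from a dosage matrix
plus a SNP map file.  GRMs round-trip both as a square matrix with id
header and as an ids-file + lower-triangle triplet pair.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import GenotypeData, Grm, OtuTable

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_otu_table", "write_otu_table",
    "read_phenotypes", "write_phenotypes",
    "read_dosage", "write_dosage",
    "read_vcf", "write_vcf",
    "read_grm_square", "write_grm_square",
    "read_grm_triplet", "write_grm_triplet",
    "read_truth_sidecar", "write_truth_sidecar",
]


@dataclass
class PipelineConfig:
    """Printed-constant defaults for the end-to-end pipeline."""

    rarefaction_depth: int = 10000
    dead_fold: float = 3.0
    contam_fold: float = 6.0
    maf_min: float = 0.01
    snp_call_min: float = 0.90
    ind_missing_max: float = 0.10
    alpha: float = 0.05
    abundance_threshold: float = 0.01
    seed: int = 0
    n_families: int = 23
    tanks_per_family: int = 2
    fish_per_tank: int = 5
    n_genotyped_extra: int = 0
    n_snps: int = 2000
    n_chromosomes: int = 29

    def __post_init__(self) -> None:
        if self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be positive")
        if not (self.dead_fold > 1 and self.contam_fold > 1):
            raise ValueError("fold thresholds must exceed 1")
        for name in ("maf_min", "snp_call_min", "ind_missing_max", "alpha",
                     "abundance_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML key-value config; unknown keys are rejected.

    Precedence: explicit keyword overrides > file values > defaults.
    """
    values = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must be a key-value mapping")
        values.update(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**values)


# ---------------------------------------------------------------- OTU tables

def write_otu_table(table: OtuTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.insert(0, "sample", df.index)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_otu_table(path: str | Path, arm: str = "untreated") -> OtuTable:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample":
        raise ValueError(f"malformed OTU table header: first column must be "
                         f"'sample', got '{df.columns[0]}'")
    df = df.set_index("sample")
    df.index.name = None
    return OtuTable(counts=df.astype(int), arm=arm)


# ---------------------------------------------------------------- phenotypes

def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("animal", "tank", "day"):
        if col not in df.columns:
            raise ValueError(f"phenotype table is missing column '{col}'")
    return df


# ----------------------------------------------------------------- genotypes

def write_dosage(geno: GenotypeData, dosage_path: str | Path,
                 map_path: str | Path) -> None:
    df = pd.DataFrame(geno.dosages, index=geno.ids,
                      columns=geno.snp_map["snp"])
    df.insert(0, "id", df.index)
    df.to_csv(dosage_path, sep="\t", index=False, na_rep="NA",
              float_format="%g")
    geno.snp_map.to_csv(map_path, sep="\t", index=False)


def read_dosage(dosage_path: str | Path, map_path: str | Path) -> GenotypeData:
    df = pd.read_csv(dosage_path, sep="\t", na_values=["NA"])
    if df.columns[0] != "id":
        raise ValueError("malformed dosage header: first column must be 'id'")
    snp_map = pd.read_csv(map_path, sep="\t")
    for col in ("snp", "chrom", "pos"):
        if col not in snp_map.columns:
            raise ValueError(f"malformed SNP map: missing column '{col}'")
    ids = df["id"].astype(str).tolist()
    dosages = df[snp_map["snp"]].to_numpy(dtype=float)
    return GenotypeData(dosages=dosages, ids=ids, snp_map=snp_map)


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(geno: GenotypeData, path: str | Path) -> None:
    """Write dosages as a minimal uncompressed VCF (GT field only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(geno.snp_map["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.ids) + "\n")
        for j, row in geno.snp_map.iterrows():
            gts = "\t".join(
                _GT.get(geno.dosages[i, j], "./.")
                for i in range(geno.n_individuals))
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['snp']}\tA\tG\t.\t"
                     f"PASS\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> GenotypeData:
    """Read genotypes from a VCF; GT becomes alternate-allele dosage."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, snp, chrom, pos = [], [], [], []
    # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
    code = np.array([0.0, 1.0, np.nan, 2.0])
    for v in vcf:
        rows.append(code[v.gt_types])
        snp.append(v.ID if v.ID else f"{v.CHROM}:{v.POS}")
        chrom.append(v.CHROM)
        pos.append(v.POS)
    vcf.close()
    snp_map = pd.DataFrame({"snp": snp, "chrom": chrom, "pos": pos})
    return GenotypeData(dosages=np.array(rows).T, ids=ids, snp_map=snp_map)


# ----------------------------------------------------------------------- GRM

def write_grm_square(grm: Grm, path: str | Path) -> None:
    df = pd.DataFrame(grm.matrix, index=grm.ids, columns=grm.ids)
    df.insert(0, "id", df.index)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_grm_square(path: str | Path, n_snps_used: int = 0) -> Grm:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "id":
        raise ValueError("malformed GRM header: first column must be 'id'")
    ids = df["id"].astype(str).tolist()
    M = df[df.columns[1:]].to_numpy(dtype=float)
    M = (M + M.T) / 2.0  # kill round-trip asymmetry at print precision
    return Grm(ids=ids, matrix=M, n_snps_used=n_snps_used)


def write_grm_triplet(grm: Grm, ids_path: str | Path,
                      values_path: str | Path) -> None:
    """Lower-triangle (i, j, value) text form plus an ids sidecar."""
    with open(ids_path, "w") as fh:
        fh.write("id\n")
        for s in grm.ids:
            fh.write(f"{s}\n")
    n = len(grm.ids)
    with open(values_path, "w") as fh:
        fh.write("i\tj\tvalue\n")
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i}\t{j}\t{grm.matrix[i, j]:.17g}\n")


def read_grm_triplet(ids_path: str | Path, values_path: str | Path,
                     n_snps_used: int = 0) -> Grm:
    ids = pd.read_csv(ids_path, sep="\t")["id"].astype(str).tolist()
    trip = pd.read_csv(values_path, sep="\t")
    n = len(ids)
    M = np.zeros((n, n))
    M[trip["i"], trip["j"]] = trip["value"]
    M = M + np.tril(M, -1).T
    return Grm(ids=ids, matrix=M, n_snps_used=n_snps_used)


# ------------------------------------------------------------- truth sidecar

def write_truth_sidecar(truth, path: str | Path) -> None:
    """Planted simulation truth as a YAML sidecar for recovery tests."""
    payload = {
        "h2": [float(v) for v in truth.h2],
        "c2": [float(v) for v in truth.c2],
        "dead_folds": {k: float(v) for k, v in truth.dead_folds.items()},
        "contam_folds": {k: float(v) for k, v in truth.contam_folds.items()},
        "seed": int(truth.seed),
    }
    if truth.otu_effects is not None:
        payload["otu_effects"] = {
            str(ph): {str(o): float(v) for o, v in row.items()}
            for ph, row in truth.otu_effects.iterrows()
        }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_truth_sidecar(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
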