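"""SNP/individual quality control and VanRaden method-1 GRM construction.

The genomic relationship matrix (GRM) is built as

    G = Z Z' / (2 * sum_j p_j (1 - p_j)),    Z = M - 2p,

where ``M`` is the dosage matrix, ``p_j`` the observed allele frequency of
SNP ``j`` in the (post-QC) sample, and missing dosages are mean-imputed
(equivalently: zero deviation after centering).  A leave-one-chromosome-out
(LOCO) variant drops all SNPs on one chromosome, for use in mixed-model
association scans where the candidate SNP's chromosome must not enter the
polygenic covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import GenotypeData, Grm

__all__ = ["GenotypeQcReport", "qc_genotypes", "vanraden_grm", "loco_grm"]


@dataclass
class GenotypeQcReport:
    n_individuals_in: int
    n_individuals_kept: int
    n_snps_in: int
    n_snps_kept: int
    n_snps_failed_maf: int
    n_snps_failed_callrate: int


def _allele_freqs(dosages: np.ndarray) -> np.ndarray:
    """Observed allele frequency per SNP, ignoring missing calls."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(dosages, axis=0) / 2.0


def qc_genotypes(
    geno: GenotypeData,
    maf_min: float = 0.01,
    snp_call_min: float = 0.90,
    ind_missing_max: float = 0.10,
    return_report: bool = False,
):
    """Filter individuals by missingness, then SNPs by MAF and call rate.

    Individuals with a missing-genotype fraction >= ``ind_missing_max`` are
    dropped first; SNP statistics are then computed on the retained
    individuals.  A SNP is kept when its minor allele frequency is at least
    ``maf_min`` and its call rate is strictly greater than ``snp_call_min``.
    """
    miss_ind = np.isnan(geno.dosages).mean(axis=1)
    keep_ind = miss_ind < ind_missing_max
    sub = geno.subset_individuals(keep_ind)

    call_rate = 1.0 - np.isnan(sub.dosages).mean(axis=0)
    p = _allele_freqs(sub.dosages)
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)
    ok_call = call_rate > snp_call_min
    ok_maf = maf >= maf_min
    keep_snp = ok_call & ok_maf
    if not keep_snp.any():
        raise ValueError("genotype QC removed every SNP")
    out = sub.subset_snps(keep_snp)
    if return_report:
        report = GenotypeQcReport(
            n_individuals_in=geno.n_individuals,
            n_individuals_kept=sub.n_individuals,
            n_snps_in=geno.n_snps,
            n_snps_kept=out.n_snps,
            n_snps_failed_maf=int((~ok_maf).sum()),
            n_snps_failed_callrate=int((~ok_call).sum()),
        )
        return out, report
    return out


def _centered_dosages(geno: GenotypeData, snp_idx: np.ndarray | None = None,
                      freqs: np.ndarray | None = None):
    """Z = M - 2p with missing entries imputed to the SNP mean (zero deviation)."""
    M = geno.dosages if snp_idx is None else geno.dosages[:, snp_idx]
    if freqs is None:
        p = _allele_freqs(M)
    else:
        p = np.asarray(freqs, dtype=float)
        if snp_idx is not None:
            p = p[snp_idx]
    Z = M - 2.0 * p
    Z[np.isnan(Z)] = 0.0
    return Z, p


def vanraden_grm(geno: GenotypeData, snp_subset: np.ndarray | None = None,
                 allele_freqs: np.ndarray | None = None) -> Grm:
    """VanRaden method-1 GRM from (QC'd) dosages.

    Allele frequencies default to the observed sample frequencies;
    ``allele_freqs`` (one per SNP of ``geno``) substitutes an external,
    e.g. founder-population, estimate.  ``snp_subset`` restricts the
    computation to a boolean/integer selection of SNP columns (used by
    :func:`loco_grm`).
    """
    if snp_subset is not None:
        snp_subset = np.asarray(snp_subset)
        if snp_subset.dtype == bool:
            snp_subset = np.flatnonzero(snp_subset)
        if snp_subset.size == 0:
            raise ValueError("empty SNP subset for GRM")
    Z, p = _centered_dosages(geno, snp_subset, allele_freqs)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: GRM denominator is zero")
    G = (Z @ Z.T) / denom
    return Grm(
        ids=list(geno.ids),
        matrix=G,
        n_snps_used=Z.shape[1],
        allele_freqs=p,
    )


def loco_grm(geno: GenotypeData, exclude_chromosome) -> Grm:
    """GRM from all SNPs *not* on ``exclude_chromosome``."""
    chroms = geno.snp_map["chrom"].to_numpy()
    if len(np.unique(chroms)) < 2 and (chroms == exclude_chromosome).any():
        raise ValueError("cannot leave out the only chromosome")
    keep = chroms != exclude_chromosome
    if not keep.any():
        raise ValueError("excluding this chromosome removes every SNP")
    return vanraden_grm(geno, snp_subset=keep)
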