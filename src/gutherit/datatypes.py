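"""Core in-memory containers shared across the pipeline stages.

All tabular data is carried in pandas objects so that identifiers travel
with the numbers; heavy numerics (GRM algebra, REML) work on the
underlying numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OtuTable", "GenotypeData", "Grm"]


@dataclass
class OtuTable:
    """Integer OTU count matrix, samples x OTUs.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with one integer column per OTU.
    arm
        Treatment arm the counts come from: ``"pma"`` (propidium-monoazide
        treated, live signal), ``"untreated"`` (control arm), or ``"live"``
        (simulated ground truth / screened output).
    taxonomy
        Optional Series mapping OTU id -> phylum (or any roll-up label),
        passed through by community summaries.
    """

    counts: pd.DataFrame
    arm: str = "untreated"
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples x OTUs table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("OTU counts must be non-negative")

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.columns

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised relative abundances (rows with zero total stay zero)."""
        totals = self.counts.sum(axis=1).replace(0, np.nan)
        return self.counts.div(totals, axis=0).fillna(0.0)


@dataclass
class GenotypeData:
    """Biallelic SNP dosages for a set of individuals.

    ``dosages`` is an ``n_individuals x n_snps`` float array with values in
    {0, 1, 2} and ``nan`` for missing calls.  ``snp_map`` has one row per
    SNP with columns ``snp``, ``chrom``, ``pos`` in column order of
    ``dosages``.
    """

    dosages: np.ndarray
    ids: list[str]
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.snp_map)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} ids x {len(self.snp_map)} mapped SNPs"
            )
        required = {"snp", "chrom", "pos"}
        if not required.issubset(self.snp_map.columns):
            raise ValueError(f"snp_map must have columns {sorted(required)}")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, [0.0, 1.0, 2.0]).all():
            raise ValueError("dosages must be 0/1/2 or missing (nan)")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.snp_map["chrom"]))

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeData":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeData(
            dosages=self.dosages[idx],
            ids=[self.ids[i] for i in idx],
            snp_map=self.snp_map.copy(),
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypeData":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeData(
            dosages=self.dosages[:, idx],
            ids=list(self.ids),
            snp_map=self.snp_map.iloc[idx].reset_index(drop=True),
        )


@dataclass
class Grm:
    """Genomic relationship matrix over a set of individuals."""

    ids: list[str]
    matrix: np.ndarray
    n_snps_used: int
    allele_freqs: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM must be square over the individual ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")

    def subset(self, ids: list[str]) -> "Grm":
        """Submatrix for the given individuals, in the given order."""
        pos = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"individuals not in GRM: {missing[:5]}")
        idx = np.array([pos[s] for s in ids])
        return Grm(
            ids=list(ids),
            matrix=self.matrix[np.ix_(idx, idx)],
            n_snps_used=self.n_snps_used,
            allele_freqs=self.allele_freqs,
        )
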