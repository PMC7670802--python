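"""Mixed-linear-model GWAS with a leave-one-chromosome-out polygenic term.

For each chromosome c the polygenic model

    y = a + b x + g- + eps,   g- ~ N(0, G_loco sigma_g^2),  eps ~ N(0, I sigma_e^2)

is fitted once under the null (no SNP) by REML, with G_loco built from all
SNPs *except* those on c, and sigma_g^2 re-estimated for every excluded
chromosome.  The eigendecomposition of G_loco then whitens the data so
each SNP on c is tested by weighted least squares at O(n) cost: the
default per-SNP test re-estimates the residual scale of the whitened
regression and reports a t-based p-value (this collapses exactly to
simple-regression p-values when the polygenic variance is zero); a
generalized likelihood-ratio test with variance components held at the
null fit is available as ``test="lr"``.

Genome-wide significance uses Bonferroni control over the number of SNPs
tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeData
from .grm import loco_grm
from .reml import reml

__all__ = [
    "GwasResult",
    "mlm_loco_scan",
    "bonferroni_threshold",
    "genomic_inflation",
]


@dataclass
class GwasResult:
    table: pd.DataFrame  # snp, chrom, pos, beta, se, stat, p, neglog10p
    sigma_g2: dict = field(default_factory=dict)  # chrom -> polygenic variance
    sigma_e2: dict = field(default_factory=dict)

    def top_hits(self, k: int = 10) -> pd.DataFrame:
        return self.table.nsmallest(k, "p")


def mlm_loco_scan(
    y: np.ndarray,
    geno: GenotypeData,
    covariates: np.ndarray | None = None,
    test: str = "wald",
    fix_sigma_g2: float | None = None,
) -> GwasResult:
    """Scan every SNP against ``y`` with a LOCO polygenic control.

    ``y`` must be aligned with ``geno.ids`` (one phenotype per genotyped
    individual in order).  ``covariates`` is an optional n x q matrix added
    to the intercept in the fixed design.  ``fix_sigma_g2`` pins the
    polygenic variance instead of re-estimating it per chromosome
    (diagnostic use; 0.0 reduces the scan to simple regression).
    """
    y = np.asarray(y, dtype=float)
    n = geno.n_individuals
    if len(y) != n:
        raise ValueError("phenotype length does not match genotype rows")
    chroms = geno.chromosomes
    if len(chroms) < 2:
        raise ValueError("leave-one-chromosome-out needs >= 2 chromosomes")
    if test not in ("wald", "lr"):
        raise ValueError(f"unknown test {test!r}")

    X0 = np.ones((n, 1))
    if covariates is not None:
        X0 = np.column_stack([X0, np.asarray(covariates, dtype=float)])
    p0 = X0.shape[1]

    rows = []
    sigma_g2, sigma_e2 = {}, {}
    chrom_col = geno.snp_map["chrom"].to_numpy()
    for c in chroms:
        G = loco_grm(geno, c)
        if fix_sigma_g2 is None:
            fit = reml(y, X0, [("polygenic", G.matrix)])
            sg = fit.components["polygenic"]
            se_ = fit.components["residual"]
        else:
            sg = float(fix_sigma_g2)
            se_ = float(np.var(y, ddof=1))
        sigma_g2[c], sigma_e2[c] = sg, se_

        d, U = np.linalg.eigh(G.matrix)
        w = 1.0 / np.sqrt(np.maximum(sg * d + se_, 1e-12))
        yt = w * (U.T @ y)
        Xt0 = w[:, None] * (U.T @ X0)
        rss_null = None
        if test == "lr":
            beta0, rss0, *_ = np.linalg.lstsq(Xt0, yt, rcond=None)
            rss_null = float(((yt - Xt0 @ beta0) ** 2).sum())

        on_c = np.flatnonzero(chrom_col == c)
        M = geno.dosages[:, on_c]
        M = np.where(np.isnan(M), np.nanmean(M, axis=0), M)
        Mt = w[:, None] * (U.T @ M)
        for jj, j in enumerate(on_c):
            x = Mt[:, jj]
            Xt = np.column_stack([Xt0, x])
            XtX = Xt.T @ Xt
            try:
                coef = np.linalg.solve(XtX, Xt.T @ yt)
            except np.linalg.LinAlgError:
                rows.append((geno.snp_map.iloc[j]["snp"], c,
                             geno.snp_map.iloc[j]["pos"],
                             np.nan, np.nan, np.nan, np.nan, np.nan))
                continue
            resid = yt - Xt @ coef
            rss = float(resid @ resid)
            df = n - p0 - 1
            if test == "wald":
                s2 = rss / df
                cov = s2 * np.linalg.inv(XtX)
                b = coef[-1]
                se_b = float(np.sqrt(cov[-1, -1]))
                tval = b / se_b
                stat = tval * tval
                p = 2.0 * stats.t.sf(abs(tval), df)
            else:
                stat = n * np.log(rss_null / rss)
                p = float(stats.chi2.sf(stat, df=1))
                b = coef[-1]
                s2 = rss / df
                se_b = float(np.sqrt(s2 * np.linalg.inv(XtX)[-1, -1]))
            p = min(max(p, np.finfo(float).tiny), 1.0)
            rows.append((geno.snp_map.iloc[j]["snp"], c,
                         geno.snp_map.iloc[j]["pos"],
                         float(b), se_b, float(stat), p, -np.log10(p)))

    table = pd.DataFrame(
        rows, columns=["snp", "chrom", "pos", "beta", "se", "stat", "p",
                       "neglog10p"])
    return GwasResult(table=table, sigma_g2=sigma_g2, sigma_e2=sigma_e2)


def bonferroni_threshold(alpha: float, n_tests: int) -> tuple[float, float]:
    """Genome-wide p threshold alpha/n_tests and its -log10."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    thr = alpha / n_tests
    return thr, -np.log10(thr)


def genomic_inflation(result) -> float:
    """Genomic inflation factor lambda: median observed test statistic over
    the chi-square(1) median (0.4549...).  Accepts a :class:`GwasResult`
    or an array of chi-square-distributed statistics."""
    if isinstance(result, GwasResult):
        statistics = result.table["stat"].to_numpy(dtype=float)
    else:
        statistics = np.asarray(result, dtype=float)
    statistics = statistics[np.isfinite(statistics)]
    if statistics.size == 0:
        raise ValueError("no test statistics to compute inflation from")
    if statistics.size < 100:
        raise ValueError("need >= 100 statistics for a stable median")
    return float(np.median(statistics) / stats.chi2.ppf(0.5, df=1))
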