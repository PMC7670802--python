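"""Live/dead/contaminant OTU screening from paired PMA and untreated samples.

Propidium monoazide (PMA) blocks PCR amplification of free DNA and DNA in
membrane-compromised cells, so comparing an untreated aliquot to its
PMA-treated pair separates signal from live cells, dead cells, and
contamination.  Per sample and OTU the untreated-to-PMA abundance ratio is
thresholded: more than 6-fold excess in the untreated arm marks a
contaminant, more than 3-fold (but at most 6) a dead OTU, anything else
live.  Contaminant takes precedence over dead so that both rules bind.

Ratios are computed on pseudocounted relative abundances within rarefied
samples: both counts get +1 before normalisation, which keeps zero-in-PMA
OTUs classifiable and removes depth confounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import OtuTable

__all__ = [
    "ViabilityCall",
    "ScreenSummary",
    "ScreenResult",
    "rarefy",
    "classify_otu_viability",
    "screen_dataset",
    "summarize_community",
    "spearman_matrix",
]

LABELS = ("live", "dead", "contaminant", "undetected")


@dataclass
class ViabilityCall:
    sample_id: str
    otu_id: str
    ratio: float  # untreated-to-PMA pseudocounted abundance ratio
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class ScreenSummary:
    """Dataset-level screen outcome, read-weighted over the untreated arm."""

    fraction_dead_reads: float
    fraction_contaminant_reads: float
    n_otus_live: int
    n_otus_dead: int
    n_otus_contaminant: int


@dataclass
class ScreenResult:
    filtered: OtuTable
    summary: ScreenSummary
    qc_pass: list[str]
    calls: pd.DataFrame  # long format: sample, otu, ratio, label


def rarefy(counts: np.ndarray, depth: int, seed: int = 0) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement.

    Raises if the vector holds fewer than ``depth`` reads: such samples
    fail QC and must be excluded by the caller (see :func:`screen_dataset`).
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    counts = counts.astype(np.int64)
    total = int(counts.sum())
    if total < depth:
        raise ValueError(
            f"sample has {total} reads, below rarefaction depth {depth}")
    if total == depth:
        return counts.copy()
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def classify_otu_viability(
    count_untreated: int,
    count_pma: int,
    dead_fold: float = 3.0,
    contam_fold: float = 6.0,
    depth_untreated: int | None = None,
    depth_pma: int | None = None,
) -> ViabilityCall:
    """Classify one OTU in one sample from its paired counts.

    The ratio is formed on pseudocounted relative abundances,
    ``((u+1)/(Du+K)) / ((p+1)/(Dp+K))``; with equal (rarefied) depths this
    reduces to ``(u+1)/(p+1)``.  Zero in both arms is ``undetected``.
    """
    if count_untreated < 0 or count_pma < 0:
        raise ValueError("counts must be non-negative")
    if not (dead_fold > 1 and contam_fold > 1):
        raise ValueError("fold thresholds must exceed 1")
    if count_untreated == 0 and count_pma == 0:
        return ViabilityCall("", "", float("nan"), "undetected")
    du = depth_untreated if depth_untreated is not None else 1
    dp = depth_pma if depth_pma is not None else 1
    ratio = ((count_untreated + 1.0) / du) / ((count_pma + 1.0) / dp)
    if ratio > contam_fold:
        label = "contaminant"
    elif ratio > dead_fold:
        label = "dead"
    else:
        label = "live"
    return ViabilityCall("", "", float(ratio), label)


def screen_dataset(
    pma_table: OtuTable,
    untreated_table: OtuTable,
    depth: int = 10000,
    dead_fold: float = 3.0,
    contam_fold: float = 6.0,
    seed: int = 0,
) -> ScreenResult:
    """Screen every paired sample and remove dead/contaminant signal.

    Samples below ``depth`` in either arm fail QC and are excluded; the
    rest are rarefied to ``depth`` per arm.  Classification and removal
    are per sample: an OTU called dead or contaminant in one fish is
    zeroed only in that fish's filtered counts.  The filtered table is the
    untreated-arm rarefied counts with dead/contaminant entries removed.
    Summary fractions are read-weighted over the untreated arm of passing
    samples; OTU-level counts label each OTU by its modal per-sample call.
    """
    shared = [s for s in untreated_table.sample_ids if s in set(pma_table.sample_ids)]
    if not shared:
        raise ValueError("PMA and untreated tables share no sample ids")
    otus = untreated_table.otu_ids.union(pma_table.otu_ids)
    pma = pma_table.counts.reindex(index=shared, columns=otus, fill_value=0)
    untr = untreated_table.counts.reindex(index=shared, columns=otus, fill_value=0)

    rng = np.random.default_rng(seed)
    qc_pass = []
    filtered_rows = {}
    records = []
    dead_reads = contam_reads = total_reads = 0
    for s in shared:
        u_row = untr.loc[s].to_numpy()
        p_row = pma.loc[s].to_numpy()
        if u_row.sum() < depth or p_row.sum() < depth:
            continue
        qc_pass.append(s)
        u_rar = rarefy(u_row, depth, seed=rng.integers(2**31))
        p_rar = rarefy(p_row, depth, seed=rng.integers(2**31))
        keep = u_rar.copy()
        for j, otu in enumerate(otus):
            u, p = int(u_rar[j]), int(p_rar[j])
            if u == 0 and p == 0:
                continue
            call = classify_otu_viability(u, p, dead_fold, contam_fold)
            records.append((s, otu, call.ratio, call.label))
            if call.label == "dead":
                dead_reads += u
                keep[j] = 0
            elif call.label == "contaminant":
                contam_reads += u
                keep[j] = 0
        total_reads += depth
        filtered_rows[s] = keep

    if not qc_pass:
        raise ValueError("no sample passed the depth QC in both arms")

    calls = pd.DataFrame(records, columns=["sample", "otu", "ratio", "label"])
    modal = calls.groupby("otu")["label"].agg(
        lambda x: x.value_counts().idxmax())
    n_live = int((modal == "live").sum())
    n_dead = int((modal == "dead").sum())
    n_contam = int((modal == "contaminant").sum())

    summary = ScreenSummary(
        fraction_dead_reads=dead_reads / total_reads,
        fraction_contaminant_reads=contam_reads / total_reads,
        n_otus_live=n_live,
        n_otus_dead=n_dead,
        n_otus_contaminant=n_contam,
    )
    filtered = OtuTable(
        counts=pd.DataFrame.from_dict(filtered_rows, orient="index",
                                      columns=otus).loc[qc_pass],
        arm="live",
        taxonomy=untreated_table.taxonomy,
    )
    return ScreenResult(filtered=filtered, summary=summary,
                        qc_pass=qc_pass, calls=calls)


def summarize_community(
    table: OtuTable,
    abundance_threshold: float = 0.01,
) -> tuple[pd.DataFrame, list[str], pd.DataFrame | None]:
    """Mean relative abundance and prevalence per OTU, plus the
    high-abundance set (mean relative abundance above ``abundance_threshold``)
    and, when taxonomy is attached, a phylum-level roll-up of read counts."""
    if table.counts.empty:
        raise ValueError("empty OTU table")
    rel = table.relative_abundance()
    per_otu = pd.DataFrame({
        "mean_rel_abundance": rel.mean(axis=0),
        "prevalence": (table.counts > 0).mean(axis=0),
    })
    high = per_otu.index[per_otu["mean_rel_abundance"] > abundance_threshold]
    rollup = None
    if table.taxonomy is not None:
        tax = table.taxonomy.reindex(table.otu_ids).fillna("unclassified")
        reads = table.counts.sum(axis=0)
        rollup = pd.DataFrame({
            "n_otus": tax.groupby(tax).size(),
            "n_reads": reads.groupby(tax).sum(),
        })
    return per_otu, list(high), rollup


def spearman_matrix(table: OtuTable, otus: list[str] | None = None) -> pd.DataFrame:
    """Spearman rank-correlation matrix between OTU abundance profiles.

    Ties get average ranks; a constant OTU column yields NaN against every
    other OTU (undefined rank correlation), with 1.0 kept on the diagonal.
    """
    if otus is None:
        otus = list(table.otu_ids)
    sub = table.counts[otus]
    if len(sub) < 3:
        raise ValueError("need at least 3 samples for rank correlations")
    arr = sub.to_numpy(dtype=float)
    k = arr.shape[1]
    out = np.full((k, k), np.nan)
    constant = arr.std(axis=0) == 0
    for i in range(k):
        out[i, i] = 1.0
        for j in range(i + 1, k):
            if constant[i] or constant[j]:
                continue
            rho = stats.spearmanr(arr[:, i], arr[:, j]).statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=otus, columns=otus)
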