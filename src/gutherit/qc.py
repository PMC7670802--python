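"""Log transformation and influence-based outlier removal.

Relative OTU abundances are brought to approximate normality with the
natural logarithm (restricted to OTUs present in every sample, as is the
case for the dominant OTUs the heritability analyses use).  Outlying
animals are then detected by regressing ln(OTU) on all host phenotypes and
flagging observations whose leverage (hat-matrix diagonal) exceeds the
classical cutoff 3p/n, where p is the number of model parameters and n the
number of samples fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = ["OutlierReport", "ln_transform", "leverage_cutoff", "detect_outliers"]


@dataclass
class OutlierReport:
    n_params: int
    n_samples: int
    cutoff: float  # 3p/n
    influence: pd.Series  # hat diagonal per sample
    flagged: list  # sample ids with influence > cutoff

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "influence": self.influence,
            "cutoff": self.cutoff,
            "flagged": self.influence > self.cutoff,
        })


def ln_transform(abundances) -> np.ndarray:
    """Elementwise natural log of strictly positive relative abundances."""
    arr = np.asarray(abundances, dtype=float)
    if (arr <= 0).any():
        raise ValueError(
            "ln transform requires strictly positive abundances; restrict "
            "to OTUs present in all samples (e.g. the dominant OTUs) or "
            "filter zero-count samples first")
    return np.log(arr)


def leverage_cutoff(p: int, n: int) -> float:
    """Leverage cutoff 3p/n for flagging influential observations."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < p < n:
        raise ValueError("need n > p > 0")
    return 3.0 * p / n


def detect_outliers(y, X, sample_ids=None, statistic: str = "leverage",
                    column_names=None) -> OutlierReport:
    """OLS of ln(OTU) on the phenotype design; flag high-influence rows.

    ``X`` must include an intercept column.  The default influence measure
    is the hat-matrix diagonal with cutoff 3p/n; ``statistic="cooks"``
    flags on Cook's distance against the same cutoff instead (non-default
    alternative).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples than parameters: n={n}, p={p}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        names = (list(column_names) if column_names is not None
                 else [f"col{i}" for i in range(p)])
        # QR with column pivoting: trailing pivots are the dependent columns
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        bad = sorted(names[i] for i in piv[rank:])
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns: {bad}")
    if sample_ids is None:
        sample_ids = list(range(n))

    model = sm.OLS(y, X).fit()
    infl = OLSInfluence(model)
    if statistic == "leverage":
        values = infl.hat_matrix_diag
    elif statistic == "cooks":
        values = infl.cooks_distance[0]
    else:
        raise ValueError(f"unknown influence statistic {statistic!r}")
    cutoff = leverage_cutoff(p, n)
    series = pd.Series(values, index=sample_ids, name="influence")
    flagged = list(series.index[series > cutoff])
    return OutlierReport(n_params=p, n_samples=n, cutoff=cutoff,
                         influence=series, flagged=flagged)
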