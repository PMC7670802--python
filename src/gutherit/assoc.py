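"""Mixed-model association between host phenotypes and OTU abundances.

Each phenotype is regressed on sampling day and the log abundances of the
dominant OTUs jointly, with random animal (genomic relationship
covariance) and tank effects absorbing the family/tank structure:

    y = X b + Z_a a + Z_t t + e,

where the fixed part X holds intercept, a linear day regression, and one
regression per ln(OTU).  Each regression coefficient is tested with a
Wald F statistic on 1 numerator degree of freedom, the denominator
degrees of freedom taken as n - rank(X).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .datatypes import Grm
from .reml import AnimalModelSpec, VarCompFit, fit_animal_model

__all__ = ["AssocTable", "fit_association", "build_assoc_report"]


@dataclass
class AssocTable:
    """Per-phenotype mixed-model regression results (one row per regressor)."""

    response: str
    table: pd.DataFrame  # variable, estimate, stderr, F, p
    varcomps: dict = field(default_factory=dict)  # name -> (estimate, se)
    fit: VarCompFit | None = None


def _check_collinearity(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        bad = sorted(names[i] for i in piv[rank:])
        raise ValueError(
            f"collinear fixed-effect regressors: {bad}; the model cannot "
            "separate their effects (as happens for confounded tank and "
            "family structure)")


def fit_association(
    response: str,
    data: pd.DataFrame,
    grm: Grm,
    otu_columns: list[str],
    one_at_a_time: bool = False,
) -> AssocTable:
    """Fit the phenotype-on-OTUs mixed model and test each regressor.

    ``data`` must hold columns ``animal``, ``tank``, ``day``, the response
    and the ln(OTU) regressors.  All OTU regressors are fitted jointly by
    default; ``one_at_a_time=True`` fits one model per OTU instead (day
    always included).
    """
    for col in list(otu_columns) + [response]:
        if col not in data.columns:
            raise ValueError(f"data is missing column '{col}'")
        vals = data[col].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError(f"non-finite values in regressor '{col}'")

    def _one_fit(covs: list[str]) -> VarCompFit:
        spec = AnimalModelSpec(response=response, data=data, grm=grm,
                               day_as_factor=False,
                               fixed_covariates=tuple(covs))
        y, X, names, _, _ = spec.build()
        _check_collinearity(X, names)
        return fit_animal_model(spec)

    rows = []
    if one_at_a_time:
        fit = None
        for otu in otu_columns:
            f = _one_fit([otu])
            rows.extend(_wald_rows(f, ["day", otu]))
            fit = f
        # de-duplicate day rows, keep the first
        seen = set()
        rows = [r for r in rows if not (r[0] in seen or seen.add(r[0]))]
    else:
        fit = _one_fit(list(otu_columns))
        rows = _wald_rows(fit, ["day"] + list(otu_columns))

    table = pd.DataFrame(rows, columns=["variable", "estimate", "stderr",
                                        "F", "p"])
    varcomps = {name: (fit.components[name], fit.se[name])
                for name in fit.components}
    return AssocTable(response=response, table=table, varcomps=varcomps,
                      fit=fit)


def _wald_rows(fit: VarCompFit, variables: list[str]):
    """Wald F (1 numerator df) per fixed regressor from the GLS solution."""
    df_den = fit.n - len(fit.fixed_names)
    rows = []
    for var in variables:
        i = fit.fixed_names.index(var)
        b = float(fit.beta[i])
        se = float(fit.beta_se[i])
        F = (b / se) ** 2
        p = float(stats.f.sf(F, 1, df_den))
        rows.append((var, b, se, F, p))
    return rows


def build_assoc_report(fits: list[AssocTable],
                       thresholds: tuple[float, ...] = (0.005, 0.05)) -> pd.DataFrame:
    """Combine per-phenotype fits into one long table.

    One block per dependent variable with a significance column that
    labels each regressor by the smallest threshold its p-value clears
    (e.g. ``"< 0.005"``, ``"< 0.05"``) or ``"NS"``.
    """
    if not fits:
        raise ValueError("no fitted phenotypes to report")
    thresholds = tuple(sorted(thresholds))

    def _mark(p: float) -> str:
        for t in thresholds:
            if p < t:
                return f"< {t:g}"
        return "NS"

    blocks = []
    for fit in fits:
        block = fit.table.copy()
        block.insert(0, "dependent_variable", fit.response)
        block["significance"] = block["p"].map(_mark)
        blocks.append(block)
        vc_rows = [{
            "dependent_variable": fit.response,
            "variable": f"varcomp_{name}",
            "estimate": est,
            "stderr": se,
            "F": np.nan,
            "p": np.nan,
            "significance": "",
        } for name, (est, se) in fit.varcomps.items() if name != "residual"]
        if vc_rows:
            blocks.append(pd.DataFrame(vc_rows))
    return pd.concat(blocks, ignore_index=True)
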