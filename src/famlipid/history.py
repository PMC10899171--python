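"""Family-history odds ratios: parental dyslipidemia and offspring risk.

Exposure is the number of affected parents among parents with known
status; the effect on offspring status is estimated with an age- and
sex-adjusted logistic regression, overall and within sex strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .pedigree import Pedigree

log = logging.getLogger(__name__)

__all__ = ["ORResult", "parental_exposure", "fit_logistic_or"]

EXPOSURE_LEVELS = ("no_affected_parent", "at_least_one", "both")


@dataclass
class ORResult:
    """Odds ratio with 95% Wald confidence interval."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    n: int
    stratum: str = "total"
    trait: str = "dyslipidemia"
    contrast: str = "at_least_one_vs_none"
    p_value: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("confidence bounds must bracket the odds ratio")


def parental_exposure(
    ped: Pedigree,
    statuses: Mapping[str, bool],
) -> pd.DataFrame:
    """Per-offspring parental-exposure categories.

    Parents with unknown status are excluded from the denominator; a person
    whose parents are both absent from the pedigree (or both of unknown
    status) is omitted (logged).  Categories: ``both`` (two known affected
    parents), ``at_least_one`` (>= 1 affected), ``no_affected_parent``.
    """
    rows = []
    n_skipped = 0
    for m in ped.members:
        parent_statuses = [
            statuses[p]
            for p in (m.father_id, m.mother_id)
            if p is not None and p in statuses
        ]
        if not parent_statuses:
            n_skipped += 1
            continue
        n_aff = sum(bool(s) for s in parent_statuses)
        if n_aff == 2:
            cat = "both"
        elif n_aff >= 1:
            cat = "at_least_one"
        else:
            cat = "no_affected_parent"
        rows.append(
            {
                "person_id": m.individual_id,
                "sex": m.sex,
                "n_known_parents": len(parent_statuses),
                "n_affected_parents": n_aff,
                "exposure": cat,
            }
        )
    if n_skipped:
        log.info("parental_exposure: %d persons with no parent of known status omitted", n_skipped)
    return pd.DataFrame(
        rows,
        columns=["person_id", "sex", "n_known_parents", "n_affected_parents", "exposure"],
    )


def fit_logistic_or(
    records: pd.DataFrame,
    contrast: str = "at_least_one_vs_none",
    covariates: tuple[str, ...] = ("age", "sex"),
    stratum: str = "total",
    trait: str = "dyslipidemia",
    tol: float = 1e-8,
    maxiter: int = 100,
) -> ORResult:
    """Covariate-adjusted odds ratio from a maximum-likelihood logit fit.

    ``records`` needs columns ``outcome`` (bool), ``exposure`` (category in
    :data:`EXPOSURE_LEVELS`) and the covariates.  Contrasts:
    ``at_least_one_vs_none`` pools ``both`` with ``at_least_one``;
    ``both_vs_none`` compares ``both`` against the reference only.  The
    reference category is ``no_affected_parent``.  Constant covariate
    columns (e.g. sex within a single-sex stratum) are dropped
    automatically.  95% CI from the observed information (Wald).
    """
    df = records.copy()
    if contrast == "at_least_one_vs_none":
        df["_exp"] = df["exposure"].isin(("at_least_one", "both")).astype(float)
    elif contrast == "both_vs_none":
        df = df[df["exposure"].isin(("both", "no_affected_parent"))]
        df["_exp"] = (df["exposure"] == "both").astype(float)
    else:
        raise ValueError(f"unknown contrast {contrast!r}")

    y = df["outcome"].astype(float).to_numpy()
    for level in (0.0, 1.0):
        sub = y[df["_exp"] == level]
        if len(sub) == 0 or sub.min() == sub.max():
            raise ValueError(
                f"exposure level {level:g} lacks both cases and controls"
            )

    X = pd.DataFrame({"exposure": df["_exp"].to_numpy()})
    for cov in covariates:
        if cov not in df:
            continue
        col = df[cov]
        if col.dtype.kind in "OU" or str(col.dtype) == "category":
            col = (col == "male").astype(float)
        col = col.astype(float)
        if col.nunique() <= 1:
            log.info("fit_logistic_or: dropping constant covariate %r", cov)
            continue
        X[cov] = col.to_numpy()
    X = sm.add_constant(X, has_constant="add")

    try:
        fit = sm.Logit(y, X).fit(disp=0, method="newton", tol=tol, maxiter=maxiter)
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise ValueError(f"logistic fit failed (perfect separation?): {err}") from err
    if not fit.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge")

    beta = fit.params["exposure"]
    se = fit.bse["exposure"]
    if not np.isfinite(se) or se > 50:
        raise ValueError("quasi-separation: exposure standard error is unbounded")
    return ORResult(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        n=int(len(df)),
        stratum=stratum,
        trait=trait,
        contrast=contrast,
        p_value=float(fit.pvalues["exposure"]),
    )
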