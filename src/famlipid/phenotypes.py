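"""Per-phase lipid record processing.

Derived LDL-C (Friedewald), medication adjustment of total cholesterol,
ATP III threshold flags, first-measurement (FM) and average-measurement (AM)
scenario tables, and the age/sex adjustment + rank-based inverse normal
transform applied before correlation and heritability analyses.

All concentrations are mg/dL.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

log = logging.getLogger(__name__)

__all__ = [
    "ATP3_THRESHOLDS",
    "TRAITS",
    "LOG_TRAITS",
    "friedewald_ldl",
    "adjust_tc_for_medication",
    "prepare_measurements",
    "classify_flags",
    "first_measurement",
    "average_measurement",
    "residualize",
    "inverse_normal_transform",
    "scenario_traits",
]

TRAITS = ("tc", "tg", "hdl", "ldl")

#: traits adjusted on the log scale (TC stays on the raw scale)
LOG_TRAITS = ("tg", "hdl", "ldl")

#: ATP III cut-points: high TC >= 200, high TG >= 200, high LDL-C >= 160,
#: low HDL-C < 40 (men) / < 50 (women), all mg/dL.
ATP3_THRESHOLDS = {
    "tc_high": 200.0,
    "tg_high": 200.0,
    "ldl_high": 160.0,
    "hdl_low_male": 40.0,
    "hdl_low_female": 50.0,
}

#: TG bound above which the Friedewald TG/5 approximation is invalid.
FRIEDEWALD_TG_LIMIT = 400.0

#: Measured TC in treated individuals is divided by this factor to undo the
#: average effect of lipid-lowering medication.
TC_MEDICATION_FACTOR = 0.8


def friedewald_ldl(tc, hdl, tg, tg_limit: float = FRIEDEWALD_TG_LIMIT):
    """LDL-C = TC - HDL-C - TG/5, undefined (NaN) for TG >= ``tg_limit``.

    Accepts scalars or arrays; raises on non-positive inputs (missing values
    are allowed and propagate as NaN).
    """
    tc, hdl, tg = (np.asarray(x, dtype=float) for x in (tc, hdl, tg))
    for name, arr in (("tc", tc), ("hdl", hdl), ("tg", tg)):
        if np.any(arr[~np.isnan(arr)] <= 0):
            raise ValueError(f"non-positive {name} value passed to friedewald_ldl")
    ldl = tc - hdl - tg / 5.0
    ldl = np.where(tg >= tg_limit, np.nan, ldl)
    return float(ldl) if ldl.ndim == 0 else ldl


def adjust_tc_for_medication(tc, drug, factor: float = TC_MEDICATION_FACTOR):
    """Divide measured TC by ``factor`` (default 0.8) for treated records."""
    tc = np.asarray(tc, dtype=float)
    if np.any(tc[~np.isnan(tc)] <= 0):
        raise ValueError("non-positive tc value")
    drug = np.asarray(drug, dtype=bool)
    out = np.where(drug, tc / factor, tc)
    return float(out) if out.ndim == 0 else out


def classify_flags(records: pd.DataFrame) -> pd.DataFrame:
    """ATP III flags for a table with columns ``sex, tc, tg, hdl, ldl``.

    Returns a DataFrame (same index) with boolean columns ``high_tc,
    high_tg, low_hdl, high_ldl``.  Missing lipid values yield False for the
    corresponding flag.  The HDL rule is sex-specific.
    """
    if "sex" not in records:
        raise ValueError("records need a 'sex' column for the HDL-C rule")
    sex = records["sex"]
    if records["hdl"].notna().any() and sex.isna().any():
        bad = records.index[sex.isna() & records["hdl"].notna()]
        if len(bad):
            raise ValueError(f"missing sex with hdl present at rows {list(bad)[:5]}")
    hdl_cut = np.where(
        sex == "male",
        ATP3_THRESHOLDS["hdl_low_male"],
        ATP3_THRESHOLDS["hdl_low_female"],
    )
    out = pd.DataFrame(index=records.index)
    out["high_tc"] = records["tc"].to_numpy(dtype=float) >= ATP3_THRESHOLDS["tc_high"]
    out["high_tg"] = records["tg"].to_numpy(dtype=float) >= ATP3_THRESHOLDS["tg_high"]
    out["low_hdl"] = records["hdl"].to_numpy(dtype=float) < hdl_cut
    out["high_ldl"] = records["ldl"].to_numpy(dtype=float) >= ATP3_THRESHOLDS["ldl_high"]
    return out


def _eligible(phases: pd.DataFrame, min_age: float) -> pd.DataFrame:
    return phases[phases["age"] >= min_age]


def first_measurement(phases: pd.DataFrame, min_age: float = 18.0) -> pd.DataFrame:
    """First-measurement (FM) scenario: the earliest phase at age >= 18.

    ``phases`` has one row per person per phase with columns
    ``person_id, phase, age, sex`` and the trait columns.  Persons never
    reaching ``min_age`` are dropped (logged).  Returns one row per person
    with a ``scenario`` column set to ``"FM"``.
    """
    elig = _eligible(phases, min_age)
    dropped = set(phases["person_id"]) - set(elig["person_id"])
    if dropped:
        log.info("first_measurement: dropped %d persons under age %.0f", len(dropped), min_age)
    fm = (
        elig.sort_values(["person_id", "phase"])
        .groupby("person_id", as_index=False)
        .first()
    )
    fm = fm.copy()
    fm["scenario"] = "FM"
    return fm


def average_measurement(phases: pd.DataFrame, min_age: float = 18.0) -> pd.DataFrame:
    """Average-measurement (AM) scenario: per-trait means over eligible phases.

    The mean is taken over non-missing eligible (age >= 18) phases per trait,
    so per-trait sample sizes differ; they are reported as ``n_<trait>``
    columns.  Age is averaged over eligible phases; sex is constant per
    person.
    """
    elig = _eligible(phases, min_age)
    if elig.empty:
        return pd.DataFrame(
            columns=["person_id", "age", "sex", *TRAITS, "scenario"]
        )
    trait_cols = [t for t in TRAITS if t in elig.columns]
    g = elig.groupby("person_id")
    am = g.agg(
        age=("age", "mean"),
        sex=("sex", "first"),
        **{t: (t, "mean") for t in trait_cols},
        **{f"n_{t}": (t, "count") for t in trait_cols},
    ).reset_index()
    am["scenario"] = "AM"
    return am


def residualize(
    values,
    age,
    sex,
    log_scale: bool = False,
) -> np.ndarray:
    """Residuals of (log-)trait regressed on intercept, age and sex.

    ``sex`` may be the strings male/female or a numeric indicator.  Constant
    (collinear) covariate columns are dropped with a warning — e.g. a
    single-sex stratum.  Missing trait values propagate as NaN.
    """
    y = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if sex.dtype.kind in "OU":
        sex = (sex == "male").astype(float)
    else:
        sex = sex.astype(float)
    if log_scale:
        if np.any(y[~np.isnan(y)] <= 0):
            raise ValueError("log_scale requires positive trait values")
        y = np.log(y)
    X_cols = [np.ones_like(age)]
    for name, col in (("age", age), ("sex", sex)):
        if np.nanstd(col) == 0:
            warnings.warn(f"residualize: dropping constant covariate {name!r}")
            continue
        X_cols.append(col)
    X = np.column_stack(X_cols)
    ok = ~np.isnan(y) & np.all(~np.isnan(X), axis=1)
    resid = np.full(y.shape, np.nan)
    beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
    resid[ok] = y[ok] - X[ok] @ beta
    return resid


def inverse_normal_transform(values, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse normal (Blom) scores.

    ``score_i = Phi^-1((rank_i - offset) / (n - 2*offset + 1))`` with
    midranks for ties and ``offset = 3/8`` by default.  Missing values are
    ignored for ranking and returned as NaN.  Raises if all finite values are
    identical (degenerate ranks).
    """
    y = np.asarray(values, dtype=float)
    ok = ~np.isnan(y)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("inverse_normal_transform needs at least 2 finite values")
    finite = y[ok]
    if np.all(finite == finite[0]):
        raise ValueError("all values identical; ranks are degenerate")
    ranks = rankdata(finite, method="average")
    scores = ndtri((ranks - offset) / (n - 2.0 * offset + 1.0))
    out = np.full(y.shape, np.nan)
    out[ok] = scores
    return out


def prepare_measurements(
    phases: pd.DataFrame,
    adjust_tc: bool = True,
    derive_ldl: bool = True,
    adjust_before_ldl: bool = True,
) -> pd.DataFrame:
    """Medication-adjust TC and fill missing LDL via Friedewald.

    ``adjust_before_ldl`` controls whether the derived LDL uses the
    medication-adjusted TC (the default) or the measured one.
    """
    out = phases.copy()
    drug = out.get("drug")
    drug = drug.fillna(False).astype(bool) if drug is not None else False
    tc_adj = adjust_tc_for_medication(out["tc"], drug) if adjust_tc else out["tc"].to_numpy()
    if derive_ldl:
        tc_for_ldl = tc_adj if (adjust_tc and adjust_before_ldl) else out["tc"].to_numpy()
        derived = friedewald_ldl(tc_for_ldl, out["hdl"], out["tg"])
        derived = np.where(derived <= 0, np.nan, derived)  # implausible profile
        if "ldl" in out:
            out["ldl"] = out["ldl"].fillna(pd.Series(derived, index=out.index))
        else:
            out["ldl"] = derived
    if adjust_tc:
        out["tc"] = tc_adj
    return out


def scenario_traits(
    phases: pd.DataFrame,
    scenario: str,
    min_age: float = 18.0,
    transform: bool = True,
) -> pd.DataFrame:
    """FM or AM per-person trait table, age/sex-adjusted and normal-scored.

    Builds the scenario table, then (when ``transform``) residualizes each
    trait on age and sex — on the log scale for TG/HDL-C/LDL-C — and maps
    residuals to normal scores with the rank-based inverse normal transform.
    Returns one row per person: ``person_id, age, sex`` plus a column per
    trait.
    """
    scenario = scenario.upper()
    if scenario == "FM":
        tab = first_measurement(phases, min_age=min_age)
    elif scenario == "AM":
        tab = average_measurement(phases, min_age=min_age)
    else:
        raise ValueError("scenario must be 'FM' or 'AM'")
    out = tab[["person_id", "age", "sex"]].copy()
    for t in TRAITS:
        if t not in tab:
            continue
        if not transform:
            out[t] = tab[t].to_numpy()
            continue
        resid = residualize(
            tab[t].to_numpy(),
            tab["age"].to_numpy(),
            tab["sex"].to_numpy(),
            log_scale=t in LOG_TRAITS,
        )
        out[t] = inverse_normal_transform(resid)
    out["scenario"] = scenario
    return out
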