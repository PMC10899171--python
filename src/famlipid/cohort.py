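"""Inclusion/exclusion filtering, longitudinal dyslipidemia status, prevalence.

Dyslipidemia is defined longitudinally: a person is dyslipidemic if they
ever report lipid-lowering medication, or if at least one ATP III flag is
positive in at least two observed phases.  Point prevalence is taken at a
baseline phase; periodic prevalence adds incident cases from later phases
over all ever-observed persons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenotypes import TRAITS, classify_flags

log = logging.getLogger(__name__)

__all__ = [
    "ExclusionConfig",
    "apply_exclusions",
    "dyslipidemia_status",
    "status_at_phase",
    "baseline_status",
    "point_prevalence",
    "periodic_prevalence",
    "prevalence_report",
]

EXCLUSION_REASONS = (
    "under18",
    "extreme_lipids",
    "fh_screen",
    "under40_drug",
    "over40_drug_or_cvd",
)


@dataclass
class ExclusionConfig:
    """Tunable exclusion rules.

    extreme lipids: robust z-score (median/MAD on the log scale) above
    ``robust_z_max`` in any phase, or per-trait absolute bounds when given.
    FH screen: a simplified familial-hypercholesterolemia filter — TC or
    LDL above the screening bounds, and (when a family flag is available)
    a first-degree relative exceeding them as well.
    """

    min_age: float = 18.0
    robust_z_max: float = 5.0
    absolute_bounds: dict[str, tuple[float, float]] | None = None
    fh_tc: float = 290.0
    fh_ldl: float = 190.0
    fh_requires_family: bool = True
    drug_age_cut: float = 40.0
    apply_fh_screen: bool = True


def _robust_z(x: np.ndarray) -> np.ndarray:
    logx = np.log(np.where(x > 0, x, np.nan))
    med = np.nanmedian(logx)
    mad = np.nanmedian(np.abs(logx - med))
    scale = 1.4826 * mad
    if not np.isfinite(scale) or scale == 0:
        return np.zeros_like(logx)
    return (logx - med) / scale


def apply_exclusions(
    phases: pd.DataFrame,
    config: ExclusionConfig | None = None,
    family_ids: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-person eligibility report.

    ``phases``: one row per person-phase with columns ``person_id, phase,
    age, sex, tc, tg, hdl, ldl, drug, cvd``.  ``family_ids`` (optional,
    indexed by person_id) enables the family-history arm of the FH screen.

    Returns a DataFrame ``person_id, included, reasons`` where ``reasons``
    is a sorted ';'-joined string of triggered exclusion codes (empty when
    included).
    """
    cfg = config or ExclusionConfig()
    reasons: dict[str, set[str]] = {p: set() for p in phases["person_id"].unique()}

    max_age = phases.groupby("person_id")["age"].max()
    for p in max_age.index[max_age < cfg.min_age]:
        reasons[p].add("under18")

    # extreme lipids: per-trait robust z on the log scale, pooled over phases
    for t in TRAITS:
        if t not in phases:
            continue
        x = phases[t].to_numpy(dtype=float)
        if cfg.absolute_bounds and t in cfg.absolute_bounds:
            lo, hi = cfg.absolute_bounds[t]
            bad = (x < lo) | (x > hi)
        else:
            bad = np.abs(_robust_z(x)) > cfg.robust_z_max
        for p in phases.loc[np.nan_to_num(bad, nan=0).astype(bool), "person_id"].unique():
            reasons[p].add("extreme_lipids")

    if cfg.apply_fh_screen:
        hit = (phases.get("tc", np.nan) > cfg.fh_tc) | (
            phases.get("ldl", np.nan) > cfg.fh_ldl
        )
        flagged = set(phases.loc[hit.fillna(False), "person_id"].unique())
        if cfg.fh_requires_family and family_ids is not None:
            fam_of = family_ids.to_dict()
            fams_flagged: dict[str, int] = {}
            for p in flagged:
                fam = fam_of.get(p)
                if fam is not None:
                    fams_flagged[fam] = fams_flagged.get(fam, 0) + 1
            for p in flagged:
                fam = fam_of.get(p)
                if fam is not None and fams_flagged.get(fam, 0) >= 2:
                    reasons[p].add("fh_screen")
        elif not cfg.fh_requires_family:
            for p in flagged:
                reasons[p].add("fh_screen")
        # with fh_requires_family and no family info the screen is inert

    drug = phases.get("drug")
    cvd = phases.get("cvd")
    if drug is not None:
        young_drug = (phases["age"] < cfg.drug_age_cut) & drug.fillna(False).astype(bool)
        for p in phases.loc[young_drug, "person_id"].unique():
            reasons[p].add("under40_drug")
        older = phases["age"] >= cfg.drug_age_cut
        risk = drug.fillna(False).astype(bool)
        if cvd is not None:
            risk = risk | cvd.fillna(False).astype(bool)
        for p in phases.loc[older & risk, "person_id"].unique():
            reasons[p].add("over40_drug_or_cvd")

    rows = []
    for p, rs in reasons.items():
        if rs:
            log.info("excluded %s: %s", p, ",".join(sorted(rs)))
        rows.append(
            {"person_id": p, "included": not rs, "reasons": ";".join(sorted(rs))}
        )
    return pd.DataFrame(rows, columns=["person_id", "included", "reasons"])


def dyslipidemia_status(phases: pd.DataFrame, strict_age_drug: bool = False) -> pd.DataFrame:
    """Longitudinal dyslipidemia classification.

    A person is dyslipidemic if they have a positive lipid-lowering drug
    history in any phase, or at least one ATP III flag in at least two
    phases.  ``strict_age_drug`` additionally requires age > 40 for the
    drug-history basis.  ``first_positive_phase`` is the first drug-positive
    phase, or the second flag-positive phase for the threshold basis.

    Returns ``person_id, status, first_positive_phase, basis``.
    """
    if phases.empty:
        raise ValueError("no phase records supplied")
    flags = classify_flags(phases)
    any_flag = flags.any(axis=1).to_numpy()
    df = phases[["person_id", "phase"]].copy()
    df["any_flag"] = any_flag
    drug = phases.get("drug")
    df["drug"] = (
        drug.fillna(False).astype(bool).to_numpy() if drug is not None else False
    )
    if strict_age_drug:
        df["drug"] = df["drug"] & (phases["age"].to_numpy(dtype=float) > 40.0)

    rows = []
    for pid, sub in df.sort_values("phase").groupby("person_id"):
        drug_phases = sub.loc[sub["drug"], "phase"]
        flag_phases = sub.loc[sub["any_flag"], "phase"]
        if len(drug_phases):
            rows.append(
                {
                    "person_id": pid,
                    "status": True,
                    "first_positive_phase": int(drug_phases.iloc[0]),
                    "basis": "drug_history",
                }
            )
        elif len(flag_phases) >= 2:
            rows.append(
                {
                    "person_id": pid,
                    "status": True,
                    "first_positive_phase": int(flag_phases.iloc[1]),
                    "basis": "threshold_two_phases",
                }
            )
        else:
            rows.append(
                {
                    "person_id": pid,
                    "status": False,
                    "first_positive_phase": pd.NA,
                    "basis": pd.NA,
                }
            )
    return pd.DataFrame(rows, columns=["person_id", "status", "first_positive_phase", "basis"])


def status_at_phase(statuses: pd.DataFrame, phase: int) -> pd.Series:
    """Boolean status per person as of ``phase`` (first_positive_phase <= phase)."""
    fp = pd.to_numeric(statuses["first_positive_phase"], errors="coerce")
    out = statuses["status"].to_numpy(dtype=bool) & (fp.to_numpy() <= phase)
    return pd.Series(out, index=statuses["person_id"].to_numpy(), name=f"status_p{phase}")


def baseline_status(phases: pd.DataFrame, baseline_phase: int) -> pd.Series:
    """Cross-sectional dyslipidemia at the baseline phase.

    Positive when at least one ATP III flag is raised at that phase, or a
    lipid-lowering drug history is reported by then.  (The two-phase
    longitudinal rule cannot apply at the first observed phase, so point
    prevalence uses this single-phase definition.)
    """
    at_base = phases[phases["phase"] == baseline_phase]
    if at_base.empty:
        raise ValueError(f"no persons observed at baseline phase {baseline_phase}")
    flags = classify_flags(at_base).any(axis=1).to_numpy()
    drug = phases.get("drug")
    if drug is not None:
        drug_by = (
            phases[phases["phase"] <= baseline_phase]
            .groupby("person_id")["drug"]
            .any()
        )
        drug_flag = (
            drug_by.reindex(at_base["person_id"]).fillna(False).to_numpy(dtype=bool)
        )
    else:
        drug_flag = np.zeros(len(at_base), dtype=bool)
    return pd.Series(
        flags | drug_flag, index=at_base["person_id"].to_numpy(), name="baseline_status"
    )


def point_prevalence(baseline: pd.Series) -> float:
    """Proportion positive at baseline among persons observed at baseline."""
    if len(baseline) == 0:
        raise ValueError("empty baseline population")
    return float(np.mean(baseline.to_numpy(dtype=bool)))


def periodic_prevalence(
    statuses: pd.DataFrame,
    phases: pd.DataFrame,
    baseline: pd.Series | None = None,
) -> float:
    """Baseline positives plus incident (longitudinal-rule) cases in later
    phases, over all ever-observed persons; each person counted once."""
    ever = pd.Index(phases["person_id"].unique())
    pos = set(statuses.loc[statuses["status"].astype(bool), "person_id"])
    if baseline is not None:
        pos |= set(baseline.index[baseline.to_numpy(dtype=bool)])
    return float(len(pos & set(ever)) / len(ever))


def prevalence_report(
    phases: pd.DataFrame,
    baseline_phase: int | None = None,
    statuses: pd.DataFrame | None = None,
) -> dict:
    """JSON-ready summary: point and periodic prevalence plus denominators."""
    if baseline_phase is None:
        baseline_phase = int(phases["phase"].min())
    if statuses is None:
        statuses = dyslipidemia_status(phases)
    base = baseline_status(phases, baseline_phase)
    return {
        "point": point_prevalence(base),
        "periodic": periodic_prevalence(statuses, phases, base),
        "n": int(phases["person_id"].nunique()),
        "baseline_phase": baseline_phase,
        "denominator": "ever_observed",
    }
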