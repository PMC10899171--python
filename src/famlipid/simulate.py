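"""Synthetic family cohort generator with known ground truth.

Generates pedigrees (nuclear or multi-generation families, optionally with
first-cousin marriages), longitudinal lipid phenotypes with an additive
genetic + household + permanent-environment + phase-error variance
decomposition, and binary dyslipidemia from a liability-threshold model.
Because every variance share is planted, each downstream estimator can be
validated against the truth that produced its input.

Default trait means/SDs by sex emulate an adult Iranian urban cohort (TC
~194/183 mg/dL in men/women, TG right-skewed and simulated log-normal);
ages advance 3 years per phase across five phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .heritability import BlockEigh
from .pedigree import IndividualRecord, KinshipMatrix, Pedigree, kinship_matrix, relationship_matrix

__all__ = [
    "TraitParams",
    "SimulationConfig",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_longitudinal_lipids",
    "simulate_disease_status",
    "simulate_cohort",
]


@dataclass(frozen=True)
class TraitParams:
    """Per-trait generator settings (mg/dL on the raw scale).

    ``log=True`` simulates the trait log-normally (moment-matched to the
    requested mean/SD); ``age_slope`` acts on the modeling scale per year,
    centered at age 38.
    """

    mean_male: float
    sd_male: float
    mean_female: float
    sd_female: float
    log: bool
    age_slope: float


#: lower bound for raw-scale (non-log-normal) simulated concentrations, mg/dL
_RAW_FLOOR = 40.0

#: cohort-like defaults: male/female means (SDs) for TC, TG, HDL-C, LDL-C
DEFAULT_TRAITS: dict[str, TraitParams] = {
    "tc": TraitParams(194.43, 45.6, 182.56, 80.3, log=False, age_slope=0.4),
    "tg": TraitParams(169.86, 122.97, 132.68, 109.5, log=True, age_slope=0.004),
    "hdl": TraitParams(38.8, 9.66, 40.11, 19.3, log=True, age_slope=0.0),
    "ldl": TraitParams(133.32, 39.37, 106.16, 57.24, log=True, age_slope=0.003),
}


@dataclass
class SimulationConfig:
    """Full parameter set for the synthetic cohort.

    Variance shares (per trait, on the modeling scale): ``h2_true`` additive
    genetic, ``household_share`` shared within nuclear family,
    ``phase_error_share`` independent per phase; the remainder is a
    person-level permanent environment.  Shares must sum to <= 1.
    """

    n_families: int = 500
    sibship: tuple[int, int] = (2, 4)
    generations: int = 1
    consanguinity_rate: float = 0.0
    p_marry: float = 0.5
    phases: int = 5
    first_phase: int = 2
    phase_years: float = 3.0
    traits: dict[str, TraitParams] = field(default_factory=lambda: dict(DEFAULT_TRAITS))
    h2_true: float = 0.42
    household_share: float = 0.10
    phase_error_share: float = 0.20
    drug_rate: float = 0.03
    cvd_rate: float = 0.02
    missingness: float = 0.05
    liability_h2: float = 0.41
    disease_prevalence: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h2_true + self.household_share + self.phase_error_share > 1.0 + 1e-12:
            raise ValueError("variance shares must sum to <= 1")
        for name, rate in (
            ("consanguinity_rate", self.consanguinity_rate),
            ("missingness", self.missingness),
            ("disease_prevalence", self.disease_prevalence),
            ("liability_h2", self.liability_h2),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _draw_sibship(sibship, rng) -> int:
    if isinstance(sibship, (tuple, list)) and len(sibship) == 2 and all(
        isinstance(v, (int, np.integer)) for v in sibship
    ):
        lo, hi = sibship
        return int(rng.integers(lo, hi + 1))
    probs = np.asarray(sibship, dtype=float)
    probs = probs / probs.sum()
    return int(rng.choice(np.arange(1, len(probs) + 1), p=probs))


class _FamilyBuilder:
    def __init__(self, family_id: str):
        self.family_id = family_id
        self.records: list[IndividualRecord] = []
        self._n = 0

    def person(self, sex: str, father: str | None = None, mother: str | None = None) -> str:
        self._n += 1
        iid = f"{self.family_id}-{self._n}"
        self.records.append(
            IndividualRecord(self.family_id, iid, father, mother, sex)
        )
        return iid

    def couple(self) -> tuple[str, str]:
        return self.person("male"), self.person("female")

    def children(self, father: str, mother: str, n: int, rng) -> list[str]:
        sexes = rng.choice(["male", "female"], size=n)
        return [self.person(s, father, mother) for s in sexes]


def _plain_family(fb: _FamilyBuilder, cfg: SimulationConfig, rng) -> None:
    dad, mom = fb.couple()
    kids = fb.children(dad, mom, _draw_sibship(cfg.sibship, rng), rng)
    if cfg.generations >= 2:
        for kid in kids:
            if rng.random() >= cfg.p_marry:
                continue
            kid_sex = next(r.sex for r in fb.records if r.individual_id == kid)
            spouse = fb.person("female" if kid_sex == "male" else "male")
            f, m = (kid, spouse) if kid_sex == "male" else (spouse, kid)
            fb.children(f, m, _draw_sibship(cfg.sibship, rng), rng)


def _cousin_marriage_family(fb: _FamilyBuilder, cfg: SimulationConfig, rng) -> None:
    """Three-generation family with two first-cousin marriages.

    Grandparents -> two sibs, each married to an outside founder, each with
    a boy and a girl; the cross-branch cousin pairs marry and reproduce.
    Marriages per family: 5, of which 2 are consanguineous.
    """
    gf, gm = fb.couple()
    s1 = fb.person("male", gf, gm)
    s2 = fb.person("female", gf, gm)
    w1 = fb.person("female")
    h2_ = fb.person("male")
    b1 = fb.person("male", s1, w1)
    g1 = fb.person("female", s1, w1)
    b2 = fb.person("male", h2_, s2)
    g2 = fb.person("female", h2_, s2)
    for f, m in ((b1, g2), (b2, g1)):
        fb.children(f, m, _draw_sibship(cfg.sibship, rng), rng)


#: marriages and consanguineous marriages in the cousin-marriage template
_COUSIN_TEMPLATE_MARRIAGES = 5
_COUSIN_TEMPLATE_CONSANG = 2


def simulate_pedigree(cfg: SimulationConfig, seed=None) -> Pedigree:
    """Simulate ``cfg.n_families`` independent families (seeded, deterministic).

    With ``consanguinity_rate`` c > 0, families are a Bernoulli(q) mixture
    of a three-generation cousin-marriage template (2 of its 5 marriages
    consanguineous) and plain nuclear families (1 marriage), with q solved
    so that the expected fraction of all spouse pairs with kinship > 0
    equals c; this requires c < 0.4 and ``generations == 1`` for the plain
    component.
    """
    rng = _rng(cfg.seed if seed is None else seed)
    c = cfg.consanguinity_rate
    q = 0.0
    if c > 0:
        if cfg.generations != 1:
            raise ValueError("consanguinity_rate > 0 requires generations == 1")
        denom = _COUSIN_TEMPLATE_CONSANG - c * (_COUSIN_TEMPLATE_MARRIAGES - 1)
        if denom <= 0 or c / denom > 1:
            raise ValueError("consanguinity_rate not attainable (must be < 0.4)")
        q = c / denom
    records: list[IndividualRecord] = []
    for f in range(cfg.n_families):
        fb = _FamilyBuilder(f"F{f + 1}")
        if q > 0 and rng.random() < q:
            _cousin_marriage_family(fb, cfg, rng)
        else:
            _plain_family(fb, cfg, rng)
        records.extend(fb.records)
    return Pedigree(records)


def simulate_breeding_values(
    A=None,
    sigma_g2: float = 1.0,
    seed=None,
    eig: BlockEigh | None = None,
) -> np.ndarray:
    """Draw g ~ N(0, A * sigma_g2) through a per-family factorization of A."""
    rng = _rng(seed)
    if eig is None:
        eig = BlockEigh(np.asarray(A, dtype=float))
    if sigma_g2 < 0:
        raise ValueError("sigma_g2 must be >= 0")
    z = rng.standard_normal(eig.n)
    return np.sqrt(sigma_g2) * eig.sqrt_apply(z)


def _generations_of(ped: Pedigree) -> dict[str, int]:
    """Generation depth per member; married-in founders inherit their
    spouse's depth so ages line up within couples."""
    gen: dict[str, int] = {}
    for iid in ped.topological_order():
        f, m = ped.parents(iid)
        parents = [p for p in (f, m) if p is not None]
        gen[iid] = max((gen[p] for p in parents), default=0) + (1 if parents else 0)
    for member in ped.members:
        f, m = member.father_id, member.mother_id
        if f is not None and m is not None:
            lift = max(gen[f], gen[m])
            gen[f] = gen[m] = lift
    return gen


def _base_ages(ped: Pedigree, rng, gap: float = 26.0) -> pd.Series:
    gen = _generations_of(ped)
    fam_max = {}
    for m in ped.members:
        fam_max[m.family_id] = max(fam_max.get(m.family_id, 0), gen[m.individual_id])
    ages = {}
    for m in ped.members:
        depth_up = fam_max[m.family_id] - gen[m.individual_id]
        ages[m.individual_id] = max(
            1.0, rng.normal(28.0 + gap * depth_up, 5.0)
        )
    return pd.Series(ages)


def simulate_longitudinal_lipids(
    ped: Pedigree,
    cfg: SimulationConfig,
    seed=None,
    kinship: KinshipMatrix | None = None,
) -> pd.DataFrame:
    """Longitudinal phase records for every pedigree member.

    Per trait and modeling scale (log for log-normal traits):
    ``value = sex mean + age_slope * (age - 38) + g + household + permanent
    env + phase error`` with the variance shares from ``cfg``.  Ages advance
    ``phase_years`` per phase; drug use and CVD flags are assigned at
    person level; missingness masks trait cells independently.
    """
    rng = _rng(cfg.seed + 1 if seed is None else seed)
    kin = kinship or kinship_matrix(ped)
    eig = BlockEigh(relationship_matrix(kin))
    ids = kin.ids
    n = len(ids)
    sex = np.array([ped.record(i).sex for i in ids])
    is_male = sex == "male"
    # round once so per-phase ages advance by exactly phase_years
    base_age = np.round(_base_ages(ped, rng).reindex(ids).to_numpy(), 1)

    fam = np.array([ped.record(i).family_id for i in ids])
    fam_codes, fam_idx = np.unique(fam, return_inverse=True)

    pe_share = 1.0 - cfg.h2_true - cfg.household_share - cfg.phase_error_share

    trait_values: dict[str, np.ndarray] = {}  # (n, phases) raw scale
    for name, tp in cfg.traits.items():
        if tp.log:
            mu_m, v_m = _lognormal_params(tp.mean_male, tp.sd_male)
            mu_f, v_f = _lognormal_params(tp.mean_female, tp.sd_female)
        else:
            mu_m, v_m = tp.mean_male, tp.sd_male**2
            mu_f, v_f = tp.mean_female, tp.sd_female**2
        total_var = 0.5 * (v_m + v_f)
        g = simulate_breeding_values(eig=eig, sigma_g2=cfg.h2_true * total_var, seed=rng)
        house = rng.normal(0.0, np.sqrt(cfg.household_share * total_var), len(fam_codes))[fam_idx]
        pe = rng.normal(0.0, np.sqrt(pe_share * total_var), n)
        mu = np.where(is_male, mu_m, mu_f)
        vals = np.empty((n, cfg.phases))
        for p in range(cfg.phases):
            age_p = base_age + cfg.phase_years * p
            eps = rng.normal(0.0, np.sqrt(cfg.phase_error_share * total_var), n)
            v = mu + tp.age_slope * (age_p - 38.0) + g + house + pe + eps
            # raw-scale traits get a physiological floor; the wide cohort SDs
            # would otherwise allow non-positive concentrations
            vals[:, p] = np.exp(v) if tp.log else np.clip(v, _RAW_FLOOR, None)
        trait_values[name] = vals

    drug_person = rng.random(n) < cfg.drug_rate
    drug_onset = rng.integers(0, cfg.phases, n)
    final_age = base_age + cfg.phase_years * (cfg.phases - 1)
    cvd_person = (rng.random(n) < cfg.cvd_rate) & (final_age > 40)

    rows = []
    for p in range(cfg.phases):
        phase_no = cfg.first_phase + p
        age_p = base_age + cfg.phase_years * p
        rec = pd.DataFrame(
            {
                "person_id": ids,
                "phase": phase_no,
                "age": age_p,
                "sex": sex,
                "drug": drug_person & (drug_onset <= p),
                "cvd": cvd_person,
            }
        )
        for name, vals in trait_values.items():
            col = vals[:, p].copy()
            if cfg.missingness > 0:
                col[rng.random(n) < cfg.missingness] = np.nan
            rec[name] = np.round(col, 2)
        rows.append(rec)
    out = pd.concat(rows, ignore_index=True)
    cols = ["person_id", "phase", "age", "sex", "tc", "tg", "hdl", "ldl", "drug", "cvd"]
    return out[[c for c in cols if c in out.columns]]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma^2) on the log scale matching the raw-scale mean and SD."""
    v = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * v
    return float(mu), float(v)


def simulate_disease_status(
    ped: Pedigree,
    liability_h2: float,
    prevalence: float,
    seed=None,
    eig: BlockEigh | None = None,
) -> pd.Series:
    """Liability-threshold disease: liability = genetic + residual with
    variances (h2, 1 - h2); affected when liability exceeds
    Phi^-1(1 - prevalence)."""
    if not 0.0 <= liability_h2 <= 1.0:
        raise ValueError("liability_h2 must lie in [0, 1]")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    rng = _rng(seed)
    if eig is None:
        eig = BlockEigh(relationship_matrix(kinship_matrix(ped)))
    g = simulate_breeding_values(eig=eig, sigma_g2=liability_h2, seed=rng)
    e = rng.normal(0.0, np.sqrt(1.0 - liability_h2), eig.n)
    threshold = ndtri(1.0 - prevalence)
    return pd.Series(g + e > threshold, index=ped.ids, name="status")


def simulate_cohort(cfg: SimulationConfig):
    """Pedigree + longitudinal phenotypes + true disease statuses, all from
    ``cfg.seed`` (child seeds per stage, so stages are independently
    reproducible)."""
    root = np.random.SeedSequence(cfg.seed)
    s_ped, s_pheno, s_dis = root.spawn(3)
    ped = simulate_pedigree(cfg, seed=np.random.default_rng(s_ped))
    phases = simulate_longitudinal_lipids(ped, cfg, seed=np.random.default_rng(s_pheno))
    status = simulate_disease_status(
        ped,
        cfg.liability_h2,
        cfg.disease_prevalence,
        seed=np.random.default_rng(s_dis),
    )
    return ped, phases, status
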