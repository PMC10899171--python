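"""Familial intraclass/interclass correlations by relative-pair type.

Exchangeable pair types (same-sex siblings, spouses, cousins, half-sibs)
use the double-entry product-moment estimator: each pair contributes
(x, y) and (y, x), which equals the one-way random-effects ANOVA ICC on
balanced pairs.  Ordered types (parent-offspring by sex, grandparental,
avuncular) use the plain interclass (Pearson) correlation with the senior
member in the first slot.  Confidence intervals come from a cluster
bootstrap over families, since pairs within a family are not independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ICCEstimate", "EXCHANGEABLE_CATEGORIES", "build_pair_values", "icc", "binary_icc"]

#: categories whose two slots are interchangeable (double-entered)
EXCHANGEABLE_CATEGORIES = frozenset({"sibling", "spouse", "cousin", "half_sibling"})


@dataclass
class ICCEstimate:
    icc: float
    ci_low: float
    ci_high: float
    n_pairs: int
    pair_type: str = ""
    trait: str = ""
    scenario: str = ""

    @property
    def significant(self) -> bool:
        """Bootstrap CI excludes zero."""
        return self.ci_low > 0 or self.ci_high < 0


def build_pair_values(
    pairs: pd.DataFrame,
    traits: pd.Series,
) -> pd.DataFrame:
    """Attach trait values to a typed pair table.

    ``pairs`` is the output of :func:`famlipid.pedigree.enumerate_pairs`
    (columns ``id_a, id_b, family_id, category, sex_label``); ``traits`` is
    indexed by person id.  Pairs with a missing value in either slot are
    dropped.  Adds ``x`` (value of ``id_a`` — the senior member for ordered
    types), ``y``, and an ``exchangeable`` flag.
    """
    out = pairs.copy()
    out["x"] = out["id_a"].map(traits)
    out["y"] = out["id_b"].map(traits)
    out = out.dropna(subset=["x", "y"]).reset_index(drop=True)
    out["exchangeable"] = out["category"].isin(EXCHANGEABLE_CATEGORIES)
    return out


def _corr_from_moments(n, sx, sy, sxx, syy, sxy):
    mx, my = sx / n, sy / n
    vx = sxx / n - mx**2
    vy = syy / n - my**2
    cov = sxy / n - mx * my
    denom = np.sqrt(vx * vy)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, cov / denom, np.nan)


def _family_moments(x, y, families, exchangeable):
    """Per-family sufficient statistics for the (double-entry) correlation."""
    df = pd.DataFrame({"f": families, "x": x, "y": y})
    if exchangeable:
        g = df.groupby("f")
        stats = pd.DataFrame(
            {
                "n": 2.0 * g.size(),
                "sx": g["x"].sum() + g["y"].sum(),
                "sxx": (g["x"].apply(lambda s: (s**2).sum()) + g["y"].apply(lambda s: (s**2).sum())),
                "sxy": 2.0 * g.apply(lambda s: (s["x"] * s["y"]).sum(), include_groups=False),
            }
        )
        stats["sy"] = stats["sx"]
        stats["syy"] = stats["sxx"]
    else:
        g = df.groupby("f")
        stats = pd.DataFrame(
            {
                "n": g.size().astype(float),
                "sx": g["x"].sum(),
                "sy": g["y"].sum(),
                "sxx": g["x"].apply(lambda s: (s**2).sum()),
                "syy": g["y"].apply(lambda s: (s**2).sum()),
                "sxy": g.apply(lambda s: (s["x"] * s["y"]).sum(), include_groups=False),
            }
        )
    return stats[["n", "sx", "sy", "sxx", "syy", "sxy"]].to_numpy()


def icc(
    x,
    y,
    families=None,
    exchangeable: bool = True,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = 0,
    pair_type: str = "",
    trait: str = "",
    scenario: str = "",
) -> ICCEstimate:
    """Intraclass (double-entry) or interclass correlation with a
    family-cluster bootstrap CI.

    ``families`` assigns each pair to a cluster; when omitted every pair is
    its own cluster (plain pair bootstrap).  Requires >= 2 pairs and
    non-degenerate variance in both slots.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n_pairs = len(x)
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs for a correlation")
    if exchangeable:
        pooled = np.concatenate([x, y])
        if np.ptp(pooled) == 0:
            raise ValueError("zero variance in pair values")
    else:
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("zero variance in one pair slot")
    if families is None:
        families = np.arange(n_pairs)
    families = np.asarray(families)

    moments = _family_moments(x, y, families, exchangeable)
    totals = moments.sum(axis=0)
    point = float(_corr_from_moments(*totals))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_fam = moments.shape[0]
    counts = rng.multinomial(n_fam, np.full(n_fam, 1.0 / n_fam), size=n_boot)
    boot_tot = counts @ moments  # (n_boot, 6)
    boots = _corr_from_moments(*(boot_tot[:, i] for i in range(6)))
    boots = boots[np.isfinite(boots)]
    if len(boots):
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = point
    return ICCEstimate(
        icc=point,
        ci_low=float(min(lo, point)),
        ci_high=float(max(hi, point)),
        n_pairs=n_pairs,
        pair_type=pair_type,
        trait=trait,
        scenario=scenario,
    )


def binary_icc(
    x,
    y,
    families=None,
    exchangeable: bool = True,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = 0,
    **labels,
) -> ICCEstimate:
    """Observed-scale correlation of 0/1 statuses (phi-type) using the same
    double-entry/interclass machinery as :func:`icc`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vals = set(np.unique(np.concatenate([x, y])))
    if not vals <= {0.0, 1.0}:
        raise ValueError("binary_icc expects 0/1 statuses")
    if vals in ({0.0}, {1.0}):
        raise ValueError("all pairs concordant in one class: zero variance")
    return icc(
        x,
        y,
        families=families,
        exchangeable=exchangeable,
        n_boot=n_boot,
        seed=seed,
        **labels,
    )


def icc_table(
    pair_values: pd.DataFrame,
    trait: str = "",
    scenario: str = "",
    binary: bool = False,
    min_pairs: int = 10,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = 0,
    by_sex_label: bool = True,
) -> pd.DataFrame:
    """ICC per pair category (and sex label), as a tidy table.

    Emits one pooled row per category plus, when ``by_sex_label``, one row
    per sex-specific label with at least ``min_pairs`` complete pairs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    func = binary_icc if binary else icc
    rows = []
    groups: list[tuple[str, str, pd.DataFrame]] = []
    for cat, sub in pair_values.groupby("category"):
        groups.append((cat, "pooled", sub))
        if by_sex_label:
            for lab, sub2 in sub.groupby("sex_label"):
                groups.append((cat, lab, sub2))
    for cat, lab, sub in groups:
        if len(sub) < min_pairs:
            continue
        try:
            est = func(
                sub["x"].to_numpy(),
                sub["y"].to_numpy(),
                families=sub["family_id"].to_numpy(),
                exchangeable=cat in EXCHANGEABLE_CATEGORIES,
                n_boot=n_boot,
                seed=rng,
            )
        except ValueError:
            continue
        rows.append(
            {
                "pair_type": cat,
                "sex_label": lab,
                "trait": trait,
                "scenario": scenario,
                "icc": est.icc,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_pairs": est.n_pairs,
                "significant": est.significant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_type",
            "sex_label",
            "trait",
            "scenario",
            "icc",
            "ci_low",
            "ci_high",
            "n_pairs",
            "significant",
        ],
    )
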