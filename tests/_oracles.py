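"""Independent oracles used to validate famlipid's implementations.

Each routine here deliberately takes a different computational path from
the code under test: Monte-Carlo gene dropping instead of the kinship
recursion, a networkx-based relationship classifier instead of the pair
enumerator, the one-way ANOVA ICC instead of double-entry correlation,
closed-form 2x2 odds ratios instead of logistic regression, and numeric
bivariate-normal integrals for liability-threshold concordance.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.stats import multivariate_normal, norm


def gene_drop_kinship(ped, n_drops: int, seed: int = 0):
    """Monte-Carlo kinship: drop founder alleles through the pedigree and
    count identity by descent.

    Returns (phi_hat, phi_se), both (n, n) arrays aligned with ``ped.ids``.
    The per-pair estimator averages the four allele-pair IBD indicators;
    the diagonal returns 0.5 * (1 + F_hat).
    """
    rng = np.random.default_rng(seed)
    order = ped.topological_order()
    a1: dict[str, np.ndarray] = {}
    a2: dict[str, np.ndarray] = {}
    label = 0
    for iid in order:
        f, m = ped.parents(iid)
        if f is None:
            a1[iid] = np.full(n_drops, label, dtype=np.int32)
            label += 1
        else:
            pick = rng.integers(0, 2, n_drops).astype(bool)
            a1[iid] = np.where(pick, a1[f], a2[f])
        if m is None:
            a2[iid] = np.full(n_drops, label, dtype=np.int32)
            label += 1
        else:
            pick = rng.integers(0, 2, n_drops).astype(bool)
            a2[iid] = np.where(pick, a1[m], a2[m])
    ids = ped.ids
    n = len(ids)
    phi = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            x1, x2 = a1[ids[i]], a2[ids[i]]
            y1, y2 = a1[ids[j]], a2[ids[j]]
            if i == j:
                per = 0.5 * (1.0 + (x1 == x2))
            else:
                per = 0.25 * (
                    (x1 == y1).astype(float)
                    + (x1 == y2)
                    + (x2 == y1)
                    + (x2 == y2)
                )
            phi[i, j] = phi[j, i] = per.mean()
            se[i, j] = se[j, i] = per.std(ddof=1) / np.sqrt(n_drops)
    return phi, se


def classify_pair_graph(ped, a: str, b: str, spouse_pairs: set[frozenset]) -> str | None:
    """Relationship category for one unordered pair via ancestor graphs.

    Same precedence as the production enumerator, but derived from a
    networkx DiGraph (parent -> child) and generic ancestor/path queries.
    """
    G = nx.DiGraph()
    for m in ped.members:
        G.add_node(m.individual_id)
        for p in (m.father_id, m.mother_id):
            if p is not None:
                G.add_edge(p, m.individual_id)

    def parents(x):
        return set(G.predecessors(x))

    pa, pb = parents(a), parents(b)
    if a in pb or b in pa:
        return "parent_offspring"
    if len(pa) == 2 and pa == pb:
        return "sibling"
    anc_a = nx.ancestors(G, a)
    anc_b = nx.ancestors(G, b)
    if (b in anc_a and nx.shortest_path_length(G, b, a) == 2) or (
        a in anc_b and nx.shortest_path_length(G, a, b) == 2
    ):
        return "grandparental"
    for senior, junior in ((a, b), (b, a)):
        for p in parents(junior):
            ps = parents(p)
            if len(ps) == 2 and ps == parents(senior) and p != senior:
                return "avuncular"
    if len(pa & pb) == 1:
        return "half_sibling"
    if frozenset((a, b)) in spouse_pairs:
        return "spouse"
    for x in pa:
        for y in pb:
            if x != y:
                px, py = parents(x), parents(y)
                if len(px) == 2 and px == py:
                    return "cousin"
    return None


def anova_icc(pairs: np.ndarray) -> float:
    """Fisher's one-way ANOVA intraclass correlation for balanced pairs.

    Decomposes the total sum of squares into between-pair (SSB) and
    within-pair (SSW) parts and returns (SSB - SSW) / (SSB + SSW) — the
    population-mean-square form of the one-way random-effects ICC.
    """
    pairs = np.asarray(pairs, dtype=float)
    n, k = pairs.shape
    assert k == 2
    grand = pairs.mean()
    group_means = pairs.mean(axis=1)
    ssb = 2.0 * np.sum((group_means - grand) ** 2)
    ssw = np.sum((pairs - group_means[:, None]) ** 2)
    return (ssb - ssw) / (ssb + ssw)


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """(a*d) / (b*c) for exposed cases a, exposed controls b, unexposed
    cases c, unexposed controls d."""
    return (a * d) / (b * c)


def bvn_exceedance(t: float, rho: float) -> float:
    """P(Z1 > t, Z2 > t) for standard bivariate normal with correlation rho."""
    mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    return float(1.0 - 2.0 * norm.cdf(t) + mvn.cdf([t, t]))


def observed_scale_correlation(t: float, rho: float) -> float:
    """Phi (0/1) correlation implied by a liability threshold t and
    liability correlation rho."""
    p = 1.0 - norm.cdf(t)
    p11 = bvn_exceedance(t, rho)
    return (p11 - p * p) / (p * (1.0 - p))
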