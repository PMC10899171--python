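"""Pedigree parsing, kinship/relationship matrices, and relative-pair typing.

A pedigree is a set of individuals with optional father/mother links.  From it
we compute the kinship matrix ``phi`` (probability that two randomly sampled
alleles, one from each individual, are identical by descent), the additive
(numerator) relationship matrix ``A = 2 * phi`` used as the covariance
structure of polygenic random effects, and a typed enumeration of relative
pairs (parent-offspring, siblings, grandparental, avuncular, half-siblings,
cousins, spouses) with sex-specific labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IndividualRecord",
    "Pedigree",
    "KinshipMatrix",
    "PedigreeError",
    "load_pedigree",
    "kinship_matrix",
    "relationship_matrix",
    "enumerate_pairs",
    "consanguinity_rate",
]

#: default PED sex codes
DEFAULT_SEX_CODES: Mapping[str, str] = {"1": "male", "2": "female"}
MISSING = "0"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass(frozen=True)
class IndividualRecord:
    """One pedigree member; ``father_id``/``mother_id`` are ``None`` for founders."""

    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female"


@dataclass
class Pedigree:
    """Validated collection of :class:`IndividualRecord`.

    Validation enforces unique ids, existing parent references, parent sex
    consistency, and acyclicity (no individual is its own ancestor).
    """

    members: list[IndividualRecord]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for i, rec in enumerate(self.members):
            if rec.individual_id in self._index:
                raise PedigreeError(f"duplicated individual id: {rec.individual_id!r}")
            self._index[rec.individual_id] = i
        for rec in self.members:
            for pid, want in ((rec.father_id, "male"), (rec.mother_id, "female")):
                if pid is None:
                    continue
                if pid not in self._index:
                    raise PedigreeError(
                        f"individual {rec.individual_id!r} references missing parent {pid!r}"
                    )
                parent = self.members[self._index[pid]]
                if parent.sex != want:
                    role = "father" if want == "male" else "mother"
                    raise PedigreeError(
                        f"{role} {pid!r} of {rec.individual_id!r} has sex {parent.sex!r}"
                    )
        # acyclicity check doubles as topological-order computation
        self.topological_order()

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._index

    @property
    def ids(self) -> list[str]:
        return [m.individual_id for m in self.members]

    @property
    def founders(self) -> list[str]:
        return [
            m.individual_id
            for m in self.members
            if m.father_id is None and m.mother_id is None
        ]

    def record(self, individual_id: str) -> IndividualRecord:
        return self.members[self._index[individual_id]]

    def parents(self, individual_id: str) -> tuple[str | None, str | None]:
        rec = self.record(individual_id)
        return rec.father_id, rec.mother_id

    def children(self) -> dict[str, list[str]]:
        """Map each parent id to its list of offspring ids."""
        out: dict[str, list[str]] = {}
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    out.setdefault(pid, []).append(m.individual_id)
        return out

    def topological_order(self) -> list[str]:
        """Ids sorted parents-before-children (Kahn); raises on cycles."""
        indeg = {m.individual_id: 0 for m in self.members}
        down: dict[str, list[str]] = {m.individual_id: [] for m in self.members}
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    indeg[m.individual_id] += 1
                    down[pid].append(m.individual_id)
        queue = [i for i, d in indeg.items() if d == 0]
        order: list[str] = []
        while queue:
            nxt: list[str] = []
            for i in queue:
                order.append(i)
                for c in down[i]:
                    indeg[c] -= 1
                    if indeg[c] == 0:
                        nxt.append(c)
            queue = nxt
        if len(order) != len(self.members):
            stuck = sorted(i for i, d in indeg.items() if d > 0)
            raise PedigreeError(f"pedigree contains a cycle involving: {stuck}")
        return order

    def families(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for m in self.members:
            out.setdefault(m.family_id, []).append(m.individual_id)
        return out


@dataclass
class KinshipMatrix:
    """Kinship coefficients ``phi`` aligned with ``ids``.

    ``phi[i, i] = 0.5 * (1 + F_i)`` where ``F_i`` is the inbreeding
    coefficient (kinship of i's parents); founder off-diagonals are zero.
    """

    ids: list[str]
    phi: np.ndarray

    def loc(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.phi[i, j])


def load_pedigree(
    path,
    sex_codes: Mapping[str, str] = DEFAULT_SEX_CODES,
    missing: str = MISSING,
) -> Pedigree:
    """Read a PED-style whitespace/tab-delimited table.

    Columns: family id, individual id, father id, mother id, sex.  Rows may
    appear in any order (children before parents is fine).  Extra columns are
    ignored.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        dtype=str,
        comment="#",
        usecols=[0, 1, 2, 3, 4],
    )
    df.columns = ["family", "id", "father", "mother", "sex"]
    records = []
    for row in df.itertuples(index=False):
        if row.sex not in sex_codes:
            raise PedigreeError(
                f"unknown sex code {row.sex!r} for individual {row.id!r} "
                f"(expected one of {sorted(sex_codes)})"
            )
        records.append(
            IndividualRecord(
                family_id=row.family,
                individual_id=row.id,
                father_id=None if row.father == missing else row.father,
                mother_id=None if row.mother == missing else row.mother,
                sex=sex_codes[row.sex],
            )
        )
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path, missing: str = MISSING) -> None:
    """Write a pedigree back to PED format (sex coded 1/2)."""
    inv = {"male": "1", "female": "2"}
    with open(path, "w") as fh:
        for m in ped.members:
            fh.write(
                "\t".join(
                    [
                        m.family_id,
                        m.individual_id,
                        m.father_id or missing,
                        m.mother_id or missing,
                        inv[m.sex],
                    ]
                )
                + "\n"
            )


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Kinship by the standard recursion over a topological order.

    phi(j, i) = (phi(father(j), i) + phi(mother(j), i)) / 2  for i processed
    before j (missing parents contribute 0), and
    phi(j, j) = (1 + phi(father(j), mother(j))) / 2.
    """
    order = ped.topological_order()
    ids = ped.ids
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    phi = np.zeros((n, n))
    done: list[int] = []
    for iid in order:
        j = pos[iid]
        f, m = ped.parents(iid)
        fi = pos[f] if f is not None else None
        mi = pos[m] if m is not None else None
        if done:
            prev = np.array(done)
            row = np.zeros(len(prev))
            if fi is not None:
                row += phi[fi, prev]
            if mi is not None:
                row += phi[mi, prev]
            row *= 0.5
            phi[j, prev] = row
            phi[prev, j] = row
        fm = phi[fi, mi] if (fi is not None and mi is not None) else 0.0
        phi[j, j] = 0.5 * (1.0 + fm)
        done.append(j)
    return KinshipMatrix(ids=list(ids), phi=phi)


def relationship_matrix(k: KinshipMatrix) -> np.ndarray:
    """Additive (numerator) relationship matrix ``A = 2 * phi``.

    Rows/columns are aligned with ``k.ids``; ``diag(A) = 1 + F``.
    """
    return 2.0 * k.phi


# ---------------------------------------------------------------------------
# relative-pair enumeration

PAIR_CATEGORIES = (
    "parent_offspring",
    "sibling",
    "grandparental",
    "avuncular",
    "half_sibling",
    "spouse",
    "cousin",
)

_PO_LABEL = {
    ("male", "male"): "father-son",
    ("male", "female"): "father-daughter",
    ("female", "male"): "mother-son",
    ("female", "female"): "mother-daughter",
}
_SIB_LABEL = {
    ("male", "male"): "brother-brother",
    ("female", "female"): "sister-sister",
    ("male", "female"): "brother-sister",
}
_GRAND_LABEL = {
    ("male", "male"): "grandfather-grandson",
    ("male", "female"): "grandfather-granddaughter",
    ("female", "male"): "grandmother-grandson",
    ("female", "female"): "grandmother-granddaughter",
}
_AVUNC_LABEL = {
    ("male", "male"): "uncle-nephew",
    ("male", "female"): "uncle-niece",
    ("female", "male"): "aunt-nephew",
    ("female", "female"): "aunt-niece",
}


def _sex_pair_label(sex_a: str, sex_b: str) -> str:
    return f"{sex_a}-{sex_b}"


def _spouse_pairs(ped: Pedigree, spouse_list: Iterable[tuple[str, str]] | None):
    """Unordered spouse pairs: shared offspring, plus an explicit list for
    childless couples."""
    pairs: set[frozenset[str]] = set()
    for m in ped.members:
        if m.father_id is not None and m.mother_id is not None:
            pairs.add(frozenset((m.father_id, m.mother_id)))
    if spouse_list is not None:
        for a, b in spouse_list:
            if a in ped and b in ped and a != b:
                pairs.add(frozenset((a, b)))
    return pairs


def enumerate_pairs(
    ped: Pedigree,
    spouse_list: Iterable[tuple[str, str]] | None = None,
    include_half_avuncular: bool = False,
    with_kinship: bool = True,
) -> pd.DataFrame:
    """Enumerate typed relative pairs within families.

    Each unordered pair is emitted at most once, under the
    highest-precedence category that applies: first-degree
    (parent-offspring, sibling) over second-degree (grandparental,
    avuncular, half-sibling) over spouse over cousin.  Spouses precede
    cousins so that a consanguineous marriage is reported as a spouse pair
    (its kinship column still reveals the blood relation).

    Returns a DataFrame with columns ``id_a, id_b, family_id, category,
    sex_label`` and, when ``with_kinship``, ``kinship``.  For ordered
    categories the senior member (parent, grandparent, aunt/uncle) is
    ``id_a``; for exchangeable categories males sort first, then by id.
    """
    spouse_set = _spouse_pairs(ped, spouse_list)
    kin = kinship_matrix(ped) if with_kinship else None
    pos = {i: k for k, i in enumerate(ped.ids)} if kin is not None else {}

    parent_of: dict[str, set[str]] = {}
    for m in ped.members:
        parent_of[m.individual_id] = {
            p for p in (m.father_id, m.mother_id) if p is not None
        }

    def full_sibs(a: str, b: str) -> bool:
        ra, rb = ped.record(a), ped.record(b)
        return (
            ra.father_id is not None
            and ra.mother_id is not None
            and ra.father_id == rb.father_id
            and ra.mother_id == rb.mother_id
        )

    def half_sibs(a: str, b: str) -> bool:
        shared = parent_of[a] & parent_of[b]
        return len(shared) == 1 and not full_sibs(a, b)

    def grandparents(a: str) -> set[str]:
        out: set[str] = set()
        for p in parent_of[a]:
            out |= parent_of[p]
        return out

    def classify(a: str, b: str):
        """Return (category, ordered (senior_first) ids) or None."""
        if b in parent_of[a]:
            return "parent_offspring", (b, a)
        if a in parent_of[b]:
            return "parent_offspring", (a, b)
        if full_sibs(a, b):
            return "sibling", _exchange_order(ped, a, b)
        if b in grandparents(a):
            return "grandparental", (b, a)
        if a in grandparents(b):
            return "grandparental", (a, b)
        for senior, junior in ((a, b), (b, a)):
            for p in parent_of[junior]:
                if full_sibs(senior, p) or (
                    include_half_avuncular and half_sibs(senior, p)
                ):
                    return "avuncular", (senior, junior)
        if half_sibs(a, b):
            return "half_sibling", _exchange_order(ped, a, b)
        if frozenset((a, b)) in spouse_set:
            return "spouse", _spouse_order(ped, a, b)
        for pa in parent_of[a]:
            for pb in parent_of[b]:
                if pa != pb and full_sibs(pa, pb):
                    return "cousin", _exchange_order(ped, a, b)
        return None

    rows = []
    for fam, fam_ids in ped.families().items():
        for a, b in itertools.combinations(sorted(fam_ids), 2):
            res = classify(a, b)
            if res is None:
                continue
            cat, (first, second) = res
            s1, s2 = ped.record(first).sex, ped.record(second).sex
            if cat == "parent_offspring":
                label = _PO_LABEL[(s1, s2)]
            elif cat == "sibling":
                label = _SIB_LABEL[(s1, s2)]
            elif cat == "grandparental":
                label = _GRAND_LABEL[(s1, s2)]
            elif cat == "avuncular":
                label = _AVUNC_LABEL[(s1, s2)]
            elif cat == "spouse":
                label = "husband-wife"
            else:
                label = _sex_pair_label(s1, s2)
            row = {
                "id_a": first,
                "id_b": second,
                "family_id": fam,
                "category": cat,
                "sex_label": label,
            }
            if kin is not None:
                row["kinship"] = kin.phi[pos[first], pos[second]]
            rows.append(row)
    cols = ["id_a", "id_b", "family_id", "category", "sex_label"]
    if with_kinship:
        cols.append("kinship")
    return pd.DataFrame(rows, columns=cols)


def _exchange_order(ped: Pedigree, a: str, b: str) -> tuple[str, str]:
    sa, sb = ped.record(a).sex, ped.record(b).sex
    if sa != sb:
        return (a, b) if sa == "male" else (b, a)
    return (a, b) if a <= b else (b, a)


def _spouse_order(ped: Pedigree, a: str, b: str) -> tuple[str, str]:
    return (a, b) if ped.record(a).sex == "male" else (b, a)


def consanguinity_rate(
    ped: Pedigree,
    spouse_list: Iterable[tuple[str, str]] | None = None,
) -> float:
    """Fraction of spouse pairs with kinship > 0 (consanguineous marriages)."""
    pairs = _spouse_pairs(ped, spouse_list)
    if not pairs:
        raise PedigreeError("no spouse pairs in pedigree; consanguinity undefined")
    kin = kinship_matrix(ped)
    pos = {i: k for k, i in enumerate(kin.ids)}
    n_consang = sum(
        1 for p in pairs if kin.phi[pos[min(p)], pos[max(p)]] > 0.0
    )
    return n_consang / len(pairs)
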