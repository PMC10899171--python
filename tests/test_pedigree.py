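import itertools

import numpy as np
import pytest

from famlipid.pedigree import (
    PedigreeError,
    consanguinity_rate,
    enumerate_pairs,
    kinship_matrix,
    load_pedigree,
    relationship_matrix,
    write_pedigree,
)
from famlipid.simulate import SimulationConfig, simulate_pedigree

from _oracles import classify_pair_graph, gene_drop_kinship
from conftest import ped_from_rows

TRIO_PED = "F1 C P M 2\nF1 P 0 0 1\nF1 M 0 0 2\n"


class TestLoadPedigree:
    def test_trio_roundtrip(self, tmp_path):
        path = tmp_path / "trio.ped"
        path.write_text(TRIO_PED)
        ped = load_pedigree(path)
        assert len(ped) == 3
        assert sorted(ped.founders) == ["M", "P"]

    def test_order_independence(self, tmp_path):
        shuffled = tmp_path / "a.ped"
        shuffled.write_text(TRIO_PED)  # child listed first
        sorted_file = tmp_path / "b.ped"
        sorted_file.write_text(
            "\n".join(sorted(TRIO_PED.strip().split("\n"))) + "\n"
        )
        a, b = load_pedigree(shuffled), load_pedigree(sorted_file)
        ka, kb = kinship_matrix(a), kinship_matrix(b)
        order = [ka.ids.index(i) for i in kb.ids]
        assert np.allclose(ka.phi[np.ix_(order, order)], kb.phi)

    @pytest.mark.parametrize(
        "content, match",
        [
            ("F1 A 0 0 1\nF1 A 0 0 2\n", "duplicated"),
            ("F1 A 0 0 3\n", "sex code"),
            ("F1 A B 0 1\n", "missing parent"),
            # father slot points at a female
            ("F1 A 0 0 2\nF1 B A 0 1\n", "father 'A'"),
        ],
    )
    def test_invalid_files(self, tmp_path, content, match):
        path = tmp_path / "bad.ped"
        path.write_text(content)
        with pytest.raises(PedigreeError, match=match):
            load_pedigree(path)

    def test_cycle_detection(self):
        with pytest.raises(PedigreeError, match="cycle"):
            ped_from_rows(
                [
                    ("F1", "A", "B", None, "male"),
                    ("F1", "B", "A", None, "male"),
                ]
            )

    def test_write_read_roundtrip(self, tmp_path, cousin_marriage):
        path = tmp_path / "out.ped"
        write_pedigree(cousin_marriage, path)
        again = load_pedigree(path)
        assert again.ids == cousin_marriage.ids
        assert again.founders == cousin_marriage.founders


class TestKinship:
    def test_textbook_values(self, nuclear):
        kin = kinship_matrix(nuclear)
        assert kin.loc("dad", "s1") == pytest.approx(0.25)
        assert kin.loc("s1", "s2") == pytest.approx(0.25)
        assert kin.loc("s1", "d1") == pytest.approx(0.25)
        assert kin.loc("dad", "mom") == 0.0
        assert kin.loc("dad", "dad") == pytest.approx(0.5)

    def test_first_cousins_and_inbreeding(self, cousin_marriage):
        kin = kinship_matrix(cousin_marriage)
        assert kin.loc("c1", "c2") == pytest.approx(0.0625)
        # child of first cousins: F = 1/16
        assert kin.loc("kid", "kid") == pytest.approx(0.53125)

    def test_relationship_matrix_values(self, trio, cousin_marriage):
        A = relationship_matrix(kinship_matrix(trio))
        assert np.allclose(np.diag(A), 1.0)
        assert A[0, 2] == pytest.approx(0.5)  # parent-child
        k2 = kinship_matrix(cousin_marriage)
        A2 = relationship_matrix(k2)
        assert A2[k2.ids.index("kid"), k2.ids.index("kid")] == pytest.approx(1.0625)

    def test_unrelated_founders_identity(self):
        ped = ped_from_rows(
            [(f"F{i}", f"I{i}", None, None, "male") for i in range(4)]
        )
        A = relationship_matrix(kinship_matrix(ped))
        assert np.array_equal(A, np.eye(4))

    def test_symmetry_and_psd_on_simulated(self, cohort300):
        ped, A, eig = cohort300
        kin = kinship_matrix(ped)
        assert np.allclose(kin.phi, kin.phi.T)
        assert eig.lam.min() >= -1e-8
        # founder-founder off-diagonals are zero
        founders = [kin.ids.index(i) for i in ped.founders]
        off = kin.phi[np.ix_(founders, founders)].copy()
        np.fill_diagonal(off, 0.0)
        assert np.all(off == 0.0)

    def test_against_gene_dropping(self):
        """Recursive kinship agrees with a 200k-replicate gene-dropping
        Monte-Carlo estimate within 3 MC standard errors per pair."""
        cfg = SimulationConfig(n_families=5, sibship=(2, 3), generations=2, seed=11)
        ped = simulate_pedigree(cfg, seed=11)
        assert 40 <= len(ped) <= 60
        kin = kinship_matrix(ped)
        phi_hat, se = gene_drop_kinship(ped, n_drops=200_000, seed=5)
        diff = np.abs(phi_hat - kin.phi)
        # exact-zero kinship pairs have se 0 and diff 0; elsewhere 3 SE
        assert np.all(diff <= 3.0 * se + 1e-12)


class TestPairs:
    def test_nuclear_counts(self, nuclear):
        pairs = enumerate_pairs(nuclear)
        counts = pairs.groupby(["category", "sex_label"]).size()
        assert counts[("parent_offspring", "father-son")] == 2
        assert counts[("parent_offspring", "father-daughter")] == 1
        assert counts[("parent_offspring", "mother-son")] == 2
        assert counts[("parent_offspring", "mother-daughter")] == 1
        assert counts[("sibling", "brother-brother")] == 1
        assert counts[("sibling", "brother-sister")] == 2
        assert counts[("spouse", "husband-wife")] == 1
        assert len(pairs) == 10

    def test_three_generation_line(self):
        ped = ped_from_rows(
            [
                ("F1", "gpa", None, None, "male"),
                ("F1", "gma", None, None, "female"),
                ("F1", "dad", "gpa", "gma", "male"),
                ("F1", "mom", None, None, "female"),
                ("F1", "son", "dad", "mom", "male"),
            ]
        )
        pairs = enumerate_pairs(ped)
        cats = pairs["category"].value_counts()
        assert cats["parent_offspring"] == 4  # gpa-dad, gma-dad, dad-son, mom-son
        assert cats["grandparental"] == 2
        assert (
            pairs.query("category == 'grandparental'")["id_a"].tolist()
            == ["gma", "gpa"]
        )

    def test_explicit_spouse_list(self, trio):
        pairs = enumerate_pairs(trio, spouse_list=[("P", "M")])
        assert (pairs["category"] == "spouse").sum() == 1

    def test_senior_member_first(self, nuclear):
        po = enumerate_pairs(nuclear).query("category == 'parent_offspring'")
        assert set(po["id_a"]) <= {"dad", "mom"}

    @pytest.mark.parametrize(
        "cfg",
        [
            SimulationConfig(n_families=1, sibship=(2, 4), generations=2, seed=1),
            SimulationConfig(n_families=1, sibship=(1, 3), generations=2, seed=2),
            SimulationConfig(n_families=2, sibship=(2, 2), generations=1, seed=3),
            SimulationConfig(n_families=1, sibship=(2, 2), generations=1,
                             consanguinity_rate=0.35, seed=4),
        ],
    )
    def test_against_graph_classifier_small(self, cfg):
        """Every pair in small simulated pedigrees is classified identically
        by the independent networkx-based classifier."""
        ped = simulate_pedigree(cfg, seed=cfg.seed)
        pairs = enumerate_pairs(ped)
        got = {
            frozenset((r.id_a, r.id_b)): r.category for r in pairs.itertuples()
        }
        spouse_pairs = {
            frozenset((m.father_id, m.mother_id))
            for m in ped.members
            if m.father_id is not None and m.mother_id is not None
        }
        for fam_ids in ped.families().values():
            for a, b in itertools.combinations(fam_ids, 2):
                expect = classify_pair_graph(ped, a, b, spouse_pairs)
                assert got.get(frozenset((a, b))) == expect, (a, b)

    def test_against_graph_classifier_200_members(self):
        cfg = SimulationConfig(n_families=20, sibship=(2, 4), generations=2, seed=9)
        ped = simulate_pedigree(cfg, seed=9)
        assert len(ped) >= 150
        pairs = enumerate_pairs(ped)
        spouse_pairs = {
            frozenset((m.father_id, m.mother_id))
            for m in ped.members
            if m.father_id is not None and m.mother_id is not None
        }
        oracle_counts: dict[str, int] = {}
        for fam_ids in ped.families().values():
            for a, b in itertools.combinations(fam_ids, 2):
                cat = classify_pair_graph(ped, a, b, spouse_pairs)
                if cat:
                    oracle_counts[cat] = oracle_counts.get(cat, 0) + 1
        assert pairs["category"].value_counts().to_dict() == oracle_counts


class TestConsanguinity:
    def test_all_founder_marriages(self, nuclear):
        assert consanguinity_rate(nuclear) == 0.0

    def test_one_cousin_marriage_in_four(self, cousin_marriage):
        # marriages: gf-gm, u1-w1, h2-u2 (founders x sibs), c1-c2 (cousins)
        assert consanguinity_rate(cousin_marriage) == pytest.approx(0.25)

    def test_no_spouses_flagged(self):
        singletons = ped_from_rows([("F1", "A", None, None, "male")])
        with pytest.raises(PedigreeError, match="no spouse pairs"):
            consanguinity_rate(singletons)

    def test_generator_round_trip(self):
        """Observed consanguineous-marriage fraction matches the configured
        target within a binomial 95% interval."""
        target = 0.28
        cfg = SimulationConfig(
            n_families=1200, sibship=(2, 2), generations=1,
            consanguinity_rate=target, seed=17,
        )
        ped = simulate_pedigree(cfg, seed=17)
        pairs = enumerate_pairs(ped)
        n_marr = (pairs["category"] == "spouse").sum()
        assert n_marr >= 2000
        rate = consanguinity_rate(ped)
        half_width = 1.96 * np.sqrt(target * (1 - target) / n_marr)
        assert abs(rate - target) <= half_width
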