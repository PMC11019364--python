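"""IBS, UPGMA, proxy/mislabel rules, and variant-sharing summaries."""

import numpy as np
import pytest

from refpanelqc.strain_genetics import (
    CROSS_STRAIN_HIGH,
    IBSMatrix,
    SAME_STRAIN_LOW,
    ibs_matrix,
    match_and_flag,
    sharing_summary,
    upgma_tree,
)
from refpanelqc.synthetic_data import SimConfig, generate_panel

from conftest import build_panel
from oracles import naive_upgma, tree_to_tuple, tuples_equal


class TestIBS:
    def test_identical_opposite_and_half(self):
        # columns: S0 == S1 (IBS 1); S2 opposite homozygote (0 vs S0);
        # S3 het everywhere (0.5 vs S0)
        g = np.array([[0, 0, 2, 1]] * 20)
        m = ibs_matrix(build_panel(g))
        assert m.get("S0", "S1") == pytest.approx(1.0)
        assert m.get("S0", "S2") == pytest.approx(0.0)
        assert m.get("S0", "S3") == pytest.approx(0.5)
        assert np.allclose(np.diag(m.values), 1.0)

    def test_matches_per_site_brute_force(self):
        rng = np.random.default_rng(8)
        g = rng.integers(0, 4, size=(200, 4))
        m = ibs_matrix(build_panel(g))
        dose = {0: 0, 1: 1, 2: 2}
        for i in range(4):
            for j in range(i + 1, 4):
                scores = [1 - abs(dose[a] - dose[b]) / 2
                          for a, b in zip(g[:, i], g[:, j])
                          if a != 3 and b != 3]
                assert m.get(f"S{i}", f"S{j}") == pytest.approx(
                    np.mean(scores))

    def test_missing_sites_excluded_pairwise(self):
        g = np.array([[0, 3], [2, 2], [3, 2]])
        m = ibs_matrix(build_panel(g))
        # only site 2 is co-called: identical hom-alt
        assert m.get("S0", "S1") == pytest.approx(1.0)

    def test_disjoint_call_sets_error(self):
        g = np.array([[0, 3], [3, 0]])
        with pytest.raises(ValueError, match="no co-called"):
            ibs_matrix(build_panel(g))

    def test_non_snp_sites_excluded_by_default(self):
        panel = build_panel(np.array([[2, 0], [2, 0]]))
        panel.blocks["chr1"].alts[0] = ("TTT",)   # indel site
        m_snp = ibs_matrix(panel)
        m_all = ibs_matrix(panel, biallelic_snps_only=False)
        assert m_snp.get("S0", "S1") == 0.0
        assert m_all.get("S0", "S1") == 0.0


class TestUPGMA:
    def test_three_leaf_hand_example(self):
        d = np.array([[0.0, 2, 4], [2, 0, 4], [4, 4, 0]])
        tree, nwk = upgma_tree(IBSMatrix(["A", "B", "C"], 1 - d))
        assert nwk == "((A:1,B:1):1,C:2);"

    def test_two_leaves(self):
        m = IBSMatrix(["A", "B"], 1 - np.array([[0.0, 0.6], [0.6, 0.0]]))
        assert upgma_tree(m)[1] == "(A:0.3,B:0.3);"

    def test_ultrametric_and_leaf_conservation(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            ids = [f"L{i}" for i in range(n)]
            d = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            d[iu] = rng.uniform(0.1, 1.0, size=len(iu[0]))
            d += d.T
            tree, _ = upgma_tree(IBSMatrix(ids, 1 - d))
            depths = tree.leaf_depths()
            assert sorted(depths) == sorted(ids)
            vals = list(depths.values())
            assert max(vals) - min(vals) < 1e-9

    def test_matches_average_linkage_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(3, 9))
            ids = [f"L{i}" for i in range(n)]
            d = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            d[iu] = rng.uniform(0.05, 1.0, size=len(iu[0]))
            d += d.T
            tree, _ = upgma_tree(IBSMatrix(ids, 1 - d))
            expected = naive_upgma(ids, d)
            assert tuples_equal(tree_to_tuple(tree.root), expected)

    def test_newick_parses_with_skbio(self):
        import io
        import skbio
        d = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
        _, nwk = upgma_tree(IBSMatrix(["A", "B", "C"], 1 - d))
        t = skbio.TreeNode.read(io.StringIO(nwk))
        assert {x.name for x in t.tips()} == {"A", "B", "C"}

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            IBSMatrix(["A", "B"], np.array([[1.0, 0.3], [0.5, 1.0]]))


def two_strain_matrix(ids, labels_ibs):
    n = len(ids)
    v = np.ones((n, n))
    for (a, b), x in labels_ibs.items():
        i, j = ids.index(a), ids.index(b)
        v[i, j] = v[j, i] = x
    return IBSMatrix(ids, v)


class TestProxyAndMislabel:
    def test_proxy_pass_at_996(self):
        ids = ["OLD_1", "NEW_1", "FAR_1"]
        m = two_strain_matrix(ids, {("OLD_1", "NEW_1"): 0.996,
                                    ("OLD_1", "FAR_1"): 0.7,
                                    ("NEW_1", "FAR_1"): 0.7})
        labels = {"OLD_1": ("OLD", "OLD/a"), "NEW_1": ("NEW", "NEW/b"),
                  "FAR_1": ("FAR", "FAR/c")}
        proxies, _ = match_and_flag(m, labels, proxy_queries=["OLD"])
        assert proxies[0].best_sample == "NEW_1"
        assert proxies[0].passes

    def test_proxy_excludes_own_substrain(self):
        ids = ["Q_1", "Q_2", "OTHER_1"]
        m = two_strain_matrix(ids, {("Q_1", "Q_2"): 0.999,
                                    ("Q_1", "OTHER_1"): 0.8,
                                    ("Q_2", "OTHER_1"): 0.8})
        labels = {"Q_1": ("Q", "Q/sub"), "Q_2": ("Q", "Q/sub"),
                  "OTHER_1": ("O", "O/sub")}
        proxies, _ = match_and_flag(m, labels, proxy_queries=["Q"])
        assert proxies[0].best_sample == "OTHER_1"
        assert not proxies[0].passes

    def test_same_strain_low_and_cross_strain_high_rules(self):
        ids = ["A_1", "A_2", "B_1"]
        m = two_strain_matrix(ids, {("A_1", "A_2"): 0.92,
                                    ("A_1", "B_1"): 0.99,
                                    ("A_2", "B_1"): 0.7})
        labels = {"A_1": ("A", "A/x"), "A_2": ("A", "A/x"),
                  "B_1": ("B", "B/y")}
        _, flags = match_and_flag(m, labels)
        rules = {(f.sample_a, f.sample_b): f.rule for f in flags}
        assert rules[("A_1", "A_2")] == SAME_STRAIN_LOW
        assert rules[("A_1", "B_1")] == CROSS_STRAIN_HIGH
        assert len(flags) == 2

    def test_planted_swaps_recovered_without_false_flags(self):
        for seed in range(5):
            cfg = SimConfig(n_strains=8, replicates_per_strain=2,
                            chrom_lengths={"chr1": 150_000},
                            label_swaps=[(2, 4)], seed=seed)
            panel, _ = generate_panel(cfg)
            m = ibs_matrix(panel)
            labels = {s.id: (s.strain, s.substrain) for s in panel.samples}
            _, flags = match_and_flag(m, labels)
            flagged = {x for f in flags for x in (f.sample_a, f.sample_b)}
            swapped = {panel.samples[2].id, panel.samples[4].id}
            affected_strains = {panel.samples[i].strain for i in (2, 4)}
            assert flags, "swap must produce at least one flag"
            # every swapped sample is implicated (no misses) ...
            assert swapped <= flagged
            # ... and no flag touches a strain uninvolved in the swap
            # (replicate partners of the swapped samples are legitimately
            # flagged: their same-strain pair now has low IBS)
            by_id = {s.id: s.strain for s in panel.samples}
            assert all(by_id[x] in affected_strains for x in flagged)

    def test_unknown_query_rejected(self):
        m = two_strain_matrix(["A_1", "B_1"], {("A_1", "B_1"): 0.5})
        labels = {"A_1": ("A", "A"), "B_1": ("B", "B")}
        with pytest.raises(KeyError):
            match_and_flag(m, labels, proxy_queries=["NOPE"])


class TestSharing:
    def test_enumerated_example(self):
        # sites: s1 carried by A only; s2 by all; s3 by A and B
        g = np.array([
            [2, 0, 0],
            [2, 2, 2],
            [2, 1, 0],
        ])
        panel = build_panel(g)
        out = sharing_summary(panel, {"A": ["S0"], "B": ["S1"], "C": ["S2"]})
        assert out["unique"] == {"A": 1, "B": 0, "C": 0}
        assert out["shared_by_all"] == 1
        assert out["totals"] == {"A": 3, "B": 2, "C": 1}

    def test_single_strain_degenerate(self):
        g = np.array([[2, 2], [0, 1]])
        out = sharing_summary(build_panel(g), {"only": ["S0", "S1"]})
        assert out["totals"]["only"] == 2
        assert out["unique"]["only"] == 2
        assert out["shared_by_all"] == 2

    def test_planted_private_sites_recovered(self):
        cfg = SimConfig(n_strains=5, replicates_per_strain=2,
                        chrom_lengths={"chr1": 200_000},
                        background_het_rate=0.0, missing_rate=0.0, seed=31)
        panel, _ = generate_panel(cfg)
        groups = {}
        for s in panel.samples:
            groups.setdefault(s.strain, []).append(s.id)
        out = sharing_summary(panel, groups)
        # brute-force recount from the genotype matrix
        blk = panel.blocks["chr1"]
        cls = blk.classes()
        carriers = {}
        for strain, members in groups.items():
            cols = panel.sample_index(members)
            carriers[strain] = ((cls[:, cols] == 1) |
                                (cls[:, cols] == 2)).any(axis=1)
        n_carry = np.sum(list(carriers.values()), axis=0)
        for strain in groups:
            assert out["totals"][strain] == int(carriers[strain].sum())
            assert out["unique"][strain] == int(
                (carriers[strain] & (n_carry == 1)).sum())
        assert out["shared_by_all"] == int((n_carry == len(groups)).sum())
        assert sum(out["unique"].values()) <= int((n_carry >= 1).sum())

    def test_empty_group_rejected(self, tiny_panel):
        with pytest.raises(ValueError, match="empty"):
            sharing_summary(tiny_panel, {"A": []})
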