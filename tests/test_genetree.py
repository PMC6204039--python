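import random

import dendropy
import numpy as np
import pytest

from wgdtrace import genetree as G
from wgdtrace import simulate as S


def _dm(labels, mat):
    return G.DistanceMatrix(labels=list(labels), matrix=np.array(mat, float))


def _leafsets(tree):
    out = set()
    for n in tree.preorder_node_iter():
        if not n.is_leaf():
            out.add(frozenset(lf.taxon.label for lf in n.leaf_iter()))
    return out


def _patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    return {frozenset((t1.label, t2.label)): pdm.patristic_distance(t1, t2)
            for t1 in tree.taxon_namespace for t2 in tree.taxon_namespace
            if t1.label < t2.label}


class TestNjTree:
    def test_three_taxa_three_point_lengths(self):
        t = G.nj_tree(_dm("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]]))
        d = _patristic(t)
        assert d[frozenset("AB")] == pytest.approx(3)
        assert d[frozenset("AC")] == pytest.approx(4)
        assert d[frozenset("BC")] == pytest.approx(5)

    def test_additive_four_taxon_reconstruction(self):
        m = [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]]
        t = G.nj_tree(_dm("ABCD", m))
        assert frozenset("AB") in _leafsets(t) or frozenset("CD") in _leafsets(t)
        d = _patristic(t)
        assert d[frozenset("AB")] == pytest.approx(2)
        assert d[frozenset("AC")] == pytest.approx(4)

    def test_taxon_order_invariance(self):
        m = np.array([[0, 2, 4, 4.2], [2, 0, 4.1, 4], [4, 4.1, 0, 2.2],
                      [4.2, 4, 2.2, 0]])
        t1 = G.nj_tree(_dm("ABCD", m))
        perm = [2, 0, 3, 1]
        t2 = G.nj_tree(_dm([("ABCD")[i] for i in perm], m[np.ix_(perm, perm)]))
        assert _leafsets(t1) == _leafsets(t2)

    def test_consistency_on_random_additive_matrices(self):
        """NJ recovers exact path lengths from additive distances."""
        rng = random.Random(19)
        for _ in range(20):
            n = rng.randint(4, 8)
            labels = [f"t{i}" for i in range(n)]
            # random additive matrix: random tree -> path metric
            src = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
                rng=random.Random(rng.randint(0, 10**6)))
            for i, leaf in enumerate(src.leaf_node_iter()):
                leaf.taxon.label = labels[i]
            for e in src.preorder_edge_iter():
                if e.length is not None:
                    e.length = rng.uniform(0.1, 2.0)
            pdm = src.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in src.taxon_namespace}
            mat = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    mat[i, j] = mat[j, i] = pdm.patristic_distance(
                        taxa[labels[i]], taxa[labels[j]])
            rec = G.nj_tree(_dm(labels, mat))
            d = _patristic(rec)
            for i in range(n):
                for j in range(i + 1, n):
                    assert d[frozenset((labels[i], labels[j]))] == pytest.approx(
                        mat[i, j], abs=1e-8)

    def test_cross_check_against_dendropy_nj(self):
        """Independent NJ implementation agrees on a clean additive case."""
        labels = ["a", "b", "c", "d", "e"]
        m = np.array([
            [0, 1.0, 3.0, 4.0, 4.4],
            [1.0, 0, 3.2, 4.2, 4.6],
            [3.0, 3.2, 0, 2.0, 2.4],
            [4.0, 4.2, 2.0, 0, 1.6],
            [4.4, 4.6, 2.4, 1.6, 0]])
        mine = G.nj_tree(_dm(labels, m))
        pdm_src = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(
                "," + ",".join(labels) + "\n" +
                "\n".join(l + "," + ",".join(str(x) for x in row)
                          for l, row in zip(labels, m))),
            delimiter=",")
        ref = pdm_src.nj_tree()
        ref_splits = {frozenset(lf.taxon.label for lf in n.leaf_iter())
                      for n in ref.preorder_node_iter() if not n.is_leaf()}
        mine_splits = _leafsets(mine)
        # compare non-trivial bipartitions (both trees unrooted)
        full = frozenset(labels)
        norm = lambda ss: {min(s, full - s, key=lambda x: tuple(sorted(x)))
                           for s in ss if 1 < len(s) < len(labels) - 1}
        assert norm(mine_splits) == norm(ref_splits)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            _dm("ABC", [[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])


class TestBootstrap:
    def _seqs(self, L=500, seed=4):
        # paralog clades at synonymous distance 1.0, orthologs at 0.05
        cfg = S.SimConfig(
            species_tree="((A:0.025,B:0.025)AB:0.475,O:0.5)R;",
            wgd_events=(S.WgdSpec("AB", 0.0, 1.0, "w"),),
            n_genes=1, codons_per_gene=L, omega=0.2, seed=seed)
        truth = S.simulate_history(cfg)
        return {g: r.sequence for g, r in S.simulate_sequences(truth).items()}

    def test_identical_seed_identical_supports(self):
        seqs = self._seqs()
        t1 = G.bootstrap_supports(seqs, replicates=30, seed=7)
        t2 = G.bootstrap_supports(seqs, replicates=30, seed=7)
        s1 = sorted(n.support for n in t1 if not n.is_leaf() and n.support is not None)
        s2 = sorted(n.support for n in t2 if not n.is_leaf() and n.support is not None)
        assert s1 == s2

    def test_well_separated_clade_high_support(self):
        """Clades split by synonymous distance ~2 vs within-clade 0.05 get
        >= 95% support at 100 replicates and 500 codons."""
        seqs = self._seqs()
        t = G.bootstrap_supports(seqs, replicates=100, seed=7)
        supports = [n.support for n in t
                    if not n.is_leaf() and n.support is not None]
        assert supports and min(supports) >= 95

    def test_too_few_leaves(self):
        with pytest.raises(ValueError):
            G.bootstrap_supports({"a": "GCT", "b": "GCT", "c": "GCT"})


class TestRooting:
    def _tree(self, nwk):
        t = dendropy.Tree.get(data=nwk, schema="newick",
                              suppress_internal_node_taxa=True,
                              preserve_underscores=True)
        for n in t.preorder_node_iter():
            n.support = None
            if not n.is_leaf() and n.label:
                n.support = float(n.label)
        t.support_units = "bootstrap"
        t.is_rooted = False
        return t

    def test_outgroup_sister_to_rest(self):
        rooted = G.root_by_outgroup(self._tree("((A:1,B:1):1,C:2);"), "C")
        kids = rooted.seed_node.child_nodes()
        leafsets = [frozenset(lf.taxon.label for lf in k.leaf_iter()) for k in kids]
        assert frozenset({"C"}) in leafsets
        assert frozenset({"A", "B"}) in leafsets

    def test_leaf_set_preserved(self):
        rooted = G.root_by_outgroup(self._tree("((A:1,B:1):1,(C:1,D:1):1);"), "D")
        assert {lf.taxon.label for lf in rooted.leaf_node_iter()} == set("ABCD")

    def test_support_survives_rooting(self):
        rooted = G.root_by_outgroup(
            self._tree("((A:1,B:1)88:1,(C:1,D:1)77:1);"), "D")
        by_clade = {frozenset(lf.taxon.label for lf in n.leaf_iter()): n.support
                    for n in rooted.preorder_node_iter() if not n.is_leaf()}
        assert by_clade.get(frozenset({"A", "B"})) == 88.0

    def test_missing_outgroup(self):
        with pytest.raises(KeyError):
            G.root_by_outgroup(self._tree("((A:1,B:1):1,C:2);"), "Z")


def _annotated(nwk, species):
    t = dendropy.Tree.get(data=nwk, schema="newick",
                          suppress_internal_node_taxa=True,
                          preserve_underscores=True)
    for n in t.preorder_node_iter():
        n.support = None
        if not n.is_leaf() and n.label:
            n.support = float(n.label)
    t.support_units = "bootstrap"
    t.is_rooted = True
    return t, species


class TestDetectDuplications:
    def test_deep_shared_duplication_fully_supported(self):
        """Both child clades span two lineages with all three supports high:
        a shared, supported call (the resolved deep-duplication pattern)."""
        t, sp = _annotated(
            "(((V1:1,T1:1)100:1,(V2:1,T2:1)100:1)99:1,O:3);",
            {"V1": "Vit", "T1": "Sol", "V2": "Vit", "T2": "Sol", "O": "Amb"})
        calls = G.detect_duplications(t, sp, threshold=90)
        (c,) = [c for c in calls if c.classification == "shared"]
        assert (c.bs1, c.bs2, c.bs3) == (99.0, 100.0, 100.0)
        assert c.supported and not c.fully_supported

    def test_lineage_wide_duplication_all_100(self):
        t, sp = _annotated(
            "(((S1a:1,S2a:1)100:1,(S1b:1,S2b:1)100:1)100:1,O:3);",
            {"S1a": "Sly", "S2a": "Stu", "S1b": "Sly", "S2b": "Stu", "O": "Amb"})
        calls = G.detect_duplications(t, sp, threshold=90)
        (c,) = [c for c in calls if c.classification == "shared"]
        assert c.fully_supported
        assert c.shared_species == frozenset({"Sly", "Stu"})

    def test_low_child_supports_not_supported(self):
        t, sp = _annotated(
            "(((V1:1,T1:1)45:1,(V2:1,T2:1)38:1)95:1,O:3);",
            {"V1": "Vit", "T1": "Sol", "V2": "Vit", "T2": "Sol", "O": "Amb"})
        (c,) = [c for c in G.detect_duplications(t, sp, threshold=90)
                if c.classification == "shared"]
        assert not c.supported
        assert (c.bs2, c.bs3) == (45.0, 38.0)

    def test_species_specific_classification(self):
        t, sp = _annotated("((A1:1,A2:1)97:1,O:2);",
                           {"A1": "Ath", "A2": "Ath", "O": "Amb"})
        calls = G.detect_duplications(t, sp, threshold=90)
        (c,) = calls
        assert c.classification == "species_specific"
        assert c.shared_species == frozenset({"Ath"})

    def test_leaf_children_get_full_support(self):
        t, sp = _annotated("((A1:1,A2:1)97:1,O:2);",
                           {"A1": "Ath", "A2": "Ath", "O": "Amb"})
        (c,) = G.detect_duplications(t, sp, threshold=90)
        assert (c.bs2, c.bs3) == (100.0, 100.0)

    def test_invariant_to_child_order(self):
        n1, sp = _annotated(
            "(((V1:1,T1:1)80:1,(V2:1,T2:1)60:1)99:1,O:3);",
            {"V1": "Vit", "T1": "Sol", "V2": "Vit", "T2": "Sol", "O": "Amb"})
        n2, _ = _annotated(
            "(((V2:1,T2:1)60:1,(V1:1,T1:1)80:1)99:1,O:3);", sp)
        c1 = [c for c in G.detect_duplications(n1, sp) if c.classification == "shared"][0]
        c2 = [c for c in G.detect_duplications(n2, sp) if c.classification == "shared"][0]
        assert {c1.bs2, c1.bs3} == {c2.bs2, c2.bs3}
        assert c1.supported == c2.supported

    def test_missing_species_mapping(self):
        t, _ = _annotated("((A1:1,A2:1)97:1,O:2);", {})
        with pytest.raises(KeyError):
            G.detect_duplications(t, {"A1": "Ath", "O": "Amb"})


class TestExclusionSeries:
    @pytest.fixture(scope="class")
    @staticmethod
    def basal_family():
        cfg = S.basal_lineage_scenario(seed=5, n_genes=20)
        truth = S.simulate_history(cfg)
        seqs = S.simulate_sequences(truth)
        retained = {e["family"] for e in truth.event_log if e["retained"]}
        return truth, seqs, retained

    def _family_seqs(self, seqs, fam):
        fid = f"f{fam:04d}"
        return {g: r.sequence for g, r in seqs.items() if fid in g}

    def test_empty_exclusion_matches_baseline(self, basal_family):
        truth, seqs, retained = basal_family
        fam = sorted(retained)[0]
        sub = self._family_seqs(seqs, fam)
        species_of = {g: g.split("_")[0] for g in sub}
        out = [g for g in sub if g.startswith("O_")][0]
        res, table = G.run_exclusion_series(
            sub, [("I", set()), ("II", set())], outgroup=out,
            species_of=species_of, replicates=30, seed=1)
        t1 = table[table.analysis == "I"].drop(columns="analysis")
        t2 = table[table.analysis == "II"].drop(columns="analysis")
        assert t1.reset_index(drop=True).equals(t2.reset_index(drop=True))

    def test_absent_taxon_warns(self, basal_family):
        truth, seqs, retained = basal_family
        fam = sorted(retained)[0]
        sub = self._family_seqs(seqs, fam)
        species_of = {g: g.split("_")[0] for g in sub}
        out = [g for g in sub if g.startswith("O_")][0]
        with pytest.warns(UserWarning, match="absent"):
            G.run_exclusion_series(sub, [("X", {"ZZZ"})], outgroup=out,
                                   species_of=species_of, replicates=10, seed=1)

    def test_excluding_outgroup_rejected(self, basal_family):
        truth, seqs, retained = basal_family
        fam = sorted(retained)[0]
        sub = self._family_seqs(seqs, fam)
        species_of = {g: g.split("_")[0] for g in sub}
        out = [g for g in sub if g.startswith("O_")][0]
        with pytest.raises(ValueError, match="outgroup"):
            G.run_exclusion_series(sub, [("X", {"O"})], outgroup=out,
                                   species_of=species_of)

    def test_basal_lineage_exclusion_restores_support(self, basal_family):
        """An early-diverging single-copy lineage depresses the duplication
        supports; pruning it makes the shared call supported — the
        basal-eudicot manoeuvre."""
        truth, seqs, retained = basal_family
        restored = 0
        examined = 0
        for fam in sorted(retained):
            sub = self._family_seqs(seqs, fam)
            species_of = {g: g.split("_")[0] for g in sub}
            out = [g for g in sub if g.startswith("O_")][0]
            res, _ = G.run_exclusion_series(
                sub, [("base", set()), ("noC", {"C"})], outgroup=out,
                species_of=species_of, replicates=100, seed=fam)

            def ok(calls):
                return any(c.supported and c.classification == "shared"
                           and {"A", "B"} <= c.shared_species for c in calls)

            if not ok(res["base"]):
                examined += 1
                if ok(res["noC"]):
                    restored += 1
        assert examined >= 5
        assert restored / examined >= 0.7


class TestNomenclature:
    def _tree(self, nwk):
        t = dendropy.Tree.get(data=nwk, schema="newick",
                              suppress_internal_node_taxa=True,
                              preserve_underscores=True)
        t.is_rooted = True
        return t

    def test_two_subfamily_naming(self):
        t = self._tree(
            "(((At_x:1,Vi_y:1):1,(At_z:1,Vi_w:1):1):1,Am_o:3);")
        result = G.assign_subfamily_names(
            t, {"At_x": 1, "At_z": 2}, family_prefix="VOZ")
        assert result.names["Vi_y"] == "Vi_VOZ1A"
        assert result.names["Vi_w"] == "Vi_VOZ2B"
        assert result.names["Am_o"] == "Am_VOZ"  # single-copy species, bare name

    def test_duplicated_species_letter_series(self):
        t = self._tree(
            "((((P_a:1,P_b:1):1,At_x:1):1,((P_c:1,P_d:1):1,At_z:1):1):1,Am_o:3);")
        result = G.assign_subfamily_names(
            t, {"At_x": 1, "At_z": 2}, family_prefix="VOZ")
        assert result.names["P_a"] == "P_VOZ1A"
        assert result.names["P_b"] == "P_VOZ1C"
        assert result.names["P_c"] == "P_VOZ2B"
        assert result.names["P_d"] == "P_VOZ2D"

    def test_names_unique_bijection(self):
        t = self._tree(
            "((((P_a:1,P_b:1):1,At_x:1):1,((P_c:1,P_d:1):1,At_z:1):1):1,Am_o:3);")
        result = G.assign_subfamily_names(t, {"At_x": 1, "At_z": 2}, "VOZ")
        assert len(set(result.names.values())) == len(result.names)
        assert not result.unclassified

    def test_gene_outside_anchor_clades_unclassified(self):
        t = self._tree("(((At_x:1,Vi_y:1):1,(At_z:1,Vi_w:1):1):1,(Am_o:1,Am_p:1):3);")
        result = G.assign_subfamily_names(t, {"At_x": 1, "At_z": 2}, "VOZ")
        assert result.unclassified == frozenset({"Am_o", "Am_p"})

    def test_missing_anchor_raises(self):
        t = self._tree("((A_x:1,B_y:1):1,C_o:2);")
        with pytest.raises(KeyError):
            G.assign_subfamily_names(t, {"Z_nope": 1}, "VOZ")
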