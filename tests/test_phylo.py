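"""Phylogeny: domain extraction, alignment, distances, NJ, bootstrap,
clade definition."""

import numpy as np
import pytest

from ltrcensus.families import Family, TECopy
from ltrcensus.phylo import (CladeCall, DomainSeq, PhyloParams, SupportTree, TreeNode,
                             align_domains, bipartitions, bootstrap_support,
                             define_clades, distance_matrix, extract_domain,
                             leaf_distances, neighbor_joining)


def random_additive_tree(n, rng):
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.1, 2.0))) for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        new = TreeNode(children=[nodes.pop(j), nodes.pop(i)],
                       length=float(rng.uniform(0.1, 2.0)))
        nodes.append(new)
    return TreeNode(children=nodes)


def tree_to_matrix(tree):
    pd = leaf_distances(tree)
    labels = sorted(tree.leaf_names())
    D = np.zeros((len(labels), len(labels)))
    for (a, b), v in pd.items():
        ia, ib = labels.index(a), labels.index(b)
        D[ia, ib] = D[ib, ia] = v
    return D, labels


class TestExtractDomain:
    def test_unmutated_family_yields_blueprint_translation(self, small_library):
        library, panel = small_library
        bp = library[0]
        fam = Family(bp.family_id, bp.species, bp.superfamily,
                     [TECopy("c0", bp.species, bp.superfamily, bp.element_seq)])
        dom, reason = extract_domain(fam, panel)
        assert reason == "ok"
        assert dom.aa_seq == bp.domain_aa

    def test_frameshift_spliced_into_chimeric_protein(self, small_library):
        library, panel = small_library
        bp = library[0]
        cs, ce = bp.cds_span
        shift_at = len(bp.ltr_seq) + cs + 3 * ((ce - cs) // 6)
        seq = bp.element_seq[:shift_at] + bp.element_seq[shift_at + 1:]  # 1 nt deletion
        fam = Family(bp.family_id, bp.species, bp.superfamily,
                     [TECopy("c0", bp.species, bp.superfamily, seq)])
        dom, reason = extract_domain(fam, panel)
        assert reason == "ok"
        assert len(dom.aa_seq) >= len(bp.domain_aa) - 2

    def test_domainless_family_excluded(self, rng):
        from ltrcensus.align import PanelEntry, ReferencePanel

        panel = ReferencePanel([PanelEntry("r", "MKLVWQERTYIPASDFGHKL" * 10, "Gypsy", "c1")])
        fam = Family("Gypsy-1_XX", "Sp", "Gypsy",
                     [TECopy("c0", "Sp", "Gypsy", "".join(rng.choice(list("ACGT"), 3000)))])
        dom, reason = extract_domain(fam, panel)
        assert dom is None and reason


class TestAlignDomains:
    def test_identical_sequences_gap_free(self):
        doms = [DomainSeq(f"f{i}", "Sp", "MKLVWQERTYIPASDFGHKL" * 5) for i in range(3)]
        msa = align_domains(doms)
        assert all("-" not in row for row in msa.values())

    def test_single_deletion_single_gap_column(self):
        base = "MKLVWQERTYIPASDFGHKL" * 5
        doms = [DomainSeq("a", "Sp", base), DomainSeq("b", "Sp", base),
                DomainSeq("c", "Sp", base[:40] + base[41:])]
        msa = align_domains(doms)
        assert sum(ch == "-" for ch in msa["c"]) == 1
        assert "-" not in msa["a"]
        assert len(msa["a"]) >= len(base)

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            align_domains([DomainSeq("a", "Sp", "MKLV")] * 2)


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        D, _ = distance_matrix({"a": "MKLV", "b": "MKLV"},
                               PhyloParams(model="p_distance"))
        assert D[0, 1] == 0.0

    def test_p_distance_arithmetic(self):
        a = "A" * 100
        b = "A" * 90 + "C" * 10
        D, _ = distance_matrix({"a": a, "b": b}, PhyloParams(model="p_distance"))
        assert D[0, 1] == pytest.approx(0.10)

    def test_pairwise_vs_complete_deletion(self):
        """The third row's gap removes a column only under complete deletion."""
        msa = {"a": "AAAAAAAACC", "b": "AAAAAAAAAA", "c": "-AAAAAAAAA"}
        params_p = PhyloParams(model="p_distance", deletion="pairwise")
        params_c = PhyloParams(model="p_distance", deletion="complete")
        Dp, _ = distance_matrix(msa, params_p)
        Dc, _ = distance_matrix(msa, params_c)
        assert Dp[0, 1] == pytest.approx(0.2)   # 2 diffs over 10 shared
        assert Dc[0, 1] == pytest.approx(2 / 9)  # first column removed globally

    def test_gamma_correction_monotone_and_exceeds_p(self):
        msa = {"a": "A" * 50, "b": "A" * 40 + "C" * 10}
        p = distance_matrix(msa, PhyloParams(model="p_distance"))[0][0, 1]
        g = distance_matrix(msa, PhyloParams(model="jtt_gamma"))[0][0, 1]
        assert g > p
        # shape 1 closed form: d = p / (1 - p)
        assert g == pytest.approx(p / (1 - p))

    def test_no_shared_columns_is_error(self):
        with pytest.raises(ValueError, match="no shared columns"):
            distance_matrix({"a": "MK--", "b": "--LV"}, PhyloParams())


class TestNeighborJoining:
    def test_four_taxon_exact_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) as path-length matrix
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = neighbor_joining(D, ["A", "B", "C", "D"])
        pd = leaf_distances(tree)
        for (i, a) in enumerate("ABCD"):
            for (j, b) in enumerate("ABCD"):
                if i < j:
                    assert pd[(a, b)] == pytest.approx(D[i, j], abs=1e-9)

    def test_three_taxon_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(D, ["A", "B", "C"])
        pd = leaf_distances(tree)
        assert pd[("A", "B")] == pytest.approx(3)
        assert pd[("A", "C")] == pytest.approx(4)
        assert pd[("B", "C")] == pytest.approx(5)

    def test_random_additive_matrices_recovered(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            t = random_additive_tree(n, rng)
            D, labels = tree_to_matrix(t)
            nj = neighbor_joining(D, labels)
            pd_true = leaf_distances(t)
            pd_nj = leaf_distances(nj)
            assert all(abs(pd_nj[k] - v) < 1e-8 for k, v in pd_true.items())
            assert set(bipartitions(t)) == set(bipartitions(nj))

    def test_matches_skbio_topology(self):
        """Cross-check against the independent scikit-bio implementation."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(4)
        for _ in range(10):
            t = random_additive_tree(int(rng.integers(4, 10)), rng)
            D, labels = tree_to_matrix(t)
            noisy = D + rng.uniform(0, 0.01, D.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0)
            mine = neighbor_joining(noisy, labels)
            theirs = skbio_nj(DistanceMatrix(noisy, labels))
            their_parts = set()
            ref = sorted(labels)[0]
            for node in theirs.non_tips():
                side = frozenset(t_.name for t_ in node.tips())
                if ref in side:
                    side = frozenset(labels) - side
                if 2 <= len(side) <= len(labels) - 2:
                    their_parts.add(side)
            assert set(bipartitions(mine)) == their_parts

    def test_perturbation_stability(self):
        rng = np.random.default_rng(15)
        t = random_additive_tree(8, rng)
        D, labels = tree_to_matrix(t)
        base_parts = set(bipartitions(neighbor_joining(D, labels)))
        for _ in range(5):
            eps = rng.uniform(-1e-7, 1e-7, D.shape)
            eps = (eps + eps.T) / 2
            np.fill_diagonal(eps, 0)
            parts = set(bipartitions(neighbor_joining(np.abs(D + eps), labels)))
            assert parts == base_parts

    def test_branch_lengths_nonnegative_on_nonadditive_input(self):
        rng = np.random.default_rng(33)
        D = rng.uniform(0.1, 1.0, (8, 8))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        tree = neighbor_joining(D, [f"x{i}" for i in range(8)])

        def walk(n):
            assert n.length >= 0
            for c in n.children:
                walk(c)
        walk(tree)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.array([[0, 1], [1, 0]], float), ["a", "b"])
        bad = np.array([[0, 1, 2], [1, 0, 3], [2, 4, 0]], float)  # asymmetric
        with pytest.raises(ValueError):
            neighbor_joining(bad, ["a", "b", "c"])


class TestBootstrap:
    def _saturated_msa(self):
        """Two 2-leaf groups separated by many diagnostic columns."""
        a = "A" * 60
        b = "A" * 58 + "CC"
        c = "W" * 60
        d = "W" * 58 + "YY"
        return {"a1": a, "a2": b, "c1": c, "c2": d}

    def test_saturated_signal_gives_full_support(self):
        st = bootstrap_support(self._saturated_msa(), PhyloParams(rng_seed=3))
        central = frozenset({"c1", "c2"})
        assert st.supports[central] == 100.0

    def test_same_seed_identical_supports(self):
        p = PhyloParams(rng_seed=11)
        s1 = bootstrap_support(self._saturated_msa(), p)
        s2 = bootstrap_support(self._saturated_msa(), p)
        assert s1.supports == s2.supports

    def test_supports_within_range_and_newick_wellformed(self):
        st = bootstrap_support(self._saturated_msa(), PhyloParams(rng_seed=1))
        assert all(0 <= v <= 100 for v in st.supports.values())
        nwk = st.newick()
        assert nwk.endswith(";") and nwk.count("(") == nwk.count(")")

    def test_identical_sequences_degenerate_but_deterministic(self):
        msa = {f"s{i}": "MKLV" * 10 for i in range(4)}
        p = PhyloParams(rng_seed=2)
        s1 = bootstrap_support(msa, p)
        s2 = bootstrap_support(msa, p)
        assert s1.supports == s2.supports


class TestDefineClades:
    def _make_stree(self, groups, supports):
        """Build a SupportTree from nested leaf groups with given supports."""
        children = []
        sup = {}
        all_leaves = sorted(l for g in groups for l in g)
        ref = all_leaves[0]
        for g, s in zip(groups, supports):
            node = TreeNode(children=[TreeNode(name=l, length=1.0) for l in g],
                            length=1.0, support=s)
            children.append(node)
            side = frozenset(g)
            if ref in side:
                side = frozenset(all_leaves) - side
            sup[side] = s
        return SupportTree(tree=TreeNode(children=children), supports=sup,
                           n_replicates=100)

    def test_supported_two_species_group_is_clade(self):
        st = self._make_stree([["f1", "f2"], ["g1", "g2"]], [85.0, 90.0])
        species = {"f1": "SpA", "f2": "SpB", "g1": "SpA", "g2": "SpB"}
        calls, other = define_clades(st, species, PhyloParams())
        assert len(calls) == 2 and other == []

    def test_low_support_needs_override(self):
        st = self._make_stree([["f1", "f2"], ["g1", "g2"], ["h1", "h2"]],
                              [66.0, 90.0, 95.0])
        species = {"f1": "SpA", "f2": "SpB", "g1": "SpA", "g2": "SpB",
                   "h1": "SpA", "h2": "SpB"}
        calls, other = define_clades(st, species, PhyloParams())
        assert all(set(c.members) != {"f1", "f2"} for c in calls)
        assert any(set(c.members) == {"g1", "g2"} for c in calls)
        calls2, _ = define_clades(st, species, PhyloParams(),
                                  overrides={"MolGy12like": frozenset({"f1", "f2"})})
        assert any(set(c.members) == {"f1", "f2"} for c in calls2)

    def test_single_species_group_rejected(self):
        st = self._make_stree([["f1", "f2"], ["g1", "g2"]], [95.0, 95.0])
        species = {"f1": "SpA", "f2": "SpA", "g1": "SpA", "g2": "SpB"}
        calls, other = define_clades(st, species, PhyloParams())
        assert {tuple(c.members) for c in calls} == {("g1", "g2")}
        assert set(other) == {"f1", "f2"}

    def test_member_counts_conserve_total(self, small_library):
        """Clade members plus 'other' partition the family leaves."""
        from ltrcensus.phylo import align_domains

        library, panel = small_library
        domains = [DomainSeq(bp.family_id, bp.species, bp.domain_aa) for bp in library]
        refs = [DomainSeq(e.entry_id, "ref", e.aa_seq) for e in panel.entries]
        msa = align_domains(domains + refs)
        st = bootstrap_support(msa, PhyloParams(rng_seed=9))
        species_of = {d.family_id: d.species for d in domains}
        ref_labels = {e.entry_id: e.clade for e in panel.entries}
        calls, other = define_clades(st, species_of, PhyloParams(rng_seed=9),
                                     reference_clades=ref_labels)
        claimed = [m for c in calls for m in c.members]
        assert sorted(claimed + other) == sorted(species_of)
        assert len(claimed) == len(set(claimed))

    def test_planted_clades_recovered_exactly(self, small_library):
        from ltrcensus.phylo import align_domains

        library, panel = small_library
        domains = [DomainSeq(bp.family_id, bp.species, bp.domain_aa) for bp in library]
        refs = [DomainSeq(e.entry_id, "ref", e.aa_seq) for e in panel.entries]
        msa = align_domains(domains + refs)
        st = bootstrap_support(msa, PhyloParams(rng_seed=13))
        species_of = {d.family_id: d.species for d in domains}
        ref_labels = {e.entry_id: e.clade for e in panel.entries}
        calls, other = define_clades(st, species_of, PhyloParams(rng_seed=13),
                                     reference_clades=ref_labels)
        want = {}
        for bp in library:
            want.setdefault(bp.clade_id, set()).add(bp.family_id)
        got = {c.name: set(c.members) for c in calls}
        assert got == want and other == []
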