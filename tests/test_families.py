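"""Family building: the 80-80-80 comparator, clustering, curation,
merging, orphan promotion."""

import numpy as np
import pytest

from ltrcensus.families import (DiscardRecord, Family, FamilyParams, TECopy,
                                build_families, cluster_copies, cluster_consensus,
                                curate_cluster, merge_clusters, name_families,
                                passes_80_80_80, promote_orphans)
from ltrcensus.simulate import mutate_sequence


def _copies_from(library, rng, per_family=4, sub_rate=0.04):
    out = []
    for bp in library:
        for i in range(per_family):
            seq = mutate_sequence(bp.element_seq, sub_rate, rng=rng)
            out.append(TECopy(f"{bp.family_id}:c{i}", bp.species, bp.superfamily, seq))
    return out


class TestPasses808080:
    def test_identical_sequences(self):
        a = "ACGT" * 1250
        ok, ident, cols, (fa, fb) = passes_80_80_80(a, a)
        assert ok and ident == 100.0 and cols == 5000
        assert fa == fb == 100.0

    def test_substitution_boundary(self):
        """15% substitutions pass, 25% fail the identity clause."""
        a = "".join(np.random.default_rng(1).choice(list("ACGT"), 5000))
        ok15 = passes_80_80_80(a, mutate_sequence(a, 0.15, seed=2))[0]
        ok25 = passes_80_80_80(a, mutate_sequence(a, 0.25, seed=2))[0]
        assert ok15 and not ok25

    def test_fragment_fails_length_fraction(self):
        a = "".join(np.random.default_rng(3).choice(list("ACGT"), 5000))
        ok, ident, cols, (fa, fb) = passes_80_80_80(a, a[:1000])
        assert not ok
        assert ident > 99 and min(fa, fb) <= 21

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        a = "".join(rng.choice(list("ACGT"), 2000))
        b = mutate_sequence(a, 0.1, seed=5)[:1500]
        assert passes_80_80_80(a, b)[0] == passes_80_80_80(b, a)[0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            passes_80_80_80("", "ACGT")


class TestClusterCopies:
    def test_single_linkage_transitivity(self):
        """a~b and b~c with a!~c still makes one cluster."""
        rng = np.random.default_rng(6)
        a = "".join(rng.choice(list("ACGT"), 3000))
        b = mutate_sequence(a, 0.12, seed=1)   # a~b at ~88%
        c = mutate_sequence(b, 0.12, seed=2)   # b~c; a-c ~ 78% (below 80)
        assert not passes_80_80_80(a, c)[0]
        assert passes_80_80_80(a, b)[0] and passes_80_80_80(b, c)[0]
        copies = [TECopy(n, "Sp", "Gypsy", s) for n, s in (("a", a), ("b", b), ("c", c))]
        clusters = cluster_copies(copies)
        assert len(clusters) == 1 and len(clusters[0]) == 3

    def test_dissimilar_copies_stay_apart(self, rng):
        copies = [TECopy(f"x{i}", "Sp", "Gypsy", "".join(rng.choice(list("ACGT"), 2000)))
                  for i in range(4)]
        assert len(cluster_copies(copies)) == 4

    def test_planted_families_recovered(self, small_library, rng):
        library, _ = small_library
        copies = _copies_from(library, rng, per_family=4)
        clusters = cluster_copies(copies)
        assert len(clusters) == len(library)
        for cl in clusters:
            assert len({c.copy_id.split(":")[0] for c in cl}) == 1

    def test_partition_property_and_order_invariance(self, small_library, rng):
        library, _ = small_library
        copies = _copies_from(library[:4], rng, per_family=3)
        clusters = cluster_copies(copies)
        ids = sorted(c.copy_id for cl in clusters for c in cl)
        assert ids == sorted(c.copy_id for c in copies)
        shuffled = list(copies)
        np.random.default_rng(9).shuffle(shuffled)
        clusters2 = cluster_copies(shuffled)
        as_sets = lambda cls: sorted(tuple(sorted(c.copy_id for c in cl)) for cl in cls)
        assert as_sets(clusters) == as_sets(clusters2)


class TestCuration:
    def test_nested_insertion_excised(self, small_library):
        library, _ = small_library
        base = library[0].element_seq
        guest = library[3].element_seq[:500]
        nested = base[:2000] + guest + base[2000:]
        seqs = {"host": nested, "m1": base, "m2": base, "m3": base}
        curated = curate_cluster(seqs)
        assert curated["host"] == base

    def test_short_private_insertion_kept(self, small_library):
        library, _ = small_library
        base = library[0].element_seq[:3000]
        with_15bp = base[:1500] + "ACGTACGTACGTACG" + base[1500:]
        curated = curate_cluster({"a": base, "b": with_15bp, "c": base})
        assert len(curated["b"]) == len(base) + 15

    def test_identical_members_unchanged(self, small_library):
        base = small_library[0][0].element_seq
        curated = curate_cluster({"a": base, "b": base, "c": base})
        assert all(v == base for v in curated.values())

    def test_singleton_returned_unchanged(self):
        assert curate_cluster({"only": "ACGTACGT"}) == {"only": "ACGTACGT"}

    def test_consensus_cleans_private_decay(self, small_library, rng):
        from ltrcensus.families import run_mafft

        base = small_library[0][0].element_seq
        members = {f"m{i}": mutate_sequence(base, 0.02, rng=rng) for i in range(5)}
        cons = cluster_consensus(run_mafft(members))
        from ltrcensus.align import global_identity

        assert global_identity(cons, base) > 99.0


class TestMergeClusters:
    def _cluster(self, name, seq, n=2, species="Sp", sf="Gypsy"):
        return [TECopy(f"{name}{i}", species, sf, seq) for i in range(n)]

    def test_high_identity_clusters_merge(self, rng):
        a = "".join(rng.choice(list("ACGT"), 3000))
        b = mutate_sequence(a, 0.10, seed=3)  # ~85% after alignment wobble
        merged = merge_clusters([self._cluster("a", a), self._cluster("b", b)])
        assert len(merged) == 1

    def test_low_identity_clusters_stay(self, rng):
        a = "".join(rng.choice(list("ACGT"), 3000))
        b = "".join(rng.choice(list("ACGT"), 3000))
        merged = merge_clusters([self._cluster("a", a), self._cluster("b", b)])
        assert len(merged) == 2

    def test_idempotent(self, rng):
        a = "".join(rng.choice(list("ACGT"), 3000))
        clusters = [self._cluster("a", a), self._cluster("b", mutate_sequence(a, 0.1, seed=1)),
                    self._cluster("c", "".join(rng.choice(list("ACGT"), 3000)))]
        once = merge_clusters(clusters)
        twice = merge_clusters(once)
        key = lambda cls: sorted(tuple(sorted(c.copy_id for c in cl)) for cl in cls)
        assert key(once) == key(twice)


class TestOrphans:
    def test_intact_domain_promoted(self, small_library):
        library, panel = small_library
        orphan = TECopy("orph1", "SpA", "Gypsy", library[0].element_seq)
        fams, discards = promote_orphans([orphan], panel)
        assert len(fams) == 1 and fams[0].origin == "orphan"
        assert fams[0].domain_aa and "*" not in fams[0].domain_aa
        assert discards == []

    def test_midframe_stop_discarded(self, small_library):
        library, panel = small_library
        bp = library[0]
        cs, ce = bp.cds_span
        off = len(bp.ltr_seq) + cs
        mid = off + 3 * ((ce - cs) // 6)
        seq = bp.element_seq[:mid] + "TGA" + bp.element_seq[mid + 3:]
        fams, discards = promote_orphans([TECopy("orph2", "SpA", "Gypsy", seq)], panel)
        assert fams == []
        assert len(discards) == 1 and "stop" in discards[0].reason

    def test_empty_input(self, small_library):
        _, panel = small_library
        assert promote_orphans([], panel) == ([], [])


class TestFamilyModel:
    def test_representative_is_longest_member(self):
        fam = Family("Gypsy-1_XX", "Sp", "Gypsy",
                     [TECopy("a", "Sp", "Gypsy", "ACGT" * 10),
                      TECopy("b", "Sp", "Gypsy", "ACGT" * 20)])
        assert fam.representative.copy_id == "b"

    def test_mixed_species_rejected(self):
        with pytest.raises(ValueError):
            Family("f", "Sp1", "Gypsy", [TECopy("a", "Sp1", "Gypsy", "ACGT"),
                                         TECopy("b", "Sp2", "Gypsy", "ACGT")])

    def test_naming_convention(self):
        fams = name_families([[TECopy("a", "SpA", "Gypsy", "ACGT" * 30)],
                              [TECopy("b", "SpA", "Gypsy", "ACGT" * 30)]])
        assert [f.family_id for f in fams] == ["Gypsy-1_SA", "Gypsy-2_SA"]

    def test_build_families_end_to_end(self, small_library, rng):
        library, panel = small_library
        copies = _copies_from(library, rng, per_family=3, sub_rate=0.03)
        fams, discards = build_families(copies, panel)
        assert len(fams) == len(library)
        for f in fams:
            planted = {m.copy_id.split(":")[0] for m in f.members}
            assert len(planted) == 1
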