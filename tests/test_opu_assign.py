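"""OPU classification and merging: the three-way decision rule, anchor
selection, clade-connectivity merging, and category tallies."""

import io

import numpy as np
import pytest
from skbio import TreeNode

import opucall as oc
from opucall.opu_assign import (
    CULTURED_SPECIES,
    NEW_SPECIES,
    NEW_TAXON,
    Classification,
    Opu,
    RankThresholds,
    category_tally,
    classify_otu,
    merge_otus_to_opus,
    nearest_type_strain,
)
from opucall.otu_cluster import Otu
from opucall.phylo_place import PlacementParams, build_joint_tree
from opucall.seq_io import SeqRecord


def _tree(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


def _otu(otu_id: str, rep_id: str, seq: str, count: int = 5) -> Otu:
    return Otu(otu_id=otu_id, members=[SeqRecord(rep_id, seq, count=count)])


class TestRankThresholds:
    def test_floors_decrease_with_rank_height(self):
        t = RankThresholds()
        assert t.genus > t.family > t.order > t.class_ > t.phylum

    def test_inverted_floors_rejected(self):
        with pytest.raises(ValueError):
            RankThresholds(genus=0.80, family=0.86)


class TestNearestTypeStrain:
    def test_identical_representative(self, refdb):
        e = list(refdb)[0]
        acc, ident = nearest_type_strain(SeqRecord("r", e.seq), refdb)
        assert (acc, ident) == (e.accession, 1.0)

    def test_argmax_over_references(self, refdb, rng):
        e = list(refdb)[3]
        rep = oc.mutate_to_identity(e.seq, 0.97, rng)
        acc, ident = nearest_type_strain(SeqRecord("r", rep), refdb)
        assert acc == e.accession
        assert ident == pytest.approx(0.97, abs=1e-3)

    def test_tie_breaks_to_smaller_accession(self, refdb, rng):
        # equidistant from two strains by construction: mutate the midpoint
        from opucall.seq_io import Lineage, RefEntry, ReferenceDB

        base = "".join(rng.choice(list("ACGT"), 1000))
        lineage = Lineage("G", "F", "O", "C", "P")
        db = ReferenceDB(
            [
                RefEntry("TSA", "sp A", lineage, base),
                RefEntry("TSB", "sp B", lineage, base),
            ]
        )
        rep = oc.mutate_to_identity(base, 0.95, rng)
        acc, ident = nearest_type_strain(SeqRecord("r", rep), db)
        assert acc == "TSA" and ident == pytest.approx(0.95)


class TestClassifyOtu:
    def test_species_threshold_wins_regardless_of_placement(self, refdb, rng):
        e = list(refdb)[0]
        rep = SeqRecord("rep1", oc.mutate_to_identity(e.seq, 0.995, rng))
        # the rep is not even a leaf of this tree: rule (1) must not care
        tree = _tree("(TS0001:0.1,TS0002:0.1,TS0003:0.1);")
        cls = classify_otu(rep, tree, refdb)
        assert cls.category == CULTURED_SPECIES
        assert cls.anchor_taxon == e.species_name
        assert cls.nearest_identity >= 0.987

    def test_novel_species_anchored_to_genus(self, refdb, rng):
        parent = list(refdb)[0]
        rep = SeqRecord("rep1", oc.mutate_to_identity(parent.seq, 0.96, rng))
        tree = build_joint_tree([rep], refdb, PlacementParams(knn_refs=len(refdb)))
        cls = classify_otu(rep, tree, refdb)
        assert cls.category == NEW_SPECIES
        assert cls.anchor_rank == "genus"
        assert cls.anchor_taxon == parent.lineage.genus

    def test_deep_lineage_becomes_new_taxon(self, refdb, rng):
        from opucall.synth import _consensus

        entries = [e for e in refdb if e.lineage.phylum == "Phylum1"]
        anc = _consensus([e.seq for e in entries])
        rep = SeqRecord("rep1", oc.mutate_to_identity(anc, 0.85, rng))
        tree = build_joint_tree([rep], refdb, PlacementParams(knn_refs=len(refdb)))
        cls = classify_otu(rep, tree, refdb)
        assert cls.category == NEW_TAXON
        assert cls.anchor_rank in ("family", "order", "class", "phylum")

    def test_missing_leaf_rejected_for_sub_threshold_rep(self, refdb, rng):
        rep = SeqRecord("ghost", oc.mutate_to_identity(list(refdb)[0].seq, 0.95, rng))
        tree = _tree("(TS0001:0.1,TS0002:0.1,TS0003:0.1);")
        with pytest.raises(ValueError, match="ghost"):
            classify_otu(rep, tree, refdb)

    def test_identity_perturbation_flips_category(self, refdb, rng):
        """Raising a planted novel species' identity from 0.97 to 0.99 flips
        the call to the cultured species."""
        parent = list(refdb)[0]
        calls = {}
        for target in (0.97, 0.99):
            rep = SeqRecord("rep1", oc.mutate_to_identity(parent.seq, target, rng))
            tree = build_joint_tree([rep], refdb, PlacementParams(knn_refs=len(refdb)))
            calls[target] = classify_otu(rep, tree, refdb).category
        assert calls == {0.97: NEW_SPECIES, 0.99: CULTURED_SPECIES}


class TestMergeOtus:
    def _cls(self, category, rank, anchor, acc, ident):
        return Classification(category, rank, anchor, acc, ident)

    def test_same_species_adjacent_otus_merge(self, refdb):
        e = list(refdb)[0]
        tree = _tree(
            "((q1:0.001,q2:0.001,TS0001:0.001):0.05,TS0002:0.05,TS0004:0.1);"
        )
        classified = [
            (
                _otu("OTU_1", "q1", e.seq, count=10),
                self._cls(CULTURED_SPECIES, "species", e.species_name, "TS0001", 0.995),
            ),
            (
                _otu("OTU_2", "q2", e.seq, count=4),
                self._cls(CULTURED_SPECIES, "species", e.species_name, "TS0001", 0.99),
            ),
        ]
        opus = merge_otus_to_opus(classified, tree, refdb)
        assert len(opus) == 1
        assert opus[0].member_otu_ids == ["OTU_1", "OTU_2"]
        assert opus[0].total_count == 14

    def test_disjoint_subclades_stay_separate(self, refdb):
        """Two OTUs with the same genus anchor but separated by a reference
        of another genus are distinct OPUs."""
        e = list(refdb)[0]
        genus = e.lineage.genus
        # TS0004 belongs to a different genus and splits the two queries
        tree = _tree(
            "((q1:0.01,TS0001:0.01):0.02,(q2:0.01,TS0004:0.01):0.02,TS0002:0.05);"
        )
        classified = [
            (
                _otu("OTU_1", "q1", e.seq),
                self._cls(NEW_SPECIES, "genus", genus, "TS0001", 0.96),
            ),
            (
                _otu("OTU_2", "q2", e.seq),
                self._cls(NEW_SPECIES, "genus", genus, "TS0002", 0.955),
            ),
        ]
        opus = merge_otus_to_opus(classified, tree, refdb)
        assert len(opus) == 2

    def test_distinct_lineages_in_one_genus_stay_separate(self, refdb):
        """Two novel lineages with their parent strains between them are not
        one new species."""
        e1, e2 = list(refdb)[0], list(refdb)[1]
        assert e1.lineage.genus == e2.lineage.genus
        tree = _tree(
            "((q1:0.01,TS0001:0.01):0.02,(q2:0.01,TS0002:0.01):0.02,TS0003:0.05);"
        )
        classified = [
            (
                _otu("OTU_1", "q1", e1.seq),
                self._cls(NEW_SPECIES, "genus", e1.lineage.genus, "TS0001", 0.96),
            ),
            (
                _otu("OTU_2", "q2", e2.seq),
                self._cls(NEW_SPECIES, "genus", e2.lineage.genus, "TS0002", 0.96),
            ),
        ]
        assert len(merge_otus_to_opus(classified, tree, refdb)) == 2

    def test_distinct_anchors_distinct_opus(self, refdb):
        tree = _tree("(q1:0.1,q2:0.1,q3:0.1);")
        entries = list(refdb)[:3]
        classified = [
            (
                _otu(f"OTU_{i}", f"q{i}", e.seq),
                self._cls(CULTURED_SPECIES, "species", e.species_name, e.accession, 0.99),
            )
            for i, e in enumerate(entries, 1)
        ]
        opus = merge_otus_to_opus(classified, tree, refdb)
        assert len(opus) == 3
        assert sum(len(o.member_otu_ids) for o in opus) == 3


class TestCategoryTally:
    def _opus(self, n_cult, n_ns, n_nt, count=10):
        opus = []
        for i in range(n_cult):
            opus.append(
                Opu(f"OPU_c{i}", [f"OTU_c{i}"], CULTURED_SPECIES, "species",
                    f"sp{i}", "TS0001", 0.99, count)
            )
        for i in range(n_ns):
            opus.append(
                Opu(f"OPU_s{i}", [f"OTU_s{i}"], NEW_SPECIES, "genus",
                    f"G{i}", "TS0001", 0.96, count)
            )
        for i in range(n_nt):
            opus.append(
                Opu(f"OPU_t{i}", [f"OTU_t{i}"], NEW_TAXON, "family",
                    f"F{i}", "TS0001", 0.88, count)
            )
        return opus

    def test_survey_scale_unknown_fraction(self):
        tally = category_tally(self._opus(796, 784, 151))
        assert (tally["cultured"], tally["new_species"], tally["new_taxon"]) == (
            796,
            784,
            151,
        )
        assert round(100 * tally["unknown_fraction"], 1) == 54.0

    def test_all_cultured_shares(self):
        tally = category_tally(self._opus(5, 0, 0))
        assert tally["read_share"] == {"cultured": 1.0, "new_species": 0.0, "new_taxon": 0.0}

    def test_invariants_on_opu_construction(self):
        with pytest.raises(ValueError):
            Opu("x", ["a"], CULTURED_SPECIES, "species", "sp", "TS", 0.95, 1)
        with pytest.raises(ValueError):
            Opu("x", ["a"], NEW_SPECIES, "family", "F", "TS", 0.96, 1)
        with pytest.raises(ValueError):
            Opu("x", ["a"], "WEIRD", "species", "sp", "TS", 0.99, 1)
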