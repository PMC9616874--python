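"""V4 extraction, alignment identity, neighbor joining, and isolate-Zotu matching."""

import numpy as np
import pytest

from oracles import random_additive_tree
from wellnet.matching import (
    DistanceMatrix,
    NoAmpliconError,
    V4_FWD_PRIMER,
    V4_REV_PRIMER,
    enumerate_combinations,
    extract_v4,
    match_isolates,
    nj_tree,
    p_distance_matrix,
    pairwise_identity,
    revcomp,
    tree_tip_distances,
    unmatched_zotus,
)


def amplicon(insert, fwd=V4_FWD_PRIMER, rev=V4_REV_PRIMER, left="", right=""):
    return left + fwd + insert + revcomp(rev) + right


class TestExtractV4:
    def test_constructed_amplicon_returns_insert_exactly(self):
        insert = "ACGT" * 60
        assert extract_v4(amplicon(insert, left="TT" * 30, right="GG" * 25)) == insert

    def test_missing_reverse_site_is_no_amplicon(self):
        with pytest.raises(NoAmpliconError, match="reverse"):
            extract_v4(V4_FWD_PRIMER + "ACGT" * 50)

    def test_one_mismatch_within_budget_still_extracts(self):
        fwd = list(V4_FWD_PRIMER)
        fwd[5] = "A" if fwd[5] != "A" else "G"
        seq = "".join(fwd) + "ACGTAA" * 20 + revcomp(V4_REV_PRIMER)
        assert extract_v4(seq, max_mismatch=1) == "ACGTAA" * 20
        with pytest.raises(NoAmpliconError):
            extract_v4(seq, max_mismatch=0)

    def test_degenerate_primer_bases_match_all_expansions(self):
        # 515F starts GTGY...: Y covers C and T
        for base in "CT":
            seq = ("GTG" + base + V4_FWD_PRIMER[4:]) + "ACGTACGT" * 10 + revcomp(V4_REV_PRIMER)
            assert extract_v4(seq, max_mismatch=0) == "ACGTACGT" * 10

    def test_multiple_forward_hits_use_leftmost_with_warning(self):
        insert = "AAAATTTTCCCC" * 10
        seq = V4_FWD_PRIMER + insert[:24] + V4_FWD_PRIMER + insert + revcomp(V4_REV_PRIMER)
        with pytest.warns(UserWarning, match="leftmost"):
            out = extract_v4(seq)
        assert out == insert[:24] + V4_FWD_PRIMER + insert

    def test_extracted_insert_is_identical_to_original(self):
        rng = np.random.default_rng(0)
        insert = "".join(rng.choice(list("ACGT"), 250))
        assert pairwise_identity(extract_v4(amplicon(insert)), insert) == 1.0


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        seq = "ACGT" * 60
        assert pairwise_identity(seq, seq) == 1.0

    def test_single_substitution_over_four_columns(self):
        # optimal global alignment has 4 columns, 3 matches
        assert pairwise_identity("ACGT", "ACGA") == pytest.approx(0.75)

    def test_symmetry_on_scrambled_sequences(self, rng):
        a = "".join(rng.choice(list("ACGT"), 80))
        b = "".join(rng.choice(list("ACGT"), 70))
        assert pairwise_identity(a, b) == pairwise_identity(b, a)
        assert pairwise_identity(a, b) < 1.0

    def test_gapped_alignment_counts_columns(self):
        # deletion of 2 nt: best alignment has 10 columns, 8 matches
        assert pairwise_identity("AACCGGTTAA", "AACCGGTT") == pytest.approx(0.8)


class TestNeighborJoining:
    def test_hand_worked_four_taxon_additive_matrix(self):
        labels = ("A", "B", "C", "D")
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(labels, d))
        tips = {t.name: t for t in tree.tips()}
        assert tips["A"].length == pytest.approx(1.0)
        assert tips["B"].length == pytest.approx(2.0)
        assert tips["C"].length == pytest.approx(3.0)
        assert tips["D"].length == pytest.approx(4.0)
        # topology AB|CD: A and B are siblings
        assert tips["A"].parent is tips["B"].parent
        # the internal edge has length 1
        internal = tips["A"].parent
        assert internal.length == pytest.approx(1.0)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(("x", "y", "z"), d))
        tips = {t.name: t.length for t in tree.tips()}
        # three-point equations: lx = (2+3-5)/2 = 0, ly = 2, lz = 3
        assert tips["x"] == pytest.approx(0.0)
        assert tips["y"] == pytest.approx(2.0)
        assert tips["z"] == pytest.approx(3.0)

    def test_ultrametric_matrix_reproduced_by_path_lengths(self):
        labels = ("a", "b", "c", "d")
        d = np.array(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(labels, d))
        td = tree_tip_distances(tree)
        idx = [td.labels.index(l) for l in labels]
        np.testing.assert_allclose(td.values[np.ix_(idx, idx)], d, atol=1e-9)

    @pytest.mark.parametrize("n_taxa", [4, 6, 9, 12])
    def test_recovers_random_additive_trees(self, n_taxa, rng):
        for _ in range(5):
            true_tree, labels, d = random_additive_tree(n_taxa, rng)
            built = nj_tree(DistanceMatrix(tuple(labels), d))
            td = tree_tip_distances(built)
            idx = [td.labels.index(l) for l in labels]
            np.testing.assert_allclose(td.values[np.ix_(idx, idx)], d, atol=1e-9)
            rf = built.compare_rfd(true_tree)
            assert rf == 0.0

    def test_agrees_with_reference_nj_on_additive_matrix(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        _, labels, d = random_additive_tree(8, rng)
        ours = nj_tree(DistanceMatrix(tuple(labels), d))
        theirs = skbio_nj(SkbioDM(d, ids=labels))
        assert ours.compare_rfd(theirs) == 0.0

    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b", "c"), bad)


class TestMatchIsolates:
    def seqs(self, rng, n_zotus=4, length=120):
        return {f"Zotu{i+1}": "".join(rng.choice(list("ACGT"), length)) for i in range(n_zotus)}

    def test_identical_v4_matches_with_identity_one(self, rng):
        zotus = self.seqs(rng)
        isolates = {"ISO-1": zotus["Zotu2"], "ISO-2": zotus["Zotu4"]}
        matches = {m.isolate_id: m for m in match_isolates(zotus, isolates)}
        assert matches["ISO-1"].zotu_id == "Zotu2" and matches["ISO-1"].v4_identity == 1.0
        assert matches["ISO-2"].zotu_id == "Zotu4" and matches["ISO-2"].matched

    def test_near_match_falls_back_to_tree_within_cap(self, rng):
        zotus = self.seqs(rng, length=200)
        v4 = list(zotus["Zotu1"])
        v4[10] = "A" if v4[10] != "A" else "C"  # one substitution: identity 0.995
        matches = match_isolates(zotus, {"ISO-1": "".join(v4)}, distance_cap=0.03)
        m = matches[0]
        assert m.matched and m.zotu_id == "Zotu1"
        assert m.v4_identity < 1.0

    def test_distant_isolate_stays_unmatched_and_zotu_reported(self, rng):
        zotus = self.seqs(rng)
        stranger = "".join(rng.choice(list("ACGT"), 120))
        matches = match_isolates(zotus, {"ISO-9": stranger}, distance_cap=0.03)
        assert matches[0].matched is False
        assert set(unmatched_zotus(sorted(zotus), matches)) == set(zotus)

    def test_input_order_invariance(self, rng):
        zotus = self.seqs(rng)
        isolates = {"ISO-1": zotus["Zotu1"], "ISO-2": zotus["Zotu3"]}
        a = match_isolates(zotus, isolates)
        b = match_isolates(dict(reversed(list(zotus.items()))), dict(reversed(list(isolates.items()))))
        assert a == b


class TestEnumerateCombinations:
    def test_shared_representative_set_gives_n_choose_2(self):
        reps = {"ZotuX": ["i1", "i2", "i3", "i4"], "ZotuY": ["i1", "i2", "i3", "i4"]}
        combos = enumerate_combinations(("ZotuX", "ZotuY"), reps)
        assert len(combos) == 6

    def test_disjoint_sets_give_cartesian_product(self):
        reps = {"ZotuX": ["i1", "i2", "i3", "i4"], "ZotuY": ["j1", "j2"]}
        assert len(enumerate_combinations(("ZotuX", "ZotuY"), reps)) == 8
        reps = {"ZotuX": ["i1", "i2", "i3", "i4"], "ZotuY": ["j1", "j2", "j3", "j4"]}
        assert len(enumerate_combinations(("ZotuX", "ZotuY"), reps)) == 16

    def test_overlapping_sets_deduplicate_and_drop_self_pairs(self):
        reps = {"ZotuX": ["i1", "i2", "i3"], "ZotuY": ["i2", "i3", "j1"]}
        combos = enumerate_combinations(("ZotuX", "ZotuY"), reps)
        assert all(a != b for a, b in combos)
        assert len(combos) == len(set(combos))
        # cross pairs: {i1,i2},{i1,i3},{i1,j1},{i2,i3},{i2,j1},{i3,j1}
        assert len(combos) == 6

    def test_empty_representative_set_names_the_zotu(self):
        with pytest.raises(ValueError, match="ZotuY"):
            enumerate_combinations(("ZotuX", "ZotuY"), {"ZotuX": ["i1"]})


def test_p_distance_matrix_is_valid_and_zero_on_duplicates(rng):
    a = "".join(rng.choice(list("ACGT"), 60))
    dm = p_distance_matrix({"s1": a, "s2": a, "s3": a[:30] + a[:30]})
    assert dm.values[0, 1] == 0.0
    assert dm.values[0, 2] > 0.0
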