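"""Semiglobal alignment, hit filtering, LCA assignment, taxon profiles."""

import numpy as np
import pandas as pd
import pytest

from sedadna.align import (
    Assignment,
    TaxonProfile,
    UNASSIGNED,
    align_read,
    assign_read,
    build_profile,
    filter_hits,
    project_rank,
    semiglobal_align,
)
from sedadna.taxonomy import ReferenceSequence, TaxonNode, TaxonomyTree, revcomp

from .conftest import make_read, random_seq
from .oracles import assign_oracle, best_score_all_refs, semiglobal_score


def _mutate(seq, positions, rng=None):
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    out = list(seq)
    for p in positions:
        out[p] = flip[out[p]]
    return "".join(out)


class TestSemiglobalAlign:
    def test_exact_substring(self, toy_refs):
        ref = toy_refs.sequences["SSU_t12"].sequence
        read = make_read(ref[80:140], "q")
        hits = align_read(read, toy_refs)
        assert hits and hits[0].ref_id == "SSU_t12"
        h = hits[0]
        assert h.identity == 1.0 and h.score == 60 and h.strand == "+"
        assert h.matches + len(h.mismatches) + h.gaps == h.columns

    def test_single_substitution_position_and_identity(self, toy_refs):
        ref = toy_refs.sequences["SSU_t13"].sequence
        window = ref[50:110]
        read = make_read(_mutate(window, [30]), "q")
        h = align_read(read, toy_refs)[0]
        assert h.identity == pytest.approx(59 / 60)
        assert len(h.mismatches) == 1
        pos, ref_base, read_base = h.mismatches[0]
        assert pos == 30 and ref_base == window[30] and read_base == read.sequence[30]
        # score agrees with the exhaustive oracle
        refs = {r.ref_id: r.sequence for r in toy_refs.sequences.values()}
        assert h.score == best_score_all_refs(read.sequence, refs)[0]

    def test_minus_strand_mismatch_coordinates(self, toy_refs):
        """5' C→T damage on the template surfaces as G→A at the read 3'
        when the read aligns on the minus strand."""
        ref = toy_refs.sequences["SSU_t15"].sequence
        start = ref.find("C", 60)
        window = ref[start : start + 60]
        damaged = "T" + window[1:]          # C→T at template 5' position 0
        read = make_read(revcomp(damaged), "q")
        h = align_read(read, toy_refs)[0]
        assert h.strand == "-"
        assert len(h.mismatches) == 1
        pos, ref_base, read_base = h.mismatches[0]
        assert pos == 59 and (ref_base, read_base) == ("G", "A")

    def test_no_shared_kmer_no_hits(self, toy_refs):
        # Alternating AC shares no 12-mer with random references
        assert align_read(make_read("AC" * 20, "q"), toy_refs) == []

    def test_read_shorter_than_seed_warns(self, toy_refs):
        with pytest.warns(UserWarning, match="shorter"):
            assert align_read(make_read("ACGTACGT", "q"), toy_refs) == []

    def test_gapped_alignment_accounting(self):
        raw = semiglobal_align("ACGTACGT", "TTTACGTTACGTTTT")
        assert raw.matches + len(raw.mismatches) + raw.gaps >= 8
        assert raw.score == semiglobal_score("ACGTACGT", "TTTACGTTACGTTTT")

    @pytest.mark.parametrize("n_subs", [0, 1, 2])
    def test_seeded_score_equals_full_dp_oracle(self, toy_refs, n_subs):
        rng = np.random.default_rng(100 + n_subs)
        refs = {r.ref_id: r.sequence for r in toy_refs.sequences.values()}
        ids = list(refs)
        for _ in range(40):
            ref_id = ids[int(rng.integers(0, len(ids)))]
            L = int(rng.integers(36, 81))
            start = int(rng.integers(0, 300 - L + 1))
            window = refs[ref_id][start : start + L]
            subs = rng.choice(L, size=n_subs, replace=False)
            seq = _mutate(window, subs)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            hits = align_read(make_read(seq, "q"), toy_refs)
            assert hits, "seed guaranteed by <=1 substitution per 13 bp"
            assert hits[0].score == best_score_all_refs(seq, refs)[0]


class TestFilterHits:
    def _hit(self, score, identity, ref_id="r"):
        columns = 100
        matches = int(round(identity * columns))
        mm = tuple((i, "A", "C") for i in range(columns - matches))
        from sedadna.align import AlignmentHit

        return AlignmentHit("q", ref_id, 12, "+", score, columns, matches, mm, 0)

    def test_identity_cut(self):
        assert filter_hits([self._hit(100, 0.94)]) == []
        assert len(filter_hits([self._hit(100, 0.95)])) == 1

    def test_score_window(self):
        hits = [self._hit(100, 1.0, "a"), self._hit(91, 1.0, "b"), self._hit(89, 1.0, "c")]
        kept = filter_hits(hits, top_percent=0.10)
        assert [h.score for h in kept] == [100, 91]

    def test_empty(self):
        assert filter_hits([]) == []


class TestAssignRead:
    def _hits(self, taxa):
        from sedadna.align import AlignmentHit

        return [
            AlignmentHit("q", f"r{i}", t, "+", 50, 50, 50, (), 0)
            for i, t in enumerate(taxa)
        ]

    def test_ancestor_dropped_for_more_specific_match(self, small_tree):
        # genus 11 is an ancestor of species 12: the species wins
        assert assign_read(self._hits([11, 12]), small_tree) == 12

    def test_sibling_species_meet_at_genus(self, small_tree):
        assert assign_read(self._hits([12, 13]), small_tree) == 11

    def test_no_hits_unassigned(self, small_tree):
        assert assign_read([], small_tree) is UNASSIGNED

    def test_matches_bruteforce_oracle_random_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            parents = {1: 1}
            for tid in range(2, 51):
                parents[tid] = int(rng.integers(1, tid))
            tree = TaxonomyTree(
                [
                    TaxonNode(t, p, "root" if t == p else "species", f"n{t}")
                    for t, p in parents.items()
                ],
                ranks=("root", "species"),
            )
            for _ in range(20):
                k = int(rng.integers(1, 7))
                taxa = rng.integers(1, 51, size=k).tolist()
                assert assign_read(self._hits(taxa), tree) == assign_oracle(
                    parents, taxa
                )


class TestProfiles:
    def _assignments(self):
        return [
            Assignment("s1", "r1", 12),
            Assignment("s1", "r2", 12),
            Assignment("s1", "r3", 15),
            Assignment("s2", "r1", 21),
            Assignment("s2", "r2", UNASSIGNED),
        ]

    def test_min_support_off_equals_raw_counts(self, small_tree):
        profile = build_profile(self._assignments(), small_tree, 0.0)
        assert profile.counts.loc["s1", 12] == 2
        assert profile.counts.loc["s1", 15] == 1
        assert profile.unassigned["s2"] == 1

    def test_min_support_reassigns_to_parent(self, small_tree):
        # 1000 reads: taxon 13 holds 0.4% — below a 0.5% support threshold
        assignments = [Assignment("s1", f"a{i}", 12) for i in range(996)]
        assignments += [Assignment("s1", f"b{i}", 13) for i in range(4)]
        profile = build_profile(assignments, small_tree, min_support_percent=0.5)
        assert 13 not in profile.counts.columns or profile.counts.loc["s1", 13] == 0
        # the 4 reads moved to the parent genus, totals conserved
        assert profile.counts.loc["s1", 11] == 4
        assert int(profile.totals()["s1"]) == 1000

    def test_all_unassigned(self, small_tree):
        assignments = [Assignment("s1", f"r{i}", UNASSIGNED) for i in range(5)]
        profile = build_profile(assignments, small_tree)
        assert int(profile.totals().get("s1", 0)) == 0
        assert profile.unassigned["s1"] == 5

    def test_projection_conserves_totals(self, small_tree):
        rng = np.random.default_rng(12)
        taxa = [12, 13, 15, 21, 31]
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(4, len(taxa))),
            index=[f"s{i}" for i in range(4)],
            columns=taxa,
        )
        profile = TaxonProfile(counts)
        for rank in ("phylum", "genus", "domain"):
            projected = project_rank(profile, small_tree, rank)
            assert (projected.totals() == profile.totals()).all()

    def test_projection_species_to_phylum(self, small_tree):
        counts = pd.DataFrame({12: [3], 13: [2], 15: [5]}, index=["s1"])
        projected = project_rank(TaxonProfile(counts), small_tree, "phylum")
        assert list(projected.counts.columns) == [10]
        assert projected.counts.loc["s1", 10] == 10

    def test_above_rank_goes_to_unclassified_bucket(self, small_tree):
        # a read assigned at domain level survives phylum projection
        counts = pd.DataFrame({2: [7], 12: [3]}, index=["s1"])
        projected = project_rank(TaxonProfile(counts), small_tree, "phylum")
        assert projected.counts.loc["s1", 2] == 7
        assert 2 in projected.unclassified
        assert "not further classified" in projected.column_label(2, small_tree)

    def test_unknown_rank_rejected(self, small_tree):
        with pytest.raises(ValueError, match="rank"):
            project_rank(TaxonProfile(pd.DataFrame({12: [1]}, index=["s1"])), small_tree, "tribe")

    def test_tsv_round_trip(self, small_tree, tmp_path):
        counts = pd.DataFrame({12: [3, 0], 21: [1, 9]}, index=["s1", "s2"])
        profile = TaxonProfile(counts, pd.Series({"s1": 2, "s2": 0}))
        path = tmp_path / "profile.tsv"
        profile.to_tsv(path)
        back = TaxonProfile.from_tsv(path)
        assert back.counts.equals(profile.counts)
        assert back.unassigned.equals(profile.unassigned)
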