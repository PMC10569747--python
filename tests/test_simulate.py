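"""Digestion, shearing, motif subsampling, read simulation, quality filter."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diagtax.io_formats import SeqRecord
from diagtax.seqs import revcomp
from diagtax.simulate import (DEFAULT_ENZYMES, NLA_III, NSI_I, CommunityMember,
                              CommunitySpec, Enzyme, digest_sequence,
                              make_mock_community, quality_filter,
                              shear_sequence, simulate_reads,
                              subsample_by_motif)

DIGEST_DEMO = SeqRecord("demo", "AAAA" + "ATGCAT" + "A" * 9 + "CATG" + "A" * 5)


class TestDigest:
    def test_hand_enumerated_cuts_and_flanks(self):
        frags = digest_sequence(DIGEST_DEMO, [NSI_I, NLA_III], mode="complete")
        assert [(f.start, f.end, f.left_flank, f.right_flank) for f in frags] == [
            (0, 9, None, "NsiI"),
            (9, 23, "NsiI", "NlaIII"),
            (23, 28, "NlaIII", None),
        ]
        assert frags[1].sequence == "TAAAAAAAAACATG"

    def test_no_motif_gives_whole_sequence(self):
        frags = digest_sequence(SeqRecord("x", "A" * 40), [NSI_I], mode="complete")
        assert len(frags) == 1
        assert (frags[0].left_flank, frags[0].right_flank) == (None, None)

    def test_partial_p1_equals_complete(self):
        complete = digest_sequence(DIGEST_DEMO, DEFAULT_ENZYMES, mode="complete")
        partial = digest_sequence(DIGEST_DEMO, DEFAULT_ENZYMES, mode="partial",
                                  p=1.0, seed=0)
        assert [(f.start, f.end) for f in complete] == [(f.start, f.end) for f in partial]

    def test_partial_requires_valid_p(self):
        with pytest.raises(ValueError):
            digest_sequence(DIGEST_DEMO, DEFAULT_ENZYMES, mode="partial", p=0.0)

    def test_non_palindromic_motif_scanned_on_reverse_strand(self):
        enzyme = Enzyme("Fake", "AACCG", 2)
        # revcomp occurrence of AACCG is CGGTT; cut at start + (5-2)
        rec = SeqRecord("x", "TTTT" + "CGGTT" + "TTTT")
        frags = digest_sequence(rec, [enzyme], mode="complete")
        assert [(f.start, f.end) for f in frags] == [(0, 7), (7, 13)]

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_conservation_on_random_sequences(self, seed):
        """Fragments tile the source: concatenation reconstructs it exactly,
        #fragments == #cuts + 1, and adjacent flank enzymes agree."""
        rng = np.random.default_rng(seed)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=2000)])
        rec = SeqRecord("g", seq)
        frags = digest_sequence(rec, DEFAULT_ENZYMES, mode="complete")
        assert "".join(f.sequence for f in frags) == seq
        for left, right in zip(frags[:-1], frags[1:]):
            assert left.end == right.start
            assert left.right_flank == right.left_flank is not None


class TestShear:
    def test_empirical_length_distribution(self):
        rng = np.random.default_rng(1)
        seq = SeqRecord("g", "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100_000)]))
        frags = shear_sequence(seq, 1000, 150, 30, seed=1)
        mean_len = np.mean([len(f) for f in frags])
        assert 145 <= mean_len <= 155

    def test_deterministic_under_seed(self):
        seq = SeqRecord("g", "ACGT" * 100)
        a = shear_sequence(seq, 50, 60, 10, seed=3)
        b = shear_sequence(seq, 50, 60, 10, seed=3)
        assert [(f.start, f.end) for f in a] == [(f.start, f.end) for f in b]

    def test_zero_sd_gives_exact_lengths(self):
        seq = SeqRecord("g", "ACGT" * 100)
        assert {len(f) for f in shear_sequence(seq, 20, 64, 0, seed=0)} == {64}

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            shear_sequence(SeqRecord("g", "ACGT"), 1, 10, 1)


class TestMotifSubsample:
    def test_mixed_flank_fragment_kept_by_re1_re2(self):
        frags = digest_sequence(DIGEST_DEMO, DEFAULT_ENZYMES, mode="complete")
        kept = subsample_by_motif(frags, NSI_I, NLA_III, "RE1::RE2", min_len=10)
        assert [(f.start, f.end) for f in kept] == [(9, 23)]

    def test_default_min_len_drops_short_fragment(self):
        frags = digest_sequence(DIGEST_DEMO, DEFAULT_ENZYMES, mode="complete")
        assert subsample_by_motif(frags, NSI_I, NLA_III, "RE1::RE2") == []

    def test_same_enzyme_flanks_by_scheme(self):
        frag = digest_sequence(
            SeqRecord("x", "AA" + "ATGCAT" + "A" * 20 + "ATGCAT" + "AA"),
            [NSI_I, NLA_III], mode="complete",
        )[1]
        assert (frag.left_flank, frag.right_flank) == ("NsiI", "NsiI")
        assert subsample_by_motif([frag], NSI_I, NLA_III, "RE1::RE2", min_len=4) == []
        assert subsample_by_motif([frag], NSI_I, NLA_III, "RE1/2::RE1/2", min_len=4) == [frag]

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            subsample_by_motif([], NSI_I, NLA_III, "RE1")

    def test_plain_reads_are_digested_in_place(self):
        read = SeqRecord("r", "CC" + "ATGCAT" + "T" * 20 + "CATG" + "CC")
        kept = subsample_by_motif([read], NSI_I, NLA_III, "RE1::RE2", min_len=10)
        assert len(kept) == 1
        assert {kept[0].left_flank, kept[0].right_flank} == {"NsiI", "NlaIII"}


def _two_member_community(rng):
    genomes = []
    for _ in range(2):
        genomes.append("".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)]))
    tree_members = [
        CommunityMember([SeqRecord("gA", genomes[0])], 11, 0.9),
        CommunityMember([SeqRecord("gB", genomes[1])], 22, 0.1),
    ]
    return CommunitySpec(tree_members), genomes


class TestSimulateReads:
    def test_error_free_reads_are_verbatim_substrings(self):
        community, genomes = _two_member_community(np.random.default_rng(0))
        sim = simulate_reads(community, "complete_digest", total_reads=200,
                             min_fragment_len=32, seed=5)
        by_acc = {"gA": genomes[0], "gB": genomes[1]}
        truth_acc = {11: "gA", 22: "gB"}
        for read in sim.reads:
            genome = by_acc[truth_acc[sim.truth[read.id]]]
            assert read.sequence in genome or revcomp(read.sequence) in genome

    def test_abundance_rounding(self):
        community, _ = _two_member_community(np.random.default_rng(0))
        sim = simulate_reads(community, "complete_digest", total_reads=1000, seed=5)
        assert sim.member_counts == {11: 900, 22: 100}

    def test_same_seed_is_byte_identical(self, tmp_path):
        from diagtax.io_formats import write_fastq

        community, _ = _two_member_community(np.random.default_rng(0))
        files = []
        for name in ("a.fq", "b.fq"):
            sim = simulate_reads(community, "shotgun", total_reads=100, seed=9)
            write_fastq(sim.reads, tmp_path / name)
            files.append((tmp_path / name).read_bytes())
        assert files[0] == files[1]

    def test_shotgun_then_digest_lifts_coordinates(self):
        community, genomes = _two_member_community(np.random.default_rng(3))
        sim = simulate_reads(community, "shotgun_then_digest", total_reads=500,
                             shear_mean=400, shear_sd=50, seed=5)
        for read_id, frag in list(sim.fragments.items())[:50]:
            genome = genomes[0] if sim.truth[read_id] == 11 else genomes[1]
            assert genome[frag.start:frag.end] == frag.sequence

    def test_error_rate_perturbs_reads_with_matching_quality(self):
        community, genomes = _two_member_community(np.random.default_rng(0))
        sim = simulate_reads(community, "complete_digest", total_reads=500,
                             error_rate=0.01, min_fragment_len=32, seed=5)
        assert all(q == 20 for read in sim.reads for q in read.qualities)
        mismatched = sum(
            read.sequence not in genomes[0] and read.sequence not in genomes[1]
            for read in sim.reads
        )
        assert mismatched > 0


class TestQualityFilter:
    def _read(self, quals):
        return SeqRecord("r", "A" * len(quals), quals)

    def test_over_20_percent_low_bases_removed(self):
        read = self._read([10] * 3 + [30] * 7)  # 30% below Q20
        assert quality_filter([read]) == []

    def test_exactly_20_percent_kept(self):
        read = self._read([10] * 2 + [30] * 8)  # 20% is not > 20%
        assert quality_filter([read]) == [read]

    def test_base_at_exactly_q20_is_not_low(self):
        read = self._read([20] * 10)
        assert quality_filter([read]) == [read]

    def test_missing_qualities_pass_with_warning(self):
        read = SeqRecord("r", "ACGT")
        with pytest.warns(UserWarning):
            assert quality_filter([read]) == [read]


class TestMockCommunity:
    def test_shape_and_abundance_spectrum(self, mock):
        assert len(mock.community.members) == 10
        assert len(mock.decoy_records) == 5
        abundances = [m.abundance for m in mock.community.members]
        assert abs(sum(abundances) - 1.0) < 1e-9
        assert max(abundances) / min(abundances) == pytest.approx(1000.0)

    def test_congeneric_pairs_are_about_95_percent_identical(self, mock):
        members = mock.community.members
        pair_a, pair_b = members[0].records[0], members[1].records[0]
        same = sum(a == b for a, b in zip(pair_a.sequence, pair_b.sequence))
        assert 0.94 <= same / len(pair_a.sequence) <= 0.96
        genus = mock.tree.lineage_of(members[0].taxid, "genus")
        assert mock.tree.lineage_of(members[1].taxid, "genus") == genus

    def test_every_lineage_reaches_phylum(self, mock):
        for taxid in mock.taxid_map.values():
            assert mock.tree.lineage_of(taxid, "phylum") is not None

    def test_decoy_taxa_absent_from_community(self, mock):
        community = set(mock.community.taxids)
        decoys = {mock.taxid_map[r.id] for r in mock.decoy_records}
        assert community.isdisjoint(decoys)
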