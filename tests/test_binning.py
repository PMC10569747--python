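"""Diagnostic-read classification rules and cross-rank validation."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diagtax.align import AlignmentHit
from diagtax.binning import (BinningConfig, bin_sample, cross_rank_validate,
                             diagnostic_classify, rank_hit_filter)
from diagtax.io_formats import SeqRecord
from diagtax.profiling import ProfileRow, RankProfile
from diagtax.taxonomy import RANKS, TaxonomyNode, TaxonomyTree


def _hit(taxid, aln_len=64, identity=100.0, mismatches=0, acc=None):
    return AlignmentHit(
        query_id="r", subject_accession=acc or f"acc{taxid}", subject_taxid=taxid,
        identity=identity, aln_len=aln_len, q_start=0, q_end=aln_len,
        s_start=0, s_end=aln_len, mismatches=mismatches,
    )


@pytest.fixture(scope="module")
def pseudomonas_like_tree():
    """Two species in one genus, a second genus, all under one phylum."""
    return TaxonomyTree([
        TaxonomyNode(1, 1, "root", "root"),
        TaxonomyNode(10, 1, "phylum", "Proteobacteria-like"),
        TaxonomyNode(100, 10, "genus", "GenusA"),
        TaxonomyNode(101, 10, "genus", "GenusB"),
        TaxonomyNode(1000, 100, "species", "A sp1"),
        TaxonomyNode(1001, 100, "species", "A sp2"),
        TaxonomyNode(1002, 101, "species", "B sp1"),
        TaxonomyNode(10000, 1000, "strain", "A sp1 st1"),
        TaxonomyNode(10001, 1000, "strain", "A sp1 st2"),
        TaxonomyNode(10002, 1001, "strain", "A sp2 st1"),
        TaxonomyNode(10003, 1002, "strain", "B sp1 st1"),
    ])


class TestRankHitFilter:
    cfg = BinningConfig()

    def test_full_length_hit_kept_at_every_rank(self):
        hit = _hit(1, aln_len=64)
        for rank in RANKS:
            assert rank_hit_filter([hit], rank, self.cfg, read_len=64) == [hit]

    def test_partial_coverage_dropped_at_strain_kept_at_species(self):
        hit = _hit(1, aln_len=96)
        cfg = BinningConfig(qcov=0.95)
        assert rank_hit_filter([hit], "strain", cfg, read_len=100) == []
        assert rank_hit_filter([hit], "species", cfg, read_len=100) == [hit]

    def test_sub_32bp_hit_dropped_everywhere(self):
        hit = _hit(1, aln_len=30)
        for rank in RANKS:
            assert rank_hit_filter([hit], rank, self.cfg, read_len=30) == []

    def test_imperfect_identity_always_dropped(self):
        hit = _hit(1, identity=99.9, mismatches=1)
        assert rank_hit_filter([hit], "phylum", self.cfg, read_len=64) == []

    def test_fullqlen_false_only_checks_length_and_identity(self):
        cfg = BinningConfig(fullqlen_alignment=False)
        hit = _hit(1, aln_len=40)
        assert rank_hit_filter([hit], "strain", cfg, read_len=200) == [hit]

    def test_qcov_outside_range_rejected(self):
        with pytest.raises(ValueError, match="qcov"):
            BinningConfig(qcov=0.90)


class TestDiagnosticClassify:
    def test_two_species_one_genus(self, pseudomonas_like_tree):
        """A read matching two congeneric species is discarded at species
        rank but diagnostic for the shared genus."""
        hits = [_hit(1000), _hit(1001)]  # species A sp1 and A sp2
        at_species = diagnostic_classify(hits, "species", pseudomonas_like_tree)
        at_genus = diagnostic_classify(hits, "genus", pseudomonas_like_tree)
        assert at_species.verdict == "ambiguous_discard"
        assert at_genus.taxid == 100

    def test_single_strain_hit_assigns_whole_lineage(self, pseudomonas_like_tree):
        hits = [_hit(10000)]
        assert diagnostic_classify(hits, "strain", pseudomonas_like_tree).taxid == 10000
        assert diagnostic_classify(hits, "phylum", pseudomonas_like_tree).taxid == 10

    def test_two_strains_same_species(self, pseudomonas_like_tree):
        hits = [_hit(10000), _hit(10001)]
        assert diagnostic_classify(hits, "strain", pseudomonas_like_tree).verdict == \
            "ambiguous_discard"
        assert diagnostic_classify(hits, "species", pseudomonas_like_tree).taxid == 1000

    def test_no_hits_is_no_hit(self, pseudomonas_like_tree):
        assert diagnostic_classify([], "genus", pseudomonas_like_tree,
                                   read_id="r").verdict == "no_hit"

    def test_lineage_without_rank_is_ignored(self, pseudomonas_like_tree):
        # genus-level subject taxid cannot vote at strain rank
        hits = [_hit(100), _hit(10000)]
        assert diagnostic_classify(hits, "strain", pseudomonas_like_tree).taxid == 10000

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.sampled_from([1000, 1001, 1002, 10000, 10001, 100, 101]),
                    min_size=0, max_size=6),
           st.sampled_from(RANKS))
    def test_agrees_with_brute_force_enumeration(self, pseudomonas_like_tree,
                                                 taxids, rank):
        """The single-taxon rule equals brute-force enumeration of the
        projected taxid set on every hit set of <= 6 hits."""
        tree = pseudomonas_like_tree
        hits = [_hit(t, acc=f"acc{t}_{i}") for i, t in enumerate(taxids)]
        result = diagnostic_classify(hits, rank, tree, read_id="r")
        projected = {tree.lineage_of(t, rank) for t in taxids}
        projected.discard(None)
        if len(projected) == 1:
            assert result.taxid == next(iter(projected))
        elif not projected:
            assert result.verdict == "no_hit"
        else:
            assert result.verdict == "ambiguous_discard"

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.sampled_from([10000, 10001, 10002, 10003]),
                    min_size=1, max_size=6))
    def test_rank_monotonicity_on_arbitrary_hit_sets(self, pseudomonas_like_tree,
                                                     taxids):
        """If a read is assigned at a finer rank it is assigned at every
        coarser rank, to the finer assignment's ancestor. Holds whenever all
        subject taxids carry full strain-to-phylum lineages (as references
        built from strain genomes do); a species-level subject taxid is
        ignored at strain rank and can break the nesting."""
        tree = pseudomonas_like_tree
        hits = [_hit(t, acc=f"acc{t}_{i}") for i, t in enumerate(taxids)]
        previous = None
        for rank in RANKS:  # finest to coarsest
            result = diagnostic_classify(hits, rank, tree, read_id="r")
            if previous is not None and previous.taxid is not None:
                assert result.taxid == tree.lineage_of(previous.taxid, rank)
            previous = result


class TestBinSample:
    def test_empty_read_set(self, pseudomonas_like_tree):
        from diagtax.align import build_reference_index

        index = build_reference_index(
            [SeqRecord("acc", "ACGT" * 20)], {"acc": 10000})
        result = bin_sample([], index, pseudomonas_like_tree)
        assert all(v == [] for v in result.assignments.values())

    def test_short_reads_counted_too_short(self, pseudomonas_like_tree):
        result = bin_sample([SeqRecord("r", "ACGT")], {},
                            pseudomonas_like_tree)
        assert result.summary["strain"]["too_short"] == 1

    def test_hits_for_unknown_read_raise(self, pseudomonas_like_tree):
        hits = {"ghost": [_hit(10000)]}
        with pytest.raises(ValueError, match="ghost"):
            bin_sample([SeqRecord("r", "A" * 40)], hits, pseudomonas_like_tree)

    def test_precomputed_hits_path(self, pseudomonas_like_tree):
        read = SeqRecord("r", "A" * 64)
        result = bin_sample([read], {"r": [_hit(10000)]}, pseudomonas_like_tree)
        assert result.assignments["species"][0].taxid == 1000


def _profile_from_taxa(rank, taxa):
    return RankProfile(rank, {
        t: ProfileRow(read_count=1, locus_count=1, mean_depth=1.0,
                      percent_reads=1.0) for t in taxa
    })


class TestCrossRankValidation:
    def _tree(self):
        return TaxonomyTree([
            TaxonomyNode(1, 1, "root", "root"),
            TaxonomyNode(10, 1, "phylum", "P1"),
            TaxonomyNode(11, 1, "phylum", "P2"),
            TaxonomyNode(100, 10, "species", "A"),
            TaxonomyNode(101, 11, "species", "B"),
        ])

    def test_half_alien_species(self):
        """One of two species projects outside the phylum profile: FPR 50%,
        sensitivity 100%."""
        profiles = {
            "species": _profile_from_taxa("species", [100, 101]),
            "phylum": _profile_from_taxa("phylum", [10]),
        }
        report = cross_rank_validate(profiles, self._tree())
        assert report.per_rank["species"].fpr == 50.0
        assert report.per_rank["species"].sensitivity == 100.0
        assert report.per_rank["species"].flagged_taxa == {101}

    def test_consistent_profiles_are_clean(self):
        profiles = {
            "species": _profile_from_taxa("species", [100, 101]),
            "phylum": _profile_from_taxa("phylum", [10, 11]),
        }
        report = cross_rank_validate(profiles, self._tree())
        assert (report.per_rank["species"].fpr,
                report.per_rank["species"].sensitivity) == (0.0, 100.0)

    def test_empty_lower_rank_degenerates_with_warning(self):
        profiles = {
            "species": _profile_from_taxa("species", []),
            "phylum": _profile_from_taxa("phylum", [10]),
        }
        with pytest.warns(UserWarning):
            report = cross_rank_validate(profiles, self._tree())
        assert (report.per_rank["species"].fpr,
                report.per_rank["species"].sensitivity) == (0.0, 0.0)

    def test_empty_baseline_skips_validation(self):
        profiles = {
            "species": _profile_from_taxa("species", [100]),
            "phylum": _profile_from_taxa("phylum", []),
        }
        with pytest.warns(UserWarning):
            report = cross_rank_validate(profiles, self._tree())
        assert report.per_rank == {}

    def test_remove_flagged_prunes_profile(self):
        species = _profile_from_taxa("species", [100, 101])
        profiles = {
            "species": species,
            "phylum": _profile_from_taxa("phylum", [10]),
        }
        cross_rank_validate(profiles, self._tree(), remove_flagged=True)
        assert set(species.rows) == {100}


class TestPrecisionGuarantee:
    def test_error_free_reads_with_decoys_never_misassign(self):
        """Error-free reads whose sources are all in the database: every
        assignment at every rank is an ancestor of the true source, no
        matter how many near-identical decoys the database carries."""
        from diagtax.align import build_reference_index
        from diagtax.simulate import make_mock_community, simulate_reads

        mc = make_mock_community(seed=42, genome_length=10_000)
        sim = simulate_reads(mc.community, "complete_digest", total_reads=2000,
                             scheme="RE1/2::RE1/2", seed=43)
        index = build_reference_index(mc.all_records, mc.taxid_map)
        result = bin_sample(sim.reads, index, mc.tree)
        for rank, assignments in result.assignments.items():
            for a in assignments:
                if a.taxid is None:
                    continue
                true_strain = sim.truth[a.read_id]
                assert mc.tree.lineage_of(true_strain, rank) == a.taxid
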