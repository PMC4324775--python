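"""Branch/PPT motif search and catalog refinement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicescape.junction_catalog import (
    JunctionFilterReport,
    annotate_junctions,
    extract_junctions,
    find_branch_site,
    find_ppt,
    infer_strand,
    junctions_from_counts,
    make_junction,
    refine_junctions,
)

from conftest import make_sj
from oracles import branch_oracle, ppt_oracle

DNA = st.text(alphabet="ACGT", min_size=0, max_size=80)


class TestBranchSite:
    def test_primary_tier_match(self):
        b = find_branch_site("GTAAGTCCCCCTAACTTTTTTTTCAG")
        assert b.motif_tier == "primary"
        assert b.motif == "CTAAC"
        assert b.a_pos == 14
        assert b.offset_to_3ss == 12

    def test_secondary_tier_match(self):
        b = find_branch_site("GTAAGTCCCCTTGACCCCCCCCAG")
        assert b.motif_tier == "secondary"
        assert b.motif == "TTGAC"
        assert b.a_pos == 14

    def test_no_match(self):
        assert find_branch_site("GTAAGTCCCCCCCCCCCCCCCCAG") is None

    def test_terminal_acceptor_never_consumed(self):
        # the only CURAY instance would need the final AG bases
        seq = "GGGGGGGGCTAAG"  # CTAAG ends at the last base
        assert find_branch_site(seq) is None or (
            find_branch_site(seq).a_pos + 1 <= len(seq) - 2
        )

    def test_configurable_secondary_motif(self):
        # UUARY instead of UURAY: TTAGC matches UUARY only
        seq = "GGGGGGTTAGCGGGGGGGGG"
        assert find_branch_site(seq) is None
        b = find_branch_site(seq, secondary_motif="UUARY")
        assert b is not None and b.motif == "TTAGC"

    @settings(max_examples=400, derandomize=True)
    @given(DNA)
    def test_matches_regex_oracle(self, seq):
        got = find_branch_site(seq)
        want = branch_oracle(seq)
        if want is None:
            assert got is None
        else:
            assert got is not None
            assert (got.motif_tier, got.a_pos) == want


class TestPPT:
    def test_unique_window(self):
        tract = find_ppt("GGGGGGTTCTTCGGGGGG", None)
        assert tract.seq == "TTCTTC"
        assert tract.t_count == 4
        assert tract.region == "no_branch"

    def test_maximal_t_dominates_position(self):
        # 5 T window 5' of a 3-T window: the T-richer one wins
        seq = "TTTTTCGGGGGGGGTCTCTC"
        tract = find_ppt(seq, None)
        assert tract.seq == "TTTTTC"

    def test_tie_broken_3_prime(self):
        seq = "TTCTTCGGGGGGGGTTCTTC"
        tract = find_ppt(seq, None)
        assert tract.window_start_offset == 15

    def test_region_relative_to_branch(self):
        seq = "GGTTTTTTGGGGGGGGGGGGGGGGGGGG" + "CTAAC" + "GGGG"
        b = find_branch_site(seq)
        tract = find_ppt(seq, b.a_pos)
        assert tract.region == "five_to_branch"
        seq2 = "G" * 20 + "CTAAC" + "GGTTTTTTGG"
        b2 = find_branch_site(seq2)
        tract2 = find_ppt(seq2, b2.a_pos)
        assert tract2.region == "branch_to_three"

    @settings(max_examples=400, derandomize=True)
    @given(DNA)
    def test_matches_brute_force_oracle(self, seq):
        got = find_ppt(seq, None)
        want = ppt_oracle(seq)
        if want is None:
            assert got is None
        else:
            assert got is not None
            assert (got.window_start_offset, got.seq) == want


class TestExtraction:
    def test_strand_orientation_of_minus_intron(self, small_dataset):
        genome, truth, sim = small_dataset
        sjs = junctions_from_counts(sim.counts, genome)
        minus = [j for j in sjs if j.strand == "-"]
        assert minus, "expected minus-strand junctions in the dataset"
        for j in minus:
            assert (j.donor_dinucleotide, j.acceptor_dinucleotide) in {
                ("GT", "AG"), ("GC", "AG"), ("AT", "AC"),
            }

    def test_min_support_threshold(self, small_dataset):
        genome, _truth, sim = small_dataset
        counts = sim.counts.copy()
        key = counts.iloc[0][["chrom", "intron_start", "intron_end", "strand"]]
        mask = (
            (counts["chrom"] == key["chrom"])
            & (counts["intron_start"] == key["intron_start"])
            & (counts["intron_end"] == key["intron_end"])
        )
        counts.loc[mask, "reads"] = 0
        counts.loc[mask.idxmax(), "reads"] = 1  # pooled support 1 < 2
        sjs = junctions_from_counts(counts, genome)
        assert (key["chrom"], key["strand"], key["intron_start"], key["intron_end"]) not in {
            j.key() for j in sjs
        }

    def test_sample_aggregation(self, small_dataset):
        genome, _truth, sim = small_dataset
        sjs = junctions_from_counts(sim.counts, genome)
        pooled = sim.counts.groupby(
            ["chrom", "strand", "intron_start", "intron_end"]
        )["reads"].sum()
        for j in sjs:
            assert j.pooled_support == pooled.loc[j.key()]
            assert j.pooled_support == sum(j.support.values())

    def test_out_of_bounds_intron_rejected(self):
        genome = {"chr1": "A" * 100}
        with pytest.raises(ValueError):
            make_junction(genome, "chr1", "+", 95, 120, {"s1": 3})

    def test_infer_strand(self):
        genome = {"c": "NNGTAAGTCCCCCTAACTTTCAGNN"}
        assert infer_strand(genome, "c", 3, 23) == "+"
        from splicescape.io import revcomp

        genome2 = {"c": "NN" + revcomp("GTAAGTCCCCCTAACTTTCAG") + "NN"}
        assert infer_strand(genome2, "c", 3, 23) == "-"
        assert infer_strand({"c": "A" * 30}, "c", 3, 23) == "unknown"


def _scored(sjs, scores):
    return {j.key(): s for j, s in zip(sjs, scores)}


class TestRefinement:
    def test_branch_distance_boundary(self):
        # branch offsets 60 and 61: only the first survives
        near = make_sj(start=100, end=200, seq="G" * 101)
        far = make_sj(start=300, end=400, seq="G" * 101)
        annotate_junctions([near, far])
        from splicescape.junction_catalog import BranchSite

        near.branch = BranchSite(41, 60, "primary", "CTAAC")
        far.branch = BranchSite(40, 61, "primary", "CTAAC")
        kept, report = refine_junctions([near, far], {})
        assert [j.key() for j in kept] == [near.key()]
        assert report.n_branch_too_far == 1

    def test_no_branch_removed(self):
        sj = make_sj(seq="G" * 101)
        sj.branch = None
        kept, report = refine_junctions([sj], {})
        assert kept == [] and report.n_no_branch == 1

    def test_overlap_correction_merges_support(self):
        from splicescape.junction_catalog import BranchSite

        a = make_sj(start=100, end=159, support={"s1": 10}, seq="G" * 60)
        b = make_sj(start=104, end=163, support={"s1": 3}, seq="G" * 60)
        for j in (a, b):
            j.branch = BranchSite(45, 15, "primary", "CTAAC")
        scores = {a.key(): 8.2, b.key(): 3.1}
        kept, report = refine_junctions([a, b], scores)
        assert len(kept) == 1
        assert kept[0].key() == a.key()
        assert kept[0].pooled_support == 13
        assert report.n_overlap_corrected == 1

    def test_n_exclusion(self):
        from splicescape.junction_catalog import BranchSite

        sj = make_sj(seq="GTAAG" + "N" + "G" * 40 + "CTAAC" + "G" * 10 + "AG")
        sj.branch = BranchSite(51, 12, "primary", "CTAAC")
        kept, report = refine_junctions([sj], {})
        assert kept == [] and report.n_n_excluded == 1

    def test_report_identity(self):
        r = JunctionFilterReport(
            n_input=14678,
            n_no_branch=36,
            n_branch_too_far=248,
            n_overlap_corrected=88,
            n_n_excluded=1,
        )
        assert r.n_final == 14305

    def test_support_conservation_and_permutation_invariance(self, small_dataset):
        genome, _truth, sim = small_dataset
        sjs = junctions_from_counts(sim.counts, genome)
        annotate_junctions(sjs)
        total_in = sum(j.pooled_support for j in sjs)
        kept, report = refine_junctions(sjs, {j.key(): 0.0 for j in sjs})
        removed = [j for j in sjs if j.key() not in {k.key() for k in kept}]
        # merged support stays; only branch/N-removed junctions drop support
        assert sum(j.pooled_support for j in kept) + sum(
            j.pooled_support
            for j in removed
            if j.branch is None
            or j.branch.offset_to_3ss > 60
            or "N" in j.intron_seq
        ) == total_in

        rev = junctions_from_counts(sim.counts, genome)
        annotate_junctions(rev)
        rev.reverse()
        kept2, _ = refine_junctions(rev, {j.key(): 0.0 for j in rev})
        assert {j.key() for j in kept2} == {j.key() for j in kept}
        assert {j.key(): j.pooled_support for j in kept2} == {
            j.key(): j.pooled_support for j in kept
        }
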