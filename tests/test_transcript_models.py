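"""TAR detection, unit linking, artificial reads, assembly and ORFs."""

import numpy as np
import pytest

from splicescape.alignment_filter import AlignedPair
from splicescape.io import GeneModel, revcomp
from splicescape.transcript_models import (
    ArtificialRead,
    AssembledModel,
    assemble_models,
    detect_tars,
    find_longest_orf,
    link_units,
    make_artificial_reads,
    screen_against_reference,
    spliced_sequence,
)

from conftest import make_sj
from oracles import orf_oracle


def _cov(runs, n=1000):
    arr = np.zeros(n, dtype=int)
    for s0, e0, depth in runs:
        arr[s0:e0] = depth
    return {"chr1": arr}


def _pair(blocks1, blocks2):
    return AlignedPair("p", "chr1", (list(blocks1), list(blocks2)))


class TestTars:
    def test_qualifying_run(self):
        tars = detect_tars(_cov([(100, 140, 5)]))  # 40 bp at depth 5
        assert len(tars) == 1
        assert (tars[0].start, tars[0].end) == (101, 140)

    def test_length_boundary_strict(self):
        assert detect_tars(_cov([(100, 135, 100)])) == []  # exactly 35 bp
        assert len(detect_tars(_cov([(100, 136, 100)]))) == 1

    def test_internal_dip_splits_run(self):
        cov = _cov([(100, 140, 4)])
        cov["chr1"][120] = 3
        tars = detect_tars(cov)
        # two sub-runs of 20 and 19 bp, neither longer than 35
        assert tars == []

    def test_maximality(self):
        cov = _cov([(100, 150, 6)])
        (tar,) = detect_tars(cov)
        arr = cov["chr1"]
        assert arr[tar.start - 2] < 4 and arr[tar.end] < 4  # flanking bases fail


class TestUnits:
    def test_bridged_tars_form_unit(self):
        tars = detect_tars(_cov([(100, 200, 20), (300, 400, 20)]))
        pairs = [_pair([(120, 180)], [(320, 380)])]
        units = link_units(tars, pairs)
        assert len(units) == 1 and len(units[0].tars) == 2

    def test_unbridged_tars_stay_separate(self):
        tars = detect_tars(_cov([(100, 300, 20), (400, 600, 20)]))
        units = link_units(tars, [])
        assert len(units) == 2

    def test_length_boundary(self):
        # one 150-bp unit: dropped (needs longer than 150)
        tars = detect_tars(_cov([(100, 250, 20)]))
        assert tars[0].length == 150
        assert link_units(tars, []) == []

    def test_depth_boundary(self):
        tars = detect_tars(_cov([(100, 300, 9)]))  # mean depth 9 < 10
        assert link_units(tars, []) == []
        tars = detect_tars(_cov([(100, 300, 10)]))
        assert len(link_units(tars, [])) == 1


class TestArtificialReads:
    def test_overlapping_mates_merged(self):
        (read,) = make_artificial_reads([_pair([(100, 160)], [(150, 210)])], [])
        assert read.blocks == [(100, 210)]

    def test_interval_filled_as_exonic(self):
        (read,) = make_artificial_reads([_pair([(100, 150)], [(200, 260)])], [])
        assert read.blocks == [(100, 260)]
        assert read.junctions() == []

    def test_single_junction_embedded(self):
        # interval 120 bp containing a 60-bp junction: 120-60 = 60 < 85
        sj = make_sj(start=180, end=239)
        pair = _pair([(100, 150)], [(271, 330)])
        assert pair.interval_length == 120
        (read,) = make_artificial_reads([pair], [sj])
        assert read.blocks == [(100, 179), (240, 330)]
        assert read.junctions() == [(180, 239)]

    def test_large_remainder_passes_mates_through(self):
        # interval 200 bp with a 100-bp junction: remainder 100 >= 85
        sj = make_sj(start=200, end=299)
        pair = _pair([(100, 150)], [(351, 410)])
        assert pair.interval_length == 200
        reads = make_artificial_reads([pair], [sj])
        assert len(reads) == 2
        assert all(r.junctions() == [] for r in reads)


def _tile(start, end, step=20, rlen=60):
    """Overlapping single-block reads covering [start, end] at depth >= 2."""
    reads = []
    pos = start
    while pos + rlen - 1 <= end:
        reads.append(ArtificialRead("chr1", [(pos, pos + rlen - 1)]))
        pos += step
    reads.append(ArtificialRead("chr1", [(end - rlen + 1, end)]))
    # duplicate terminal reads so no edge base falls below the support floor
    reads.append(ArtificialRead("chr1", [(start, start + rlen - 1)]))
    reads.append(ArtificialRead("chr1", [(end - rlen + 1, end)]))
    return reads


class TestAssembly:
    def test_overlap_chaining(self):
        models = assemble_models(_tile(101, 400))
        assert len(models) == 1
        assert models[0].start >= 101 and models[0].end <= 400
        assert models[0].exonic_length >= 100

    def test_short_contig_dropped(self):
        # two identical 99-base reads: depth 2 everywhere but too short
        reads = [
            ArtificialRead("chr1", [(101, 199)]),
            ArtificialRead("chr1", [(101, 199)]),
        ]
        assert assemble_models(reads) == []
        reads = [
            ArtificialRead("chr1", [(101, 200)]),
            ArtificialRead("chr1", [(101, 200)]),
        ]
        assert len(assemble_models(reads)) == 1

    def test_unsupported_base_never_emitted(self):
        models = assemble_models(_tile(101, 400, step=25))
        depth = np.zeros(500, dtype=int)
        for r in _tile(101, 400, step=25):
            for s, e in r.blocks:
                depth[s - 1 : e] += 1
        for m in models:
            for s, e in m.exons:
                assert (depth[s - 1 : e] >= 2).all()

    def test_locus_link_distance_boundary(self):
        left = _tile(101, 300)
        right_linked = _tile(311, 510)  # gap of 10 bp
        assert len(assemble_models(left + right_linked)) == 1
        right_apart = _tile(312, 511)  # gap of 11 bp
        assert len(assemble_models(left + right_apart)) == 2

    def test_contradictory_junctions_block_chaining(self):
        a = ArtificialRead("chr1", [(101, 200), (301, 400)])
        b = ArtificialRead("chr1", [(101, 400)])  # same span, no junction
        models = assemble_models([a, a, b, b])
        # incompatible reads must not merge into one chimeric contig
        assert all(
            [(201, 300)] != m.exons for m in models
        )
        contents = {tuple(m.exons) for m in models}
        assert len(models) >= 1


class TestOrf:
    def _model(self):
        return AssembledModel("m1", "chr1", [(1, 102)], strand="+")

    def test_complete_orf_33_aa(self):
        rng = np.random.default_rng(4)
        body = "".join(
            rng.choice(["GCT", "GGT", "TGT", "CCT", "TCT"]) for _ in range(32)
        )
        seq = "ATG" + body[: 96] + "TAA"
        genome = {"chr1": seq}
        model = AssembledModel("m1", "chr1", [(1, len(seq))], strand="+")
        model = find_longest_orf(model, genome)
        assert len(model.protein) == 33
        assert model.complete

    def test_30_aa_boundary_noncoding(self):
        seq = "ATG" + "GCT" * 29 + "TAA"  # 30 aa including Met
        genome = {"chr1": seq + "C" * 10}
        model = AssembledModel("m1", "chr1", [(1, len(seq))], strand="+")
        model = find_longest_orf(model, genome)
        assert len(model.protein) == 30
        assert not model.is_coding

    def test_known_strand_restricts_frames(self):
        # reverse-strand ORF invisible when the model strand is fixed to +
        core = "ATG" + "GCT" * 40 + "TAA"
        seq = revcomp(core)
        genome = {"chr1": seq}
        plus = AssembledModel("m", "chr1", [(1, len(seq))], strand="+")
        both = AssembledModel("m", "chr1", [(1, len(seq))], strand="unknown")
        assert len(find_longest_orf(both, genome).protein) == 41
        assert len(find_longest_orf(plus, genome).protein) < 41

    def test_spliced_sequence_concatenates_exons(self):
        genome = {"chr1": "AAACCCGGGTTT"}
        model = AssembledModel("m", "chr1", [(1, 3), (10, 12)])
        assert spliced_sequence(model, genome) == "AAATTT"

    def test_matches_six_frame_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = int(rng.integers(30, 400))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            genome = {"chr1": seq}
            model = AssembledModel("m", "chr1", [(1, n)], strand="unknown")
            got = find_longest_orf(model, genome)
            want_aa, _want_complete = orf_oracle(seq)
            assert len(got.protein) == want_aa


class TestScreening:
    def test_overlap_boundaries(self):
        ref = [GeneModel("r", "chr1", "+", [(100, 200)])]
        keep = AssembledModel("a", "chr1", [(191, 300)])  # 10 bp overlap
        drop = AssembledModel("b", "chr1", [(190, 300)])  # 11 bp overlap
        out = screen_against_reference([keep, drop], ref)
        assert [m.model_id for m in out] == ["a"]

    def test_structural_rna_any_overlap_drops(self):
        trna = [GeneModel("t", "chr1", "+", [(300, 360)])]
        model = AssembledModel("a", "chr1", [(100, 300)])  # 1 bp overlap
        assert screen_against_reference([model], [], trna) == []
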