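"""Cluster formation, AS taxonomy, IRR statistics and event accounting."""

import numpy as np
import pytest

from splicescape.as_classifier import (
    AccountingSummary,
    classify_clusters,
    classify_multi,
    classify_pair,
    classify_single,
    cluster_junctions,
    irr_bin,
    summarize_events,
    SJCluster,
)
from splicescape.io import GeneModel

from conftest import make_sj
from oracles import multi_oracle, pair_oracle


class TestClustering:
    def test_overlapping_junctions_cluster(self):
        a, b = make_sj(start=100, end=200), make_sj(start=150, end=250)
        clusters, n_mixed = cluster_junctions([a, b])
        assert len(clusters) == 1 and len(clusters[0].members) == 2
        assert n_mixed == 0

    def test_adjacent_junctions_do_not_cluster(self):
        a, b = make_sj(start=100, end=200), make_sj(start=201, end=300)
        clusters, _ = cluster_junctions([a, b])
        assert len(clusters) == 2

    def test_mixed_strand_component_excluded(self):
        a = make_sj(start=100, end=200, strand="+")
        b = make_sj(start=150, end=250, strand="-")
        clusters, n_mixed = cluster_junctions([a, b])
        assert clusters == [] and n_mixed == 1


class TestPairClassification:
    @pytest.mark.parametrize(
        "span_a,span_b,strand,expected",
        [
            ((100, 200), (150, 200), "+", "A5SS"),
            ((100, 200), (100, 250), "+", "A3SS"),
            ((100, 250), (120, 200), "+", "A5SS_AND_A3SS"),
            ((100, 200), (150, 260), "+", "A5SS_OR_A3SS"),
            ((100, 200), (300, 400), "+", "disjoint"),
            # strand flips the donor/acceptor roles of shared ends
            ((100, 200), (150, 200), "-", "A3SS"),
            ((100, 200), (100, 250), "-", "A5SS"),
            ((100, 250), (120, 200), "-", "A5SS_AND_A3SS"),
        ],
    )
    def test_coordinate_rules(self, span_a, span_b, strand, expected):
        a = make_sj(start=span_a[0], end=span_a[1], strand=strand)
        b = make_sj(start=span_b[0], end=span_b[1], strand=strand)
        assert classify_pair(a, b) == expected
        assert classify_pair(b, a) == expected  # symmetric up to label

    def test_mixed_strand_raises(self):
        with pytest.raises(ValueError):
            classify_pair(make_sj(strand="+"), make_sj(strand="-"))

    def test_matches_reflection_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            strand = "+" if rng.random() < 0.5 else "-"
            s1, s2 = sorted(rng.integers(1, 25, size=2))
            spans = []
            for _j in range(2):
                s = int(rng.integers(1, 25))
                e = s + int(rng.integers(9, 20))
                spans.append((s, e))
            if spans[0] == spans[1]:
                continue
            a = make_sj(start=spans[0][0], end=spans[0][1], strand=strand)
            b = make_sj(start=spans[1][0], end=spans[1][1], strand=strand)
            assert classify_pair(a, b) == pair_oracle(spans[0], spans[1], strand)


class TestMultiClassification:
    def test_shared_acceptor_is_ma5ss(self):
        members = [make_sj(start=s, end=500) for s in (100, 150, 200)]
        rec = classify_multi(SJCluster("c1", "+", members))
        assert rec.event_type == "MA5SS" and rec.k == 3

    def test_exon_skipping_pattern(self):
        members = [
            make_sj(start=100, end=200),
            make_sj(start=300, end=400),
            make_sj(start=100, end=400),
        ]
        rec = classify_multi(SJCluster("c1", "+", members))
        assert rec.event_type == "EXON_SKIPPING"

    def test_complex_code(self):
        spans = [(100, 200), (150, 200), (150, 260), (220, 260)]
        members = [make_sj(start=s, end=e) for s, e in spans]
        rec = classify_multi(SJCluster("c1", "+", members))
        assert rec.event_type == "COMPLEX"
        assert rec.complex_code == "n=4;A5SS=2;A3SS=1;AND=0;OR=1"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            strand = "+" if rng.random() < 0.5 else "-"
            k = int(rng.integers(3, 5))
            spans = set()
            while len(spans) < k:
                s = int(rng.integers(1, 20))
                spans.add((s, s + int(rng.integers(9, 15))))
            spans = sorted(spans)
            members = [make_sj(start=s, end=e, strand=strand) for s, e in spans]
            rec = classify_multi(SJCluster("c1", strand, members))
            want = multi_oracle(spans, strand)
            if rec.event_type == "COMPLEX":
                assert rec.complex_code == want
            elif rec.event_type in ("MA5SS", "MA3SS"):
                assert rec.event_type == want
            else:
                assert want == "EXON_SKIPPING"

    def test_translation_and_mirror_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            k = int(rng.integers(2, 5))
            spans = set()
            while len(spans) < k:
                s = int(rng.integers(1, 30))
                spans.add((s, s + int(rng.integers(9, 15))))
            spans = sorted(spans)
            label = _label(spans, "+")
            shifted = [(s + 1000, e + 1000) for s, e in spans]
            assert _label(shifted, "+") == label
            hi = max(e for _s, e in spans) + 10
            mirrored = sorted((hi - e, hi - s) for s, e in spans)
            assert _label(mirrored, "-") == label


def _label(spans, strand):
    members = [make_sj(start=s, end=e, strand=strand) for s, e in spans]
    if len(members) == 2:
        return classify_pair(members[0], members[1])
    return classify_multi(SJCluster("c", strand, members)).event_type


class TestIntronRetention:
    def _cluster(self, support=50):
        sj = make_sj(start=11, end=40, support={"s1": support})
        return SJCluster("c1", "+", [sj]), sj

    def test_zero_coverage_is_constitutive(self):
        cluster, _ = self._cluster()
        cov = {"chr1": np.zeros(100, dtype=int)}
        rec, ir = classify_single(cluster, cov)
        assert rec.event_type == "IC" and ir is None

    def test_irr_formula_and_bin(self):
        cluster, sj = self._cluster(support=50)
        cov = {"chr1": np.zeros(100, dtype=int)}
        cov["chr1"][sj.intron_start - 1 : sj.intron_end] = 5
        rec, ir = classify_single(cluster, cov)
        assert rec.event_type == "IR"
        assert ir.irr == pytest.approx(0.1)
        assert ir.irr_bin == "[0.1,1)"
        assert ir.coverage_class == "high"

    def test_low_coverage_class(self):
        cluster, sj = self._cluster(support=10)
        cov = {"chr1": np.zeros(100, dtype=int)}
        cov["chr1"][sj.intron_start - 1] = 1  # a single covered base
        rec, ir = classify_single(cluster, cov)
        assert rec.event_type == "IR" and ir.coverage_class == "low"

    def test_monotonicity_zero_to_positive(self):
        cluster, sj = self._cluster()
        cov = {"chr1": np.zeros(100, dtype=int)}
        assert classify_single(cluster, cov)[0].event_type == "IC"
        for pos in range(sj.intron_start - 1, sj.intron_end):
            bumped = {"chr1": cov["chr1"].copy()}
            bumped["chr1"][pos] = 1
            assert classify_single(cluster, bumped)[0].event_type == "IR"

    def test_even_length_median(self):
        # median of an even number of bases is the mean of the central pair
        sj = make_sj(start=11, end=14, support={"s1": 10})
        cluster = SJCluster("c1", "+", [sj])
        cov = {"chr1": np.zeros(100, dtype=int)}
        cov["chr1"][10:14] = [1, 2, 4, 8]
        _rec, ir = classify_single(cluster, cov)
        assert ir.irr == pytest.approx(3 / 10)

    @pytest.mark.parametrize(
        "irr,label",
        [(0.0, "[0,0.01)"), (0.0099, "[0,0.01)"), (0.01, "[0.01,0.1)"),
         (0.1, "[0.1,1)"), (0.999, "[0.1,1)"), (1.0, "[1,inf)"), (7.5, "[1,inf)")],
    )
    def test_bin_edges(self, irr, label):
        assert irr_bin(irr) == label


class TestAccounting:
    def test_reported_category_counts_identity(self):
        summary = AccountingSummary.from_counts(
            n_ic=3140,
            n_ir=9369,
            two_sj={"A5SS": 167, "A3SS": 302, "A5SS_AND_A3SS": 19, "A5SS_OR_A3SS": 15},
            multi={"MA5SS": 13, "MA3SS": 28, "COMPLEX": 121},
        )
        assert summary.n_AS_events == 10034
        assert summary.n_clusters == 13174
        assert summary.n_single == 12509
        assert summary.n_two_sj == 503
        assert summary.n_multi == 162
        assert summary.as_cluster_ratio == pytest.approx(0.7617, abs=5e-5)

    def test_all_constitutive_degenerate(self):
        summary = AccountingSummary.from_counts(5, 0, {}, {})
        assert summary.n_AS_events == 0 and summary.as_cluster_ratio == 0.0

    def test_identity_holds_on_synthetic_run(self, default_run):
        summary = default_run["summary"]
        assert summary.n_AS_events == summary.n_clusters - summary.n_IC
        assert summary.n_clusters == summary.n_single + summary.n_two_sj + summary.n_multi

    def test_gene_mapping_counts_each_gene_once(self):
        sj1 = make_sj(start=100, end=150, support={"s1": 9})
        sj2 = make_sj(start=300, end=360, support={"s1": 9})
        clusters, _ = cluster_junctions([sj1, sj2])
        cov = {"chr1": np.ones(1000, dtype=int)}  # both IR
        records, _ir = classify_clusters(clusters, cov)
        genes = [GeneModel("g1", "chr1", "+", [(50, 250), (280, 500)])]
        summary = summarize_events(records, clusters, genes)
        assert summary.n_AS_genes == 1
        assert summary.n_multiexonic_AS_genes == 1
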