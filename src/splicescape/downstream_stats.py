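"""Intron feature tables, class comparisons, isoform-frequency statistics,
and the end-to-end pipeline driver.

Intron classes follow the event taxonomy: IC (constitutive, singleton
cluster with zero intronic coverage), IR (retained, singleton with coverage),
and IA-IR — members of any multi-junction cluster, i.e. alternatively
spliced introns other than retained introns.  Feature comparisons between
classes use the two-sided Mann-Whitney-Wilcoxon rank-sum test (raw p-values,
no multiplicity correction).  Isoform relative frequencies of two-junction
clusters are regressed (OLS) against the difference in splice-site scores:
delta 5'ss for A5SS, delta 3'ss for A3SS, delta of the sum for the combined
classes; the response is the natural-log frequency ratio, and clusters with
a zero isoform count are excluded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .as_classifier import PAIR_TYPES

_COMBINED = ("A5SS_AND_A3SS", "A5SS_OR_A3SS")


@dataclass
class ClassComparison:
    feature: str
    cls_a: str
    cls_b: str
    statistic: float
    p_value: float
    direction: str  # which class has the greater median, or "none"


@dataclass
class RegressionResult:
    pair_type: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    defined: bool = True


def gc_content(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def compute_features(junctions, clusters, records, ir_records) -> pd.DataFrame:
    """One row per junction: length, GC, the three scores, class, IRR bin."""
    rec_by_cluster = {r.cluster_id: r for r in records}
    ir_by_key = {r.junction_key: r for r in ir_records}
    cluster_of = {}
    for cluster in clusters:
        for j in cluster.members:
            cluster_of[j.key()] = cluster
    rows = []
    for sj in junctions:
        cluster = cluster_of.get(sj.key())
        if cluster is None:
            raise ValueError(f"junction {sj.key()} belongs to no cluster")
        rec = rec_by_cluster[cluster.cluster_id]
        if len(cluster.members) >= 2:
            cls = "IA_minus_IR"
        elif rec.event_type == "IR":
            cls = "IR"
        else:
            cls = "IC"
        ir = ir_by_key.get(sj.key())
        sc = sj.scores
        rows.append(
            {
                "chrom": sj.chrom,
                "strand": sj.strand,
                "intron_start": sj.intron_start,
                "intron_end": sj.intron_end,
                "cluster_id": cluster.cluster_id,
                "cls": cls,
                "length": sj.length,
                "gc": gc_content(sj.intron_seq),
                "five_score": _finite(sc.five_score) if sc else None,
                "three_score": _finite(sc.three_score) if sc else None,
                "branch_score": _finite(sc.branch_score) if sc else None,
                "irr": ir.irr if ir else None,
                "irr_bin": ir.irr_bin if ir else None,
                "coverage_class": ir.coverage_class if ir else None,
            }
        )
    return pd.DataFrame(rows)


def _finite(x):
    """Sentinel (-inf) scores are excluded from feature statistics."""
    if x is None or not math.isfinite(x):
        return None
    return x


def compare_classes(features: pd.DataFrame, feature: str, cls_a: str, cls_b: str):
    """Two-sided Mann-Whitney-Wilcoxon comparison of one feature.

    Exact p-value for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's 'auto' policy).  Identical value multisets
    give p = 1 and direction 'none'.
    """
    a = features.loc[features["cls"] == cls_a, feature].dropna().to_numpy(float)
    b = features.loc[features["cls"] == cls_b, feature].dropna().to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both classes must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return ClassComparison(feature, cls_a, cls_b, len(a) * len(b) / 2, 1.0, "none")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a > med_b:
        direction = cls_a
    elif med_b > med_a:
        direction = cls_b
    else:
        direction = "none"
    return ClassComparison(
        feature, cls_a, cls_b, float(res.statistic), float(res.pvalue), direction
    )


def isoform_stats(clusters, records, scores, sample_names=None):
    """Isoform relative frequencies and score-difference regressions.

    ``scores`` maps junction keys to objects with five_score/three_score (or
    to (five, three) tuples).  Two-junction clusters of the four pair types
    are analysed: per-sample and pooled relative frequencies, the
    class-relevant score difference, and the natural-log pooled frequency
    ratio (defined only when both isoform counts are positive).  Returns
    (records table, {pair type: RegressionResult}).
    """
    rec_by_cluster = {r.cluster_id: r for r in records}
    rows = []
    for cluster in clusters:
        rec = rec_by_cluster.get(cluster.cluster_id)
        if rec is None or rec.event_type not in PAIR_TYPES or len(cluster.members) != 2:
            continue
        a, b = sorted(cluster.members, key=lambda j: j.key())
        fa, ta = _score_pair(scores.get(a.key()))
        fb, tb = _score_pair(scores.get(b.key()))
        if rec.event_type == "A5SS":
            delta = _sub(fa, fb)
        elif rec.event_type == "A3SS":
            delta = _sub(ta, tb)
        else:
            delta = _sub(_add(fa, ta), _add(fb, tb))
        samples = sample_names or sorted(set(a.support) | set(b.support))
        row = {
            "cluster_id": cluster.cluster_id,
            "pair_type": rec.event_type,
            "chrom": a.chrom,
            "strand": a.strand,
            "isoform1": f"{a.intron_start}-{a.intron_end}",
            "isoform2": f"{b.intron_start}-{b.intron_end}",
            "delta_score": delta,
        }
        for s in samples:
            ca, cb = a.support.get(s, 0), b.support.get(s, 0)
            tot = ca + cb
            row[f"freq1_{s}"] = ca / tot if tot else None
            row[f"freq2_{s}"] = cb / tot if tot else None
        ca, cb = a.pooled_support, b.pooled_support
        tot = ca + cb
        row["freq1_pooled"] = ca / tot if tot else None
        row["freq2_pooled"] = cb / tot if tot else None
        row["log_freq_ratio"] = math.log(ca / cb) if ca > 0 and cb > 0 else None
        rows.append(row)
    table = pd.DataFrame(rows)

    regressions = {}
    groups = {"A5SS": ["A5SS"], "A3SS": ["A3SS"], "combined": list(_COMBINED)}
    for name, types in groups.items():
        if len(table) == 0:
            regressions[name] = RegressionResult(name, *[float("nan")] * 4, 0, False)
            continue
        sub = table[
            table["pair_type"].isin(types)
            & table["delta_score"].notna()
            & table["log_freq_ratio"].notna()
        ]
        x = sub["delta_score"].to_numpy(float)
        y = sub["log_freq_ratio"].to_numpy(float)
        if len(sub) < 3 or np.ptp(x) == 0:
            regressions[name] = RegressionResult(
                name, float("nan"), float("nan"), float("nan"), float("nan"),
                len(sub), False,
            )
            continue
        fit = stats.linregress(x, y)
        regressions[name] = RegressionResult(
            name,
            float(fit.slope),
            float(fit.intercept),
            float(fit.rvalue**2),
            float(fit.pvalue),
            len(sub),
        )
    return table, regressions


def _score_pair(sc):
    if sc is None:
        return None, None
    if isinstance(sc, tuple):
        return sc
    return sc.five_score, sc.three_score


def _sub(x, y):
    if x is None or y is None or not (math.isfinite(x) and math.isfinite(y)):
        return None
    return x - y


def _add(x, y):
    if x is None or y is None:
        return None
    return x + y


# ---------------------------------------------------------------------------
# pipeline driver


def run_pipeline(config: dict, outdir) -> dict:
    """Execute filter -> junctions -> score -> classify -> stats end to end.

    ``config`` is either a synthetic-mode mapping::

        {"mode": "synthetic", "seed": 1,
         "genome": {...GenomeSpec fields}, "genes": {...GeneSpec fields},
         "events": {...EventSpec fields}, "reads": {...ReadSimSpec fields},
         "emit_sam": false}

    or a real-mode mapping naming input files (genome_fasta plus either a
    SAM file or a junction counts TSV, optional coverage bedGraphs and a
    models GFF3).  Writes junctions.tsv, matrices.tsv, clusters.tsv, ir.tsv,
    features.tsv, comparisons.tsv, isoforms.tsv, regressions.tsv,
    summary.json and manifest.json into ``outdir`` and returns a result
    bundle; deterministic given the seed and inputs.
    """
    from . import (
        alignment_filter,
        as_classifier,
        junction_catalog,
        splice_scoring,
        synthetic_data,
    )
    from .io import read_bedgraph, read_fasta, read_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stage_notices": []}
    result: dict = {}

    mode = config.get("mode", "synthetic")
    truth = None
    gene_models = None
    if mode == "synthetic":
        seed = int(config.get("seed", 0))
        gspec = synthetic_data.GenomeSpec(**{"seed": seed, **config.get("genome", {})})
        gene_spec = synthetic_data.GeneSpec(**config.get("genes", {}))
        espec = synthetic_data.EventSpec(**config.get("events", {}))
        rspec = synthetic_data.ReadSimSpec(**{"seed": seed, **config.get("reads", {})})
        genome, truth, sim = synthetic_data.simulate_dataset(
            gspec, gene_spec, espec, rspec, outdir=outdir,
            emit_sam=bool(config.get("emit_sam", False)),
        )
        counts = sim.counts
        coverage = sim.pooled_coverage()
        gene_models = truth.gene_models()
    else:
        genome = read_fasta(config["genome_fasta"])
        lengths = {c: len(s) for c, s in genome.items()}
        coverage = None
        if config.get("coverage_bedgraphs"):
            coverage = None
            for path in config["coverage_bedgraphs"]:
                track = read_bedgraph(path, lengths)
                if coverage is None:
                    coverage = track
                else:
                    for c, arr in track.items():
                        coverage[c] = coverage.get(c, 0) + arr
        if config.get("models_gff3"):
            gene_models = read_gff3(config["models_gff3"])
        if config.get("sam"):
            pairs, tally = alignment_filter.filter_sam(config["sam"], genome)
            manifest["filter_tally"] = tally
            sjs = junction_catalog.extract_junctions(
                pairs, genome, min_support=int(config.get("min_support", 2))
            )
            counts = None
        else:
            counts = pd.read_csv(config["counts_tsv"], sep="\t")

    if mode == "synthetic" or counts is not None:
        sjs = junction_catalog.junctions_from_counts(
            counts, genome, min_support=int(config.get("min_support", 2))
        )

    # two-pass scoring: a 5'ss matrix from the branch-filtered set drives the
    # overlap correction, final matrices are rebuilt on the corrected set
    junction_catalog.annotate_junctions(
        sjs, secondary_motif=config.get("secondary_branch_motif",
                                        junction_catalog.SECONDARY_MOTIF)
    )
    max_branch = int(config.get("max_branch_offset", 60))
    prelim = [
        sj for sj in sjs
        if sj.branch is not None and sj.branch.offset_to_3ss <= max_branch
    ]
    five_scores: dict = {}
    if prelim:
        pre_scores, _f, _l = splice_scoring.score_junctions(prelim, genome)
        five_scores = {
            k: (v.five_score if v.five_score is not None else float("-inf"))
            for k, v in pre_scores.items()
        }
    final_sjs, report = junction_catalog.refine_junctions(
        sjs, five_scores, max_branch_offset=max_branch,
        overlap_shift=int(config.get("overlap_shift", 10)),
    )
    scores, fmats, lmats = splice_scoring.score_junctions(final_sjs, genome)
    for sj in final_sjs:
        sj.scores = scores[sj.key()]

    clusters, n_mixed = as_classifier.cluster_junctions(final_sjs)
    if coverage is None:
        manifest["stage_notices"].append(
            "no coverage input: IR/IC split skipped for singleton clusters"
        )
    records, ir_records = as_classifier.classify_clusters(clusters, coverage)
    summary = as_classifier.summarize_events(records, clusters, gene_models)

    features = compute_features(final_sjs, clusters, records, ir_records)
    comparisons = []
    for feature in ("length", "gc", "five_score", "three_score", "branch_score"):
        for cls_a, cls_b in (("IC", "IR"), ("IR", "IA_minus_IR"), ("IC", "IA_minus_IR")):
            present = features["cls"].value_counts()
            if present.get(cls_a, 0) > 0 and present.get(cls_b, 0) > 0:
                if features.loc[features["cls"] == cls_a, feature].notna().any() and \
                   features.loc[features["cls"] == cls_b, feature].notna().any():
                    comparisons.append(compare_classes(features, feature, cls_a, cls_b))
    iso_table, regressions = isoform_stats(clusters, records, scores)

    # ---- write artifacts
    files = {}

    def _write(name, df):
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        files[name] = name

    _write("junctions.tsv", junction_catalog.junctions_to_table(final_sjs))
    _write("matrices.tsv", splice_scoring.matrices_to_table(fmats, lmats))
    _write(
        "report.tsv",
        pd.DataFrame(
            [
                {
                    "n_input": report.n_input,
                    "n_no_branch": report.n_no_branch,
                    "n_branch_too_far": report.n_branch_too_far,
                    "n_overlap_corrected": report.n_overlap_corrected,
                    "n_n_excluded": report.n_n_excluded,
                    "n_final": report.n_final,
                    "n_mixed_strand_clusters": n_mixed,
                }
            ]
        ),
    )
    _write(
        "clusters.tsv",
        pd.DataFrame(
            [
                {
                    "cluster_id": c.cluster_id,
                    "chrom": c.chrom,
                    "strand": c.strand,
                    "start": c.span[0],
                    "end": c.span[1],
                    "n_members": len(c.members),
                    "event_type": r.event_type,
                    "k": r.k,
                    "complex_code": r.complex_code,
                }
                for c, r in zip(clusters, records)
            ]
        ),
    )
    _write(
        "ir.tsv",
        pd.DataFrame(
            [
                {
                    "chrom": r.junction_key[0],
                    "strand": r.junction_key[1],
                    "intron_start": r.junction_key[2],
                    "intron_end": r.junction_key[3],
                    "irr": r.irr,
                    "irr_bin": r.irr_bin,
                    "coverage_class": r.coverage_class,
                }
                for r in ir_records
            ]
        ),
    )
    _write("features.tsv", features)
    _write(
        "comparisons.tsv",
        pd.DataFrame(
            [
                {
                    "feature": c.feature,
                    "cls_a": c.cls_a,
                    "cls_b": c.cls_b,
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                    "direction": c.direction,
                }
                for c in comparisons
            ]
        ),
    )
    _write("isoforms.tsv", iso_table)
    _write(
        "regressions.tsv",
        pd.DataFrame(
            [
                {
                    "pair_type": r.pair_type,
                    "slope": r.slope,
                    "intercept": r.intercept,
                    "r_squared": r.r_squared,
                    "p_value": r.p_value,
                    "n": r.n,
                    "defined": r.defined,
                    "log_base": "e",
                }
                for r in regressions.values()
            ]
        ),
    )
    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["summary.json"] = "summary.json"
    manifest["files"] = files
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "junctions": final_sjs,
        "report": report,
        "clusters": clusters,
        "records": records,
        "ir_records": ir_records,
        "summary": summary,
        "features": features,
        "comparisons": comparisons,
        "isoforms": iso_table,
        "regressions": regressions,
        "scores": scores,
        "truth": truth,
        "manifest": manifest,
    }
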