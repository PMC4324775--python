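"""Recovery metrics of a pipeline run against a planted truth set.

These helpers compare what the catalog/classifier recovered with what the
simulator planted; they are the measurement side of simulation studies and
of the package's own acceptance checks.
"""

from __future__ import annotations

from .downstream_stats import isoform_stats
from .io import revcomp
from .junction_catalog import find_branch_site

PAIR_CLASSES = ("A5SS", "A3SS", "A5SS_AND_A3SS", "A5SS_OR_A3SS")


def ir_recovery(truth, records, clusters, min_irr: float = 0.0) -> tuple[int, int]:
    """(recovered, planted) retained introns with planted IRR >= min_irr."""
    ir_clusters = set()
    rec_by_id = {r.cluster_id: r for r in records}
    span_to_cluster = {}
    for c in clusters:
        if len(c.members) == 1:
            span_to_cluster[c.members[0].key()] = c.cluster_id
    recovered = planted = 0
    for intron in truth.introns:
        if intron.label != "IR" or (intron.irr or 0.0) < min_irr:
            continue
        planted += 1
        cid = span_to_cluster.get((intron.chrom, intron.strand, intron.start, intron.end))
        if cid is not None and rec_by_id[cid].event_type == "IR":
            recovered += 1
    return recovered, planted


def pair_label_accuracy(truth, records, clusters, classes=("A5SS", "A3SS")):
    """(correctly labelled, planted) two-junction events of the given classes."""
    rec_by_id = {r.cluster_id: r for r in records}
    cluster_of = {}
    for c in clusters:
        for j in c.members:
            cluster_of[j.key()] = c
    correct = planted = 0
    for ev in truth.events:
        if ev.cls not in classes:
            continue
        planted += 1
        cids = {cluster_of[j.key()].cluster_id for j in ev.junctions if j.key() in cluster_of}
        if len(cids) != 1:
            continue
        rec = rec_by_id[cids.pop()]
        if rec.event_type == ev.cls:
            correct += 1
    return correct, planted


def branch_recovery(truth, genome) -> tuple[int, int]:
    """(primary-tier hits at the planted position, planted branch points)."""
    hits = total = 0
    for intron in truth.introns:
        total += 1
        seq = genome[intron.chrom][intron.start - 1 : intron.end]
        if intron.strand == "-":
            seq = revcomp(seq)
        b = find_branch_site(seq)
        if b is not None and b.motif_tier == "primary" and b.a_pos == intron.branch_a_pos:
            hits += 1
    return hits, total


def usage_slope(truth, records, clusters, pair_type: str = "A5SS"):
    """Regression of the realized log frequency ratio on the planted score
    difference; returns the RegressionResult for the given pair type."""
    _table, regs = isoform_stats(clusters, records, truth.planted_scores())
    return regs[pair_type]
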