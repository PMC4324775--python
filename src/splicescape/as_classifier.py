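"""Clustering of splice junctions and alternative-splicing classification.

Junctions are clustered by single-linkage intron-span overlap (>= 1 shared
base on the same chromosome); clusters mixing strands are excluded.  Each
cluster receives exactly one event record:

* singleton clusters are retained introns (IR) when any intronic base has
  read coverage >= 1, else constitutive introns (IC); IR events carry the
  intron retention ratio IRR = median intronic coverage / pooled junction
  support, binned [0,0.01), [0.01,0.1), [0.1,1), [1,inf), and a high/low
  coverage class (high = every intronic base covered by >= 2 reads);
* two-junction clusters are A5SS (shared acceptor), A3SS (shared donor),
  "A5SS and A3SS" (nested spans) or "A5SS or A3SS" (staggered overlap);
* clusters of >= 3 junctions are MA5SS/MA3SS when all members share an
  acceptor/donor, exon skipping for the specific three-junction pattern, and
  otherwise COMPLEX, coded by the total junction count plus the tallies of
  pairwise labels.

Donor and acceptor are taken in transcription orientation: on the plus
strand the donor is the intron start and the acceptor the intron end; on the
minus strand the roles of the genomic ends swap.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

IRR_BIN_EDGES = (0.0, 0.01, 0.1, 1.0)
IRR_BIN_LABELS = ("[0,0.01)", "[0.01,0.1)", "[0.1,1)", "[1,inf)")

PAIR_TYPES = ("A5SS", "A3SS", "A5SS_AND_A3SS", "A5SS_OR_A3SS")


@dataclass
class SJCluster:
    cluster_id: str
    strand: str
    members: list  # SpliceJunction, >= 1

    @property
    def chrom(self):
        return self.members[0].chrom

    @property
    def span(self):
        return (
            min(j.intron_start for j in self.members),
            max(j.intron_end for j in self.members),
        )


@dataclass
class ASEventRecord:
    cluster_id: str
    event_type: str
    k: int = 1  # member count (for MA5SS(k)/MA3SS(k))
    complex_code: str = ""

    @property
    def is_AS(self) -> bool:
        return self.event_type not in ("IC", "UNASSESSED_SINGLE")


@dataclass
class IRRecord:
    junction_key: tuple
    irr: float
    irr_bin: str
    coverage_class: str  # high | low


def irr_bin(irr: float) -> str:
    """Left-closed/right-open IRR bins, last bin open-ended."""
    for edge, label in zip(reversed(IRR_BIN_EDGES), reversed(IRR_BIN_LABELS)):
        if irr >= edge:
            return label
    return IRR_BIN_LABELS[0]


def cluster_junctions(sjs):
    """Single-linkage overlap clustering; mixed-strand components dropped.

    Returns (clusters sorted by position, n_mixed_strand_excluded).
    """
    ordered = sorted(sjs, key=lambda j: (j.chrom, j.intron_start, j.intron_end, j.strand))
    components = []
    current, cur_chrom, cur_end = [], None, -1
    for sj in ordered:
        if sj.chrom != cur_chrom or sj.intron_start > cur_end:
            if current:
                components.append(current)
            current, cur_chrom, cur_end = [sj], sj.chrom, sj.intron_end
        else:
            current.append(sj)
            cur_end = max(cur_end, sj.intron_end)
    if current:
        components.append(current)

    clusters, n_mixed = [], 0
    idx = 0
    for members in components:
        strands = {j.strand for j in members}
        if len(strands) > 1:
            n_mixed += 1
            continue
        idx += 1
        clusters.append(SJCluster(f"cluster{idx:06d}", strands.pop(), members))
    return clusters, n_mixed


def _donor_acceptor(sj):
    """(donor coordinate, acceptor coordinate) in transcription orientation."""
    if sj.strand == "+":
        return sj.intron_start, sj.intron_end
    return sj.intron_end, sj.intron_start


def classify_pair(a, b) -> str:
    """Label of a two-junction overlap relationship.

    Order of arguments does not change the label.  Raises on mixed strands
    (clusters are single-strand by construction).
    """
    if a.strand != b.strand:
        raise ValueError("cannot classify junctions on different strands")
    da, aa = _donor_acceptor(a)
    db, ab = _donor_acceptor(b)
    if aa == ab and da != db:
        return "A5SS"
    if da == db and aa != ab:
        return "A3SS"
    if a.intron_start > b.intron_end or b.intron_start > a.intron_end:
        return "disjoint"
    nested = (a.intron_start <= b.intron_start and b.intron_end <= a.intron_end) or (
        b.intron_start <= a.intron_start and a.intron_end <= b.intron_end
    )
    return "A5SS_AND_A3SS" if nested else "A5SS_OR_A3SS"


def classify_single(cluster: SJCluster, coverage):
    """IR/IC call plus IRR statistics for a singleton cluster.

    ``coverage`` is a pooled per-base track, dict chrom -> int array
    (0-based).  IR when any intronic base has coverage >= 1; coverage class
    high when every intronic base has coverage >= 2.
    """
    sj = cluster.members[0]
    cov = np.asarray(coverage[sj.chrom][sj.intron_start - 1 : sj.intron_end])
    if cov.size == 0 or cov.max() < 1:
        return ASEventRecord(cluster.cluster_id, "IC"), None
    irr = float(np.median(cov)) / sj.pooled_support
    rec = IRRecord(
        junction_key=sj.key(),
        irr=irr,
        irr_bin=irr_bin(irr),
        coverage_class="high" if cov.min() >= 2 else "low",
    )
    return ASEventRecord(cluster.cluster_id, "IR"), rec


def classify_multi(cluster: SJCluster) -> ASEventRecord:
    """MA5SS/MA3SS, the three-junction exon-skipping pattern, or COMPLEX."""
    members = cluster.members
    k = len(members)
    das = [_donor_acceptor(j) for j in members]
    if len({aa for _, aa in das}) == 1:
        return ASEventRecord(cluster.cluster_id, "MA5SS", k=k)
    if len({da for da, _ in das}) == 1:
        return ASEventRecord(cluster.cluster_id, "MA3SS", k=k)
    if k == 3 and _is_exon_skipping(members):
        return ASEventRecord(cluster.cluster_id, "EXON_SKIPPING", k=k)
    tallies = Counter(
        classify_pair(members[i], members[j])
        for i in range(k)
        for j in range(i + 1, k)
    )
    code = (
        f"n={k};A5SS={tallies['A5SS']};A3SS={tallies['A3SS']};"
        f"AND={tallies['A5SS_AND_A3SS']};OR={tallies['A5SS_OR_A3SS']}"
    )
    return ASEventRecord(cluster.cluster_id, "COMPLEX", k=k, complex_code=code)


def _is_exon_skipping(members) -> bool:
    """Three junctions: two base-disjoint short ones whose outer boundaries
    are shared by a third spanning junction (the skipped exon sits between)."""
    for spanning in members:
        inner = [j for j in members if j is not spanning]
        a, b = sorted(inner, key=lambda j: j.intron_start)
        if a.intron_end >= b.intron_start:
            continue  # inner junctions must not share bases
        if (
            spanning.intron_start == a.intron_start
            and spanning.intron_end == b.intron_end
        ):
            return True
    return False


def classify_clusters(clusters, coverage=None):
    """Classify every cluster; returns (event records, IR records).

    Without a coverage track, singleton clusters cannot be split into IR/IC
    and are labelled 'UNASSESSED_SINGLE' (not counted as AS).
    """
    records, ir_records = [], []
    for cluster in clusters:
        n = len(cluster.members)
        if n == 1:
            if coverage is None:
                records.append(ASEventRecord(cluster.cluster_id, "UNASSESSED_SINGLE"))
                continue
            rec, ir = classify_single(cluster, coverage)
            records.append(rec)
            if ir is not None:
                ir_records.append(ir)
        elif n == 2:
            label = classify_pair(cluster.members[0], cluster.members[1])
            if label == "disjoint":  # cannot happen under overlap clustering
                label = "COMPLEX"
            records.append(ASEventRecord(cluster.cluster_id, label, k=2))
        else:
            records.append(classify_multi(cluster))
    return records, ir_records


@dataclass
class AccountingSummary:
    n_clusters: int = 0
    n_single: int = 0
    n_IC: int = 0
    n_IR: int = 0
    n_two_sj: int = 0
    two_sj_by_type: dict = field(default_factory=dict)
    n_multi: int = 0
    multi_by_type: dict = field(default_factory=dict)
    n_AS_events: int = 0
    as_cluster_ratio: float = 0.0
    n_AS_genes: int | None = None
    n_multiexonic_AS_genes: int | None = None

    @classmethod
    def from_counts(cls, n_ic: int, n_ir: int, two_sj: dict, multi: dict):
        """Build the summary arithmetic from category counts alone."""
        n_two = sum(two_sj.values())
        n_multi = sum(multi.values())
        n_single = n_ic + n_ir
        n_clusters = n_single + n_two + n_multi
        n_as = n_ir + n_two + n_multi
        return cls(
            n_clusters=n_clusters,
            n_single=n_single,
            n_IC=n_ic,
            n_IR=n_ir,
            n_two_sj=n_two,
            two_sj_by_type=dict(two_sj),
            n_multi=n_multi,
            multi_by_type=dict(multi),
            n_AS_events=n_as,
            as_cluster_ratio=n_as / n_clusters if n_clusters else 0.0,
        )

    def as_dict(self) -> dict:
        out = {
            "n_clusters": self.n_clusters,
            "n_single": self.n_single,
            "n_IC": self.n_IC,
            "n_IR": self.n_IR,
            "n_two_sj": self.n_two_sj,
            "n_multi": self.n_multi,
            "n_AS_events": self.n_AS_events,
            "as_cluster_ratio": self.as_cluster_ratio,
        }
        for t, n in sorted(self.two_sj_by_type.items()):
            out[f"two_sj_{t}"] = n
        for t, n in sorted(self.multi_by_type.items()):
            out[f"multi_{t}"] = n
        if self.n_AS_genes is not None:
            out["n_AS_genes"] = self.n_AS_genes
            out["n_multiexonic_AS_genes"] = self.n_multiexonic_AS_genes
        return out


def summarize_events(records, clusters=None, gene_models=None) -> AccountingSummary:
    """Fill the per-class accounting from classified cluster records.

    With ``gene_models`` (and the clusters, for junction spans), an AS gene
    is any model whose span overlaps at least one junction of an AS-labelled
    cluster; each gene counts once, multiexonic = >= 2 annotated exons.
    """
    single = [r for r in records if r.event_type in ("IC", "IR", "UNASSESSED_SINGLE")]
    two = [r for r in records if r.k == 2 and r.event_type in PAIR_TYPES + ("COMPLEX",)]
    multi = [r for r in records if r.k >= 3]
    n_ic = sum(r.event_type != "IR" for r in single)
    n_ir = sum(r.event_type == "IR" for r in single)
    two_by = dict(Counter(r.event_type for r in two))
    multi_by = dict(
        Counter(
            f"{r.event_type}({r.k})" if r.event_type in ("MA5SS", "MA3SS") else r.event_type
            for r in multi
        )
    )
    summary = AccountingSummary.from_counts(n_ic, n_ir, two_by, multi_by)

    if gene_models is not None and clusters is not None:
        by_id = {r.cluster_id: r for r in records}
        as_spans = []
        for cluster in clusters:
            rec = by_id.get(cluster.cluster_id)
            if rec is not None and rec.is_AS:
                for j in cluster.members:
                    as_spans.append((j.chrom, j.intron_start, j.intron_end))
        as_genes = set()
        multiexonic = set()
        for g in gene_models:
            for chrom, s, e in as_spans:
                if chrom == g.chrom and s <= g.end and g.start <= e:
                    as_genes.add(g.gene_id)
                    if g.n_exons >= 2:
                        multiexonic.add(g.gene_id)
                    break
        summary.n_AS_genes = len(as_genes)
        summary.n_multiexonic_AS_genes = len(multiexonic)
    return summary
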