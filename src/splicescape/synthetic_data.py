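"""Synthetic fungal transcriptome with planted splicing truth.

Emulates the study system end to end: a small multi-chromosome genome with
non-overlapping multi-exon genes; short GC-balanced introns (median length
72 bp by default) carrying donor/acceptor consensus, a planted branch point
and a polypyrimidine tract; alternative-splicing events of every taxonomy
class planted by editing gene sequences (alternative donors/acceptors with
their own branch machinery); and per-sample junction read counts plus
per-base coverage with known intron-retention ratios.

Design notes
------------
* Planted branch points always carry an intact primary-motif (CURAY) core;
  ``consensus_strength`` degrades the degenerate motif positions and the
  extended donor/acceptor consensus, never the core — a branch that matches
  no motif tier would have no recoverable truth position.  Accidental motif
  instances 3' of a planted branch are scrubbed (the offending A mutated) so
  the planted position is the 3'-most instance by construction.
* Every planted junction receives a support floor equal to the catalog's
  minimum support, with the overdispersed remainder on top (mean preserved):
  a planted event is only a truth-set event if both isoforms are sequenced.
* Counts are negative-binomial (dispersion ``coverage_noise``); pure Poisson
  understates RNA-seq dispersion.
* One pseudo-random stream per (purpose, seed) so adding draws to one stage
  does not perturb another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneModel, revcomp, write_bedgraph, write_fasta, write_gff3
from .junction_catalog import (
    ALTERNATE_MOTIFS,
    PRIMARY_MOTIF,
    SECONDARY_MOTIF,
    _match_at,
    _motif_sets,
)

_STREAMS = {"genome": 11, "genes": 23, "events": 37, "reads": 53, "sam": 71}

#: fraction of planted events per class, roughly the relative frequencies a
#: deep fungal RNA-seq survey observes (intron retention dominates)
DEFAULT_CLASS_FRACTIONS = {
    "IC": 0.2481,
    "IR": 0.71,
    "A5SS": 0.013,
    "A3SS": 0.023,
    "A5SS_AND_A3SS": 0.0015,
    "A5SS_OR_A3SS": 0.0012,
    "MA5SS": 0.001,
    "MA3SS": 0.0022,
}

#: minimum host-intron length per multi-junction class (room for alternative
#: sites, their branch machinery and scrub zones)
MIN_HOST_LENGTH = {
    "A5SS": 90,
    "A3SS": 90,
    "A5SS_AND_A3SS": 105,
    "A5SS_OR_A3SS": 105,
    "MA5SS": 110,
    "MA3SS": 130,
}

CONSENSUS_DONOR = "GTAAGT"
BRANCH_UP, BRANCH_DOWN = 3, 1  # CTAAC: 3 bases before the A, 1 after


class PlacementError(ValueError):
    """Chromosomes too small to place the requested genes."""


@dataclass
class GenomeSpec:
    n_chroms: int = 3
    chrom_length: int = 200_000
    gc_background: float = 0.51
    seed: int = 0

    def __post_init__(self):
        if self.n_chroms < 1:
            raise ValueError("n_chroms must be >= 1")
        if self.chrom_length < 1000:
            raise ValueError("chrom_length must be >= 1000")
        if not 0 < self.gc_background < 1:
            raise ValueError("gc_background must lie in (0, 1)")


@dataclass
class GeneSpec:
    n_genes: int = 150
    exons_per_gene: tuple = (2, 6)  # inclusive uniform range
    exon_length: tuple = (80, 300)  # inclusive uniform range, bp
    intron_length_median: float = 72.0
    intron_length_sigma: float = 0.45  # lognormal shape
    min_intron_length: int = 30
    intron_gc: float = 0.49
    consensus_strength: float = 0.95
    gc_ag_rate: float = 0.017
    at_ac_rate: float = 0.005

    def __post_init__(self):
        if self.min_intron_length < 10:
            raise ValueError("introns shorter than 10 bp are not representable")
        if not 0 <= self.consensus_strength <= 1:
            raise ValueError("consensus_strength must lie in [0, 1]")


@dataclass
class EventSpec:
    class_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    irr_range: tuple = (0.001, 2.0)  # log-uniform planted IRR for IR introns
    usage_link_beta: float = 1.0
    delta_score_sd: float = 1.5
    max_abs_delta: float = 2.5  # keeps both isoforms observable at finite depth

    def __post_init__(self):
        total = sum(self.class_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if self.irr_range[0] < 0:
            raise ValueError("planted IRR must be >= 0")


@dataclass
class ReadSimSpec:
    junction_depth_mean: float = 60.0
    n_samples: int = 2
    coverage_noise: float = 10.0  # negative-binomial dispersion (higher = tamer)
    read_length: int = 75
    support_floor: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.junction_depth_mean <= 0:
            raise ValueError("junction_depth_mean must be > 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @property
    def sample_names(self):
        return tuple(f"s{i + 1}" for i in range(self.n_samples))


@dataclass
class TruthIntron:
    intron_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int  # genomic, 1-based inclusive
    end: int
    t_start: int  # transcription-orientation offset within the gene, 0-based
    t_end: int
    branch_a_pos: int  # 1-based within the intron (transcription orientation)
    branch_offset_to_3ss: int
    ppt_start: int | None = None  # 1-based within the intron
    ppt_seq: str | None = None
    label: str = "IC"
    irr: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TruthJunction:
    chrom: str
    strand: str
    start: int
    end: int
    five_score: float = 0.0  # planted site strengths (arbitrary units)
    three_score: float = 0.0

    def key(self):
        return (self.chrom, self.strand, self.start, self.end)


@dataclass
class TruthEvent:
    event_id: str
    cls: str
    gene_id: str
    junctions: list  # [TruthJunction], host/reference isoform first
    irr: float | None = None
    delta_score: float | None = None
    usage_p: float | None = None  # planted relative frequency of junctions[0]


@dataclass
class _TruthGene:
    gene_id: str
    chrom: str
    strand: str
    offset: int  # 0-based genomic offset of the rendered gene
    seq: list  # transcription-orientation sequence (mutable char list)
    exons_t: list  # [(start, end)] 0-based inclusive, transcription orientation

    @property
    def length(self) -> int:
        return len(self.seq)

    def genomic_span(self, a: int, b: int) -> tuple:
        """Map a transcription-orientation span to a 1-based genomic span."""
        if self.strand == "+":
            return (self.offset + a + 1, self.offset + b + 1)
        L = self.length
        return (self.offset + L - b, self.offset + L - a)

    def render(self) -> str:
        s = "".join(self.seq)
        return s if self.strand == "+" else revcomp(s)


@dataclass
class TruthSet:
    seed: int
    genes: list = field(default_factory=list)  # [_TruthGene]
    introns: list = field(default_factory=list)  # [TruthIntron]
    events: list = field(default_factory=list)  # [TruthEvent]
    genome: dict = field(default_factory=dict)  # chrom -> sequence

    def gene_models(self) -> list:
        models = []
        for g in self.genes:
            exons = sorted(g.genomic_span(a, b) for a, b in g.exons_t)
            models.append(GeneModel(g.gene_id, g.chrom, g.strand, exons))
        return models

    def to_gff3(self, path) -> None:
        write_gff3(self.gene_models(), path)

    def intron_by_id(self) -> dict:
        return {i.intron_id: i for i in self.introns}

    def all_junctions(self) -> list:
        """Every junction the sequencer will support, singletons + events."""
        out = []
        covered = {
            j.key() for ev in self.events for j in ev.junctions
        }
        for intron in self.introns:
            if intron.label in ("IC", "IR"):
                key = (intron.chrom, intron.strand, intron.start, intron.end)
                if key not in covered:
                    out.append(
                        TruthJunction(intron.chrom, intron.strand, intron.start, intron.end)
                    )
        for ev in self.events:
            out.extend(ev.junctions)
        return out

    def planted_scores(self) -> dict:
        """Planted per-junction site strengths, keyed like catalog junctions."""
        return {j.key(): (j.five_score, j.three_score) for j in self.all_junctions()}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], seed])


def _random_seq(rng, n: int, gc: float) -> np.ndarray:
    return rng.choice(
        np.array(list("ATGC")), size=n, p=[(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
    )


_ALL_TIERS = (
    [_motif_sets(PRIMARY_MOTIF), _motif_sets(SECONDARY_MOTIF)]
    + [_motif_sets(m) for m in ALTERNATE_MOTIFS]
)


def _scrub_branch_zone(seq: list, lo_q: int, hi_q: int) -> None:
    """Mutate the anchor A of any branch-tier motif whose anchor (4th motif
    position) lies in [lo_q, hi_q] (0-based, inclusive).  Terminates because
    every mutation removes an A from the zone."""
    changed = True
    while changed:
        changed = False
        for q in range(max(lo_q, 3), hi_q + 1):
            if seq[q] != "A":
                continue
            window = "".join(seq[q - 3 : q + 2])
            if len(window) == 5 and any(_match_at(window, 0, m) for m in _ALL_TIERS):
                seq[q] = "C"
                changed = True


def _maybe(rng, strength: float, consensus: str, alphabet: str = "ACGT") -> str:
    return consensus if rng.random() < strength else alphabet[rng.integers(4)]


def _write_branch(seq: list, p0: int, rng, strength: float) -> None:
    """Plant a CURAY instance with the A at 0-based index p0 (CTAAC-like:
    degenerate positions drift away from consensus as strength drops)."""
    seq[p0 - 3] = "C"
    seq[p0 - 2] = "T"
    seq[p0 - 1] = "A" if rng.random() < strength else "G"  # R
    seq[p0] = "A"
    seq[p0 + 1] = "C" if rng.random() < strength else "T"  # Y


def _build_intron(rng, length: int, spec: GeneSpec, donor="GT", acceptor="AG"):
    """One intron in transcription orientation.

    Returns (char list, 0-based branch-A index, ppt (start0, seq) or None).
    """
    L = length
    s = list(_random_seq(rng, L, spec.intron_gc))
    strength = spec.consensus_strength
    s[0], s[1] = donor[0], donor[1]
    for i in range(2, 6):
        if i < L - 10:
            s[i] = _maybe(rng, strength, CONSENSUS_DONOR[i])
    s[L - 2], s[L - 1] = acceptor[0], acceptor[1]
    if L >= 13:
        s[L - 3] = _maybe(rng, strength, "T")

    d3 = int(np.clip(round(rng.normal(15, 4)), 8, min(40, L - 12)))
    p0 = L - 1 - d3  # 0-based index of the branch A; offset_to_3ss == d3
    _write_branch(s, p0, rng, strength)

    ppt = None
    if p0 - 10 >= 6:
        w0 = int(rng.integers(6, p0 - 10 + 1))
        tract = ["T", "T", "T"] + ["T" if rng.random() < 0.6 else "C" for _ in range(3)]
        s[w0 : w0 + 6] = tract
        ppt = (w0, "".join(tract))

    _scrub_branch_zone(s, p0 + 1, L - 4)
    return s, p0, ppt


def generate_genome(genome_spec: GenomeSpec, gene_spec: GeneSpec):
    """Random genome plus planted gene/intron structures.

    Genes are placed sequentially, never overlapping; raises PlacementError
    when the chromosomes cannot host the requested genes.  Every intron
    carries a canonical GT..AG (or GC..AG / AT-AC at the configured rates),
    a branch point and, where room allows, a polypyrimidine tract.
    """
    g_rng = _rng(genome_spec.seed, "genome")
    s_rng = _rng(genome_spec.seed, "genes")
    chrom_names = [f"chr{i + 1}" for i in range(genome_spec.n_chroms)]
    chroms = {
        name: list(_random_seq(g_rng, genome_spec.chrom_length, genome_spec.gc_background))
        for name in chrom_names
    }
    truth = TruthSet(seed=genome_spec.seed)

    margin = 400
    cursors = {name: margin for name in chrom_names}
    chrom_idx = 0
    n_intron = 0
    for gi in range(gene_spec.n_genes):
        strand = "+" if s_rng.random() < 0.5 else "-"
        n_ex = int(s_rng.integers(gene_spec.exons_per_gene[0], gene_spec.exons_per_gene[1] + 1))
        exon_lens = [
            int(s_rng.integers(gene_spec.exon_length[0], gene_spec.exon_length[1] + 1))
            for _ in range(n_ex)
        ]
        intron_lens = []
        for _ in range(n_ex - 1):
            while True:
                L = int(round(np.exp(s_rng.normal(np.log(gene_spec.intron_length_median),
                                                  gene_spec.intron_length_sigma))))
                if L >= gene_spec.min_intron_length:
                    intron_lens.append(L)
                    break

        seq: list = []
        exons_t, introns_t = [], []
        for k, elen in enumerate(exon_lens):
            a = len(seq)
            seq.extend(_random_seq(s_rng, elen, genome_spec.gc_background))
            exons_t.append((a, len(seq) - 1))
            if k < n_ex - 1:
                u = s_rng.random()
                if u < gene_spec.at_ac_rate:
                    donor, acceptor = "AT", "AC"
                elif u < gene_spec.at_ac_rate + gene_spec.gc_ag_rate:
                    donor, acceptor = "GC", "AG"
                else:
                    donor, acceptor = "GT", "AG"
                iseq, p0, ppt = _build_intron(
                    s_rng, intron_lens[k], gene_spec, donor, acceptor
                )
                a = len(seq)
                seq.extend(iseq)
                introns_t.append((a, len(seq) - 1, p0, ppt))

        glen = len(seq)
        placed = False
        for _ in range(len(chrom_names)):
            name = chrom_names[chrom_idx]
            gap = int(s_rng.integers(200, 501))
            start = cursors[name] + gap
            if start + glen + margin <= genome_spec.chrom_length:
                placed = True
                break
            chrom_idx = (chrom_idx + 1) % len(chrom_names)
        if not placed:
            raise PlacementError(
                f"cannot place gene {gi + 1}/{gene_spec.n_genes}: chromosomes full"
            )
        gene = _TruthGene(
            gene_id=f"gene{gi + 1:05d}",
            chrom=name,
            strand=strand,
            offset=start,
            seq=seq,
            exons_t=exons_t,
        )
        cursors[name] = start + glen
        chrom_idx = (chrom_idx + 1) % len(chrom_names)
        truth.genes.append(gene)

        for (a, b, p0, ppt) in introns_t:
            n_intron += 1
            gs, ge = gene.genomic_span(a, b)
            ilen = b - a + 1
            truth.introns.append(
                TruthIntron(
                    intron_id=f"intron{n_intron:06d}",
                    gene_id=gene.gene_id,
                    chrom=name,
                    strand=strand,
                    start=gs,
                    end=ge,
                    t_start=a,
                    t_end=b,
                    branch_a_pos=(p0 + 1),
                    branch_offset_to_3ss=ilen - (p0 + 1),
                    ppt_start=None if ppt is None else ppt[0] + 1,
                    ppt_seq=None if ppt is None else ppt[1],
                )
            )

    # render genes into the background
    for gene in truth.genes:
        rendered = gene.render()
        chroms[gene.chrom][gene.offset : gene.offset + gene.length] = rendered
    genome = {name: "".join(chars) for name, chars in chroms.items()}
    truth.genome = genome
    return genome, truth


# ---------------------------------------------------------------------------
# event planting


def _edit_alt_donor(seq: list, i0: int, d: int) -> None:
    seq[i0 + d : i0 + d + 6] = list(CONSENSUS_DONOR)


def _edit_alt_acceptor(seq: list, i0: int, m: int, rng, strength: float) -> int:
    """Plant an alternative acceptor ending the intron at local offset m
    (the alternative intron is intron-local [0, m-1]).  Returns the local
    0-based branch index of the alternative intron."""
    seq[i0 + m - 2], seq[i0 + m - 1] = "A", "G"
    seq[i0 + m - 3] = "T"
    p0 = m - 16  # branch A 15 bp from the alternative 3'ss
    _write_branch(seq, i0 + p0, rng, strength)
    _scrub_local(seq, i0, p0 + 1, m - 4)
    return p0


def _scrub_local(seq: list, i0: int, lo: int, hi: int) -> None:
    sub = seq[i0 : i0 + hi + 4]
    _scrub_branch_zone(sub, lo, hi)
    seq[i0 : i0 + hi + 4] = sub


def plant_events(truth: TruthSet, event_spec: EventSpec, genome: dict | None = None):
    """Assign AS classes to planted introns and edit the genome accordingly.

    Multi-junction classes get alternative donors/acceptors (with their own
    branch machinery) written into host introns; IR introns get a planted
    retention ratio.  Edited genes are re-rendered into ``genome`` (or into
    ``truth.genome`` when omitted).  Raises when a multi-junction class has
    no remaining intron long enough to host its alternative sites.
    """
    if genome is None:
        genome = truth.genome
    rng = _rng(truth.seed, "events")
    genes = {g.gene_id: g for g in truth.genes}
    introns = list(truth.introns)
    n = len(introns)

    # largest-remainder apportionment of introns to classes
    fracs = event_spec.class_fractions
    raw = {cls: frac * n for cls, frac in fracs.items()}
    counts = {cls: int(math.floor(v)) for cls, v in raw.items()}
    leftover = n - sum(counts.values())
    for cls in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True):
        if leftover <= 0:
            break
        counts[cls] += 1
        leftover -= 1

    order = list(rng.permutation(n))
    assigned: dict[str, list] = {cls: [] for cls in counts}
    taken = set()
    multi_classes = [c for c in counts if c in MIN_HOST_LENGTH]
    for cls in sorted(multi_classes):
        need = counts[cls]
        for idx in order:
            if need == 0:
                break
            if idx in taken:
                continue
            if introns[idx].length >= MIN_HOST_LENGTH[cls]:
                assigned[cls].append(idx)
                taken.add(idx)
                need -= 1
        if need > 0:
            raise ValueError(
                f"not enough introns >= {MIN_HOST_LENGTH[cls]} bp to host {cls}"
            )
    rest = [i for i in order if i not in taken]
    pos = 0
    for cls in ("IR", "IC"):
        take = rest[pos : pos + counts.get(cls, 0)]
        assigned.setdefault(cls, []).extend(take)
        pos += len(take)
    for idx in rest[pos:]:  # rounding slack goes to IC
        assigned.setdefault("IC", []).append(idx)

    edited_genes = set()
    n_event = 0

    def new_event_id():
        nonlocal n_event
        n_event += 1
        return f"event{n_event:05d}"

    for cls in sorted(assigned):
        for idx in sorted(assigned[cls]):
            intron = introns[idx]
            intron.label = cls
            if cls == "IC":
                continue
            gene = genes[intron.gene_id]
            if cls == "IR":
                lo, hi = event_spec.irr_range
                irr = float(np.exp(rng.uniform(np.log(max(lo, 1e-9)), np.log(hi))))
                intron.irr = irr
                truth.events.append(
                    TruthEvent(
                        new_event_id(),
                        "IR",
                        gene.gene_id,
                        [TruthJunction(intron.chrom, intron.strand, intron.start, intron.end)],
                        irr=irr,
                    )
                )
                continue

            jxs = _plant_multi_junction(gene, intron, cls, rng, event_spec)
            delta = float(
                np.clip(
                    rng.normal(0.0, event_spec.delta_score_sd),
                    -event_spec.max_abs_delta,
                    event_spec.max_abs_delta,
                )
            )
            usage_p = None
            if cls in ("A5SS", "A3SS", "A5SS_AND_A3SS", "A5SS_OR_A3SS"):
                usage_p = 1.0 / (1.0 + math.exp(-event_spec.usage_link_beta * delta))
                _attach_planted_scores(jxs, cls, delta)
            truth.events.append(
                TruthEvent(
                    new_event_id(),
                    cls,
                    gene.gene_id,
                    jxs,
                    delta_score=delta if usage_p is not None else None,
                    usage_p=usage_p,
                )
            )
            edited_genes.add(gene.gene_id)

    for gid in edited_genes:
        gene = genes[gid]
        rendered = gene.render()
        chrom = genome[gene.chrom]
        genome[gene.chrom] = (
            chrom[: gene.offset] + rendered + chrom[gene.offset + gene.length :]
        )
    truth.genome = genome
    return truth


def _attach_planted_scores(jxs, cls, delta):
    """Split the planted score difference across the class-relevant sites;
    junctions[0] is the stronger isoform when delta > 0."""
    a, b = jxs[0], jxs[1]
    if cls == "A5SS":
        a.five_score, b.five_score = delta / 2, -delta / 2
    elif cls == "A3SS":
        a.three_score, b.three_score = delta / 2, -delta / 2
    else:  # combined classes: the link is through the sum of both sites
        a.five_score, a.three_score = delta / 4, delta / 4
        b.five_score, b.three_score = -delta / 4, -delta / 4


def _plant_multi_junction(gene, intron, cls, rng, event_spec):
    """Edit the host intron to carry the class's alternative sites; returns
    the planted TruthJunctions (host/reference isoform first)."""
    seq = gene.seq
    i0, i1 = intron.t_start, intron.t_end
    L = i1 - i0 + 1
    p0 = intron.branch_a_pos - 1  # host branch, intron-local 0-based
    strength = 1.0  # alternative sites are planted at full consensus

    def span(a_local, b_local):
        return gene.genomic_span(i0 + a_local, i0 + b_local)

    def tj(a_local, b_local):
        s, e = span(a_local, b_local)
        return TruthJunction(intron.chrom, intron.strand, s, e)

    if cls == "A5SS":
        d = int(rng.integers(15, min(45, L - 60) + 1))
        _edit_alt_donor(seq, i0, d)
        return [tj(0, L - 1), tj(d, L - 1)]

    if cls == "A3SS":
        m = int(rng.integers(40, p0 - 3 + 1))
        _edit_alt_acceptor(seq, i0, m, rng, strength)
        return [tj(0, L - 1), tj(0, m - 1)]

    if cls == "A5SS_AND_A3SS":
        m = int(rng.integers(55, p0 - 3 + 1))
        d = int(rng.integers(15, m - 40 + 1))
        _edit_alt_donor(seq, i0, d)
        _edit_alt_acceptor(seq, i0, m, rng, strength)
        return [tj(0, L - 1), tj(d, m - 1)]

    if cls == "A5SS_OR_A3SS":
        m = int(rng.integers(55, p0 - 3 + 1))
        d = int(rng.integers(15, m - 25 + 1))
        _edit_alt_acceptor(seq, i0, m, rng, strength)
        _edit_alt_donor(seq, i0, d)
        return [tj(0, m - 1), tj(d, L - 1)]

    if cls == "MA5SS":
        d1 = int(rng.integers(15, 26))
        d2 = int(rng.integers(d1 + 15, min(50, L - 60) + 1))
        _edit_alt_donor(seq, i0, d1)
        _edit_alt_donor(seq, i0, d2)
        return [tj(0, L - 1), tj(d1, L - 1), tj(d2, L - 1)]

    if cls == "MA3SS":
        m2 = int(rng.integers(60, p0 - 3 + 1))
        m1 = int(rng.integers(40, m2 - 20 + 1))
        _edit_alt_acceptor(seq, i0, m2, rng, strength)
        _edit_alt_acceptor(seq, i0, m1, rng, strength)
        return [tj(0, L - 1), tj(0, m1 - 1), tj(0, m2 - 1)]

    raise ValueError(f"unknown event class {cls}")


# ---------------------------------------------------------------------------
# sequencing simulation


@dataclass
class SimResult:
    counts: pd.DataFrame  # chrom, intron_start, intron_end, strand, sample, reads
    coverage: dict  # sample -> chrom -> int array (0-based per-base)
    sample_names: tuple

    def pooled_coverage(self) -> dict:
        pooled: dict = {}
        for sample in self.sample_names:
            for chrom, arr in self.coverage[sample].items():
                if chrom in pooled:
                    pooled[chrom] = pooled[chrom] + arr
                else:
                    pooled[chrom] = arr.copy()
        return pooled

    def write(self, outdir) -> dict:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        counts_path = outdir / "counts.tsv"
        self.counts.to_csv(counts_path, sep="\t", index=False)
        paths["counts"] = counts_path
        for sample in self.sample_names:
            p = outdir / f"coverage.{sample}.bedgraph"
            write_bedgraph(self.coverage[sample], p)
            paths[f"coverage.{sample}"] = p
        return paths


def _nb(rng, mean: float, k: float, size=None):
    """Overdispersed count draw: negative binomial with dispersion k."""
    mean = max(mean, 1e-9)
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size=size)


def simulate_sequencing(truth: TruthSet, read_spec: ReadSimSpec) -> SimResult:
    """Per-sample junction counts and per-base coverage from the truth set.

    Junction counts are apportioned by planted isoform usage on top of a
    per-junction support floor; intronic coverage of IR introns is scaled so
    median intronic coverage / pooled junction support matches the planted
    IRR; constitutive introns get zero intronic coverage.
    """
    rng = _rng(read_spec.seed, "reads")
    samples = read_spec.sample_names
    k = read_spec.coverage_noise
    depth = read_spec.junction_depth_mean
    floor = max(1, math.ceil(read_spec.support_floor / read_spec.n_samples))

    chrom_lengths = {c: len(s) for c, s in truth.genome.items()}
    coverage = {
        s: {c: np.zeros(n, dtype=np.int64) for c, n in chrom_lengths.items()}
        for s in samples
    }

    # exonic background coverage per gene
    for gene in sorted(truth.genes, key=lambda g: g.gene_id):
        for (a, b) in gene.exons_t:
            gs, ge = gene.genomic_span(a, b)
            for s in samples:
                coverage[s][gene.chrom][gs - 1 : ge] += _nb(rng, depth, k, ge - gs + 1)

    rows = []

    def add_counts(jx, pooled_mean: float) -> int:
        """Append per-sample counts for one junction; returns the pooled total."""
        per_sample = pooled_mean / len(samples)
        total = 0
        for s in samples:
            reads = floor + int(_nb(rng, max(per_sample - floor, 0.01), k))
            rows.append(
                {
                    "chrom": jx.chrom,
                    "intron_start": jx.start,
                    "intron_end": jx.end,
                    "strand": jx.strand,
                    "sample": s,
                    "reads": reads,
                }
            )
            total += reads
        return total

    pooled_depth = depth * len(samples)
    support_by_intron = {}
    for ev in sorted(truth.events, key=lambda e: e.event_id):
        if ev.cls == "IR":
            jx = ev.junctions[0]
            support_by_intron[jx.key()] = add_counts(jx, pooled_depth)
        elif ev.cls in ("A5SS", "A3SS", "A5SS_AND_A3SS", "A5SS_OR_A3SS"):
            p = ev.usage_p
            add_counts(ev.junctions[0], 2 * pooled_depth * p)
            add_counts(ev.junctions[1], 2 * pooled_depth * (1 - p))
        else:  # MA5SS / MA3SS: even split across isoforms
            for jx in ev.junctions:
                add_counts(jx, pooled_depth)

    # constitutive singleton introns
    for intron in sorted(truth.introns, key=lambda i: i.intron_id):
        if intron.label == "IC":
            jx = TruthJunction(intron.chrom, intron.strand, intron.start, intron.end)
            add_counts(jx, pooled_depth)

    # intronic coverage for IR introns, scaled to the planted IRR
    for intron in sorted(truth.introns, key=lambda i: i.intron_id):
        if intron.label != "IR" or intron.irr is None:
            continue
        key = (intron.chrom, intron.strand, intron.start, intron.end)
        support = support_by_intron.get(key, 0)
        per_sample_mean = intron.irr * support / read_spec.n_samples
        L = intron.length
        for s in samples:
            if intron.irr <= 0:
                continue
            coverage[s][intron.chrom][intron.start - 1 : intron.end] += _nb(
                rng, per_sample_mean, k, L
            )

    counts = pd.DataFrame(rows).sort_values(
        ["chrom", "intron_start", "intron_end", "strand", "sample"], kind="mergesort"
    )
    counts = counts.reset_index(drop=True)
    return SimResult(counts=counts, coverage=coverage, sample_names=samples)


def write_sam(truth: TruthSet, counts: pd.DataFrame, read_spec: ReadSimSpec, path):
    """Minimal spliced paired-end SAM consistent with the junction counts.

    One fixed read length; each junction read pair has one mate spanning the
    intron as a reference skip and one downstream exonic mate.  No quality
    strings, single placement per pair (NH:i:1).
    """
    import pysam

    genome = truth.genome
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in sorted(genome.items())],
        "RG": [{"ID": s} for s in read_spec.sample_names],
    }
    rlen = read_spec.read_length
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {c: i for i, (c, _s) in enumerate(sorted(genome.items()))}
        sam_header = out.header
        for row in counts.itertuples(index=False):
            chrom, js, je = row.chrom, int(row.intron_start), int(row.intron_end)
            ilen = je - js + 1
            for r in range(int(row.reads)):
                anchor = 25 + (r % 15)  # left anchor 25..39 bp
                left0 = js - 1 - anchor  # 0-based mate1 start
                right_len = rlen - anchor
                seq1 = (
                    genome[chrom][left0 : js - 1]
                    + genome[chrom][je : je + right_len]
                )
                m2_start0 = je + right_len + 9
                seq2 = genome[chrom][m2_start0 : m2_start0 + rlen]
                name = f"{row.sample}:{chrom}:{js}:{je}:{r}"

                a = pysam.AlignedSegment(sam_header)
                a.query_name = name
                a.query_sequence = seq1
                a.flag = 99
                a.reference_id = tid[chrom]
                a.reference_start = left0
                a.mapping_quality = 50
                a.cigarstring = f"{anchor}M{ilen}N{right_len}M"
                a.next_reference_id = tid[chrom]
                a.next_reference_start = m2_start0
                a.template_length = m2_start0 + rlen - left0
                a.set_tag("NH", 1)
                a.set_tag("RG", row.sample)

                b = pysam.AlignedSegment(sam_header)
                b.query_name = name
                b.query_sequence = seq2
                b.flag = 147
                b.reference_id = tid[chrom]
                b.reference_start = m2_start0
                b.mapping_quality = 50
                b.cigarstring = f"{rlen}M"
                b.next_reference_id = tid[chrom]
                b.next_reference_start = left0
                b.template_length = -(m2_start0 + rlen - left0)
                b.set_tag("NH", 1)
                b.set_tag("RG", row.sample)
                out.write(a)
                out.write(b)


def simulate_dataset(
    genome_spec: GenomeSpec,
    gene_spec: GeneSpec,
    event_spec: EventSpec,
    read_spec: ReadSimSpec,
    outdir=None,
    emit_sam: bool = False,
):
    """Full synthetic dataset: genome, planted truth, counts and coverage.

    With ``outdir``, writes genome.fa, truth.gff3, counts.tsv and per-sample
    bedGraph tracks (plus reads.sam when requested); returns
    (genome, truth, SimResult).
    """
    genome, truth = generate_genome(genome_spec, gene_spec)
    plant_events(truth, event_spec, genome)
    sim = simulate_sequencing(truth, read_spec)
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(truth.genome, outdir / "genome.fa")
        truth.to_gff3(outdir / "truth.gff3")
        sim.write(outdir)
        if emit_sam:
            write_sam(truth, sim.counts, read_spec, outdir / "reads.sam")
    return truth.genome, truth, sim
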