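"""Coverage-based transcript detection and read-derived model assembly.

Two related reconstructions:

* transcript units — purely coverage-driven: transcriptionally active
  regions (TARs) are maximal runs longer than 35 bp with every base covered
  by at least 4 reads; TARs joined by at least one read pair form a unit,
  kept when longer than 150 bp with mean depth >= 10 reads/base;
* assembled models — read-driven: read pairs are first merged into
  artificial reads (overlapping mates merged; short intervals filled as
  exonic; a single junction in the interval embedded as a skip when the
  non-junction interval remainder is < 85 bp), then overlap-chained into
  contigs.  Chaining requires identical junction content in the shared
  region, which blocks chimeras.  Models need >= 100 bases, every base
  supported by >= 2 reads, and are screened against reference gene models
  (> 10 bp overlap) and structural RNAs (any overlap).  The longest ORF over
  the spliced exon sequence (6 frames, or 3 when an embedded junction fixes
  the strand) is annotated; models code when the ORF exceeds 30 aa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import revcomp

MIN_TAR_LENGTH = 35  # strictly longer than
MIN_TAR_DEPTH = 4
MIN_UNIT_LENGTH = 150  # strictly longer than
MIN_UNIT_DEPTH = 10.0
MAX_EMBED_REMAINDER = 85
MIN_MODEL_LENGTH = 100
MIN_MODEL_DEPTH = 2
MODEL_LINK_DISTANCE = 30
LOCUS_LINK_DISTANCE = 10
MIN_ORF_AA = 30  # coding requires strictly more

STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODON_TABLE = None


@dataclass
class TranscriptionallyActiveRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    mean_depth: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptUnit:
    unit_id: str
    chrom: str
    tars: list

    @property
    def start(self) -> int:
        return min(t.start for t in self.tars)

    @property
    def end(self) -> int:
        return max(t.end for t in self.tars)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def mean_depth(self) -> float:
        total = sum(t.mean_depth * t.length for t in self.tars)
        return total / sum(t.length for t in self.tars)


@dataclass
class ArtificialRead:
    chrom: str
    blocks: list  # [(start, end)] 1-based inclusive, sorted
    strand: str = "unknown"

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def junctions(self) -> list:
        return [
            (self.blocks[i][1] + 1, self.blocks[i + 1][0] - 1)
            for i in range(len(self.blocks) - 1)
        ]


@dataclass
class AssembledModel:
    model_id: str
    chrom: str
    exons: list  # [(start, end)]
    strand: str = "unknown"
    locus_id: str = ""
    cds: tuple | None = None  # (spliced start offset 0-based, spliced end excl.)
    protein: str = ""
    complete: bool = False

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return len(self.protein) > MIN_ORF_AA


def detect_tars(coverage: dict[str, np.ndarray]):
    """Maximal runs longer than 35 bp with every base at depth >= 4."""
    tars = []
    for chrom in sorted(coverage):
        cov = np.asarray(coverage[chrom])
        ok = cov >= MIN_TAR_DEPTH
        if not ok.any():
            continue
        run_starts, run_ends = _runs(ok)
        for s0, e0 in zip(run_starts, run_ends):
            length = e0 - s0
            if length > MIN_TAR_LENGTH:
                tars.append(
                    TranscriptionallyActiveRegion(
                        chrom, s0 + 1, e0, float(cov[s0:e0].mean())
                    )
                )
    return tars


def _runs(mask: np.ndarray):
    """(starts, ends) of True runs, 0-based half-open."""
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    return np.flatnonzero(diff == 1), np.flatnonzero(diff == -1)


def link_units(tars, pairs):
    """Group TARs joined by read pairs into transcript units.

    A pair links every TAR its aligned blocks overlap; connected components
    form candidate units, kept when longer than 150 bp with mean depth >= 10.
    """
    by_chrom: dict[str, list] = {}
    for i, t in enumerate(tars):
        by_chrom.setdefault(t.chrom, []).append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: tars[i].start)

    parent = list(range(len(tars)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for pair in pairs:
        idxs = by_chrom.get(pair.chrom)
        if not idxs:
            continue
        touched = []
        blocks = [b for mate in pair.mates for b in mate]
        for i in idxs:
            t = tars[i]
            if any(s <= t.end and t.start <= e for s, e in blocks):
                touched.append(i)
        for i in touched[1:]:
            union(touched[0], i)

    groups: dict[int, list] = {}
    for i in range(len(tars)):
        groups.setdefault(find(i), []).append(i)
    units = []
    n = 0
    for root in sorted(groups, key=lambda r: (tars[r].chrom, tars[r].start)):
        members = [tars[i] for i in groups[root]]
        unit = TranscriptUnit("", members[0].chrom, members)
        if unit.length > MIN_UNIT_LENGTH and unit.mean_depth >= MIN_UNIT_DEPTH:
            n += 1
            unit.unit_id = f"unit{n:05d}"
            units.append(unit)
    return units


def _merge_blocks(blocks):
    merged = []
    for s, e in sorted(blocks):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def make_artificial_reads(pairs, sjs):
    """Merge read pairs (and at most one interval junction) into artificial
    reads; pairs that qualify for no artificial read pass their mates through
    as single-mate reads.

    Junction spans come from the finalized catalog; a junction lies "in the
    interval" when its intron span is contained in the gap between the mates'
    facing ends.
    """
    sj_by_chrom: dict[str, list] = {}
    for sj in sjs:
        sj_by_chrom.setdefault(sj.chrom, []).append(
            (sj.intron_start, sj.intron_end, sj.strand)
        )
    for v in sj_by_chrom.values():
        v.sort()

    reads = []
    for pair in pairs:
        mates = [m for m in pair.mates if m]
        if len(mates) == 1:
            reads.append(ArtificialRead(pair.chrom, list(mates[0]), pair.strand))
            continue
        interval = pair.interval_length
        if interval < 0:
            blocks = _merge_blocks(mates[0] + mates[1])
            reads.append(ArtificialRead(pair.chrom, blocks, pair.strand))
            continue
        left, right = sorted(mates, key=lambda m: m[0][0])
        gap_start, gap_end = left[-1][1] + 1, right[0][0] - 1
        inside = [
            (s, e, strand)
            for (s, e, strand) in sj_by_chrom.get(pair.chrom, [])
            if gap_start <= s and e <= gap_end
        ]
        if not inside:
            blocks = _merge_blocks(
                left[:-1] + [(left[-1][0], right[0][1])] + right[1:]
            )
            reads.append(ArtificialRead(pair.chrom, blocks, pair.strand))
        elif len(inside) == 1:
            js, je, jstrand = inside[0]
            if interval - (je - js + 1) < MAX_EMBED_REMAINDER:
                blocks = _merge_blocks(
                    left[:-1]
                    + [(left[-1][0], js - 1), (je + 1, right[0][1])]
                    + right[1:]
                )
                strand = pair.strand if pair.strand != "unknown" else jstrand
                reads.append(ArtificialRead(pair.chrom, blocks, strand))
            else:
                reads.append(ArtificialRead(pair.chrom, list(left), pair.strand))
                reads.append(ArtificialRead(pair.chrom, list(right), pair.strand))
        else:
            reads.append(ArtificialRead(pair.chrom, list(left), pair.strand))
            reads.append(ArtificialRead(pair.chrom, list(right), pair.strand))
    return reads


def _junction_content(read, lo, hi):
    """Junctions of a read restricted to the window [lo, hi]."""
    return tuple(
        (s, e) for s, e in read.junctions() if s <= hi and e >= lo
    )


def _compatible(a: ArtificialRead, b: ArtificialRead) -> bool:
    """Overlapping reads chain only with identical junction content in the
    shared region (prevents chimeric contigs)."""
    lo, hi = max(a.start, b.start), min(a.end, b.end)
    if lo > hi:
        return False
    # require a shared aligned base, not just span overlap
    shared = any(
        bs <= ae and as_ <= be
        for as_, ae in a.blocks
        for bs, be in b.blocks
    )
    if not shared:
        return False
    return _junction_content(a, lo, hi) == _junction_content(b, lo, hi)


def assemble_models(reads):
    """Chain compatible overlapping reads into models.

    Contigs with < 100 exonic bases or any base supported by < 2 reads are
    dropped; overlapping surviving models share a locus; partial models
    within 30 bp inside a locus, and neighboring loci within 10 bp, are
    linked (their block sets unioned, the gap kept as an intron-like hole).
    """
    reads = sorted(reads, key=lambda r: (r.chrom, r.start, r.end))
    parent = list(range(len(reads)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    active: list[int] = []
    for i, r in enumerate(reads):
        active = [
            j for j in active if reads[j].chrom == r.chrom and reads[j].end >= r.start
        ]
        for j in active:
            if _compatible(reads[j], r):
                union(i, j)
        active.append(i)

    groups: dict[int, list] = {}
    for i in range(len(reads)):
        groups.setdefault(find(i), []).append(i)

    models = []
    n = 0
    for root in sorted(groups, key=lambda r: (reads[r].chrom, reads[r].start)):
        members = [reads[i] for i in groups[root]]
        chrom = members[0].chrom
        lo = min(r.start for r in members)
        hi = max(r.end for r in members)
        depth = np.zeros(hi - lo + 1, dtype=np.int32)
        for r in members:
            for s, e in r.blocks:
                depth[s - lo : e - lo + 1] += 1
        strands = {r.strand for r in members} - {"unknown"}
        strand = strands.pop() if len(strands) == 1 else "unknown"
        # supported region: bases with depth >= 2, split at unsupported holes
        ok = depth >= MIN_MODEL_DEPTH
        starts, ends = _runs(ok)
        # junction holes inside the span stay introns; unsupported holes split
        junctions = sorted({j for r in members for j in r.junctions()})
        for s0, e0 in _split_runs_at_gaps(starts, ends, junctions, lo):
            exons = _carve_exons(lo + s0, lo + e0 - 1, junctions)
            # models carved from one read component are partial models of
            # the same locus (split only by unsupported holes)
            model = AssembledModel("", chrom, exons, strand=strand, locus_id=f"comp{root}")
            if model.exonic_length >= MIN_MODEL_LENGTH:
                n += 1
                model.model_id = f"model{n:05d}"
                models.append(model)
    return _link_models(models)


def _split_runs_at_gaps(starts, ends, junctions, lo):
    """Merge supported runs whose separating hole is exactly a junction span
    (introns are not coverage gaps in the model sense)."""
    runs = list(zip(starts, ends))
    if not runs:
        return []
    jset = {(s, e) for s, e in junctions}
    merged = [list(runs[0])]
    for s0, e0 in runs[1:]:
        # depth index i maps to genomic position lo + i (both 1-based here)
        hole = (lo + merged[-1][1], lo + s0 - 1)
        if hole in jset:
            merged[-1][1] = e0
        else:
            merged.append([s0, e0])
    return [(s0, e0) for s0, e0 in merged]


def _carve_exons(start, end, junctions):
    """Split the 1-based span [start, end] into exon blocks at the junction
    intron spans fully inside it."""
    exons = []
    cursor = start
    for js, je in junctions:
        if js > cursor and je < end and js > start:
            if js - 1 >= cursor:
                exons.append((cursor, js - 1))
            cursor = je + 1
    exons.append((cursor, end))
    return [b for b in exons if b[0] <= b[1]]


def _link_models(models):
    """Merge overlapping models into loci, then link neighbors: partial
    models <= 30 bp apart within a locus and loci <= 10 bp apart."""
    models = sorted(models, key=lambda m: (m.chrom, m.start, m.end))
    linked = []
    for m in models:
        if linked:
            prev = linked[-1]
            gap = m.start - prev.end - 1
            same_chrom = prev.chrom == m.chrom
            same_locus = prev.locus_id == m.locus_id
            if same_chrom and (
                gap <= 0  # overlapping models merge into one locus
                or gap <= LOCUS_LINK_DISTANCE  # neighboring loci
                or (same_locus and gap <= MODEL_LINK_DISTANCE)  # partial models
            ):
                prev.exons = _merge_blocks(prev.exons + m.exons)
                if prev.strand == "unknown":
                    prev.strand = m.strand
                continue
        linked.append(m)
    for i, m in enumerate(linked, 1):
        m.model_id = f"model{i:05d}"
        m.locus_id = f"locus{i:05d}"
    return linked


# ---------------------------------------------------------------------------
# ORF finding


def spliced_sequence(model: AssembledModel, genome: dict[str, str]) -> str:
    seq = "".join(genome[model.chrom][s - 1 : e] for s, e in model.exons)
    return seq


def _orfs_in_frame(seq: str):
    """(start, end_exclusive, complete) of candidate CDS in one forward frame
    of ``seq`` (frame 0): each ATG paired with the nearest in-frame stop, or
    the sequence end (partial)."""
    codons = [seq[i : i + 3] for i in range(0, len(seq) - 2, 3)]
    out = []
    open_start = None
    for ci, codon in enumerate(codons):
        if codon == "ATG" and open_start is None:
            open_start = ci
        elif codon in STOP_CODONS and open_start is not None:
            out.append((open_start * 3, ci * 3, True))
            open_start = None
    if open_start is not None:
        out.append((open_start * 3, len(codons) * 3, False))
    return out


def find_longest_orf(model: AssembledModel, genome: dict[str, str]):
    """Annotate the model with its longest ORF across all frames.

    Six frames are scanned, or three when the strand is fixed (by an embedded
    junction's donor-acceptor pair).  The CDS runs from a start codon to the
    nearest in-frame stop; ORFs without a stop before the model end are kept
    as partial.  Coding requires strictly more than 30 aa.
    """
    fwd = spliced_sequence(model, genome).upper()
    strands = ("+", "-") if model.strand == "unknown" else (model.strand,)
    best = None  # (aa_len, strand, frame, start, end, complete, protein)
    for strand in strands:
        seq = fwd if strand == "+" else revcomp(fwd)
        for frame in range(3):
            for s, e, complete in _orfs_in_frame(seq[frame:]):
                aa = (e - s) // 3
                cand = (aa, strand == "+", -frame, seq[frame + s : frame + e])
                if best is None or cand[:3] > best[0]:
                    best = (cand[:3], strand, frame, frame + s, frame + e, complete, cand[3])
    if best is None or (best[4] - best[3]) // 3 == 0:
        model.cds, model.protein, model.complete = None, "", False
        return model
    _key, strand, frame, s, e, complete, cds_seq = best
    protein = _translate(cds_seq)
    model.cds = (s, e)
    model.protein = protein
    model.complete = complete and cds_seq[:3] == "ATG"
    return model


def _translate(seq: str) -> str:
    from Bio.Seq import Seq

    aa = str(Seq(seq).translate())
    return aa.rstrip("*")


def screen_against_reference(models, reference, structural_rna=()):
    """Drop models overlapping reference models by > 10 bp, or structural
    RNA annotations (rRNA/tRNA) by any amount."""
    kept = []
    for m in models:
        drop = False
        for ref in reference:
            if ref.chrom != m.chrom:
                continue
            ov = min(m.end, ref.end) - max(m.start, ref.start) + 1
            if ov > 10:
                drop = True
                break
        if not drop:
            for rna in structural_rna:
                if rna.chrom != m.chrom:
                    continue
                if m.start <= rna.end and rna.start <= m.end:
                    drop = True
                    break
        if not drop:
            kept.append(m)
    return kept
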