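"""Splice-junction catalog: extraction, branch/PPT annotation, refinement.

A splice junction (SJ) is one spliced-out intron evidenced by reads spanning
an exon-exon boundary, identified by (chromosome, strand, intron span).  The
catalog pipeline is:

1. extract junctions with pooled support >= min_support (default 2);
2. locate the branch point by hierarchical motif search (primary CURAY,
   secondary UURAY by default, then a degenerate-YURAY family) taking the
   3'-most instance, and the polypyrimidine tract as the 3'-most maximal-T
   window of six consecutive non-adenine bases with >= 3 T;
3. refine: drop junctions with no branch or with the branch A more than
   60 bp from the 3'ss; collapse same-length overlapping junction pairs whose
   starts differ by < 10 bp onto the higher-5'ss-score form (support is
   transferred, alignment-error correction); drop junctions whose intron
   contains an N.

All motifs are DNA-alphabet (U == T).  Intron sequences are handled in
transcription orientation: minus-strand slices are reverse complemented
before any motif work.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .io import revcomp
from .splice_scoring import SpliceScores

#: IUPAC degeneracy classes used by the branch-motif tiers
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "N": "ACGT", "U": "T",
}

PRIMARY_MOTIF = "CURAY"
SECONDARY_MOTIF = "UURAY"  # the alternative reading UUARY is one config change
#: degenerate-YURAY family: first, third or fifth position freed
ALTERNATE_MOTIFS = ("NURAY", "YUNAY", "YURAN")

MIN_INTRON_LENGTH = 10
CANONICAL_PAIRS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}
_MINUS_PAIRS = {(revcomp(a), revcomp(d)) for d, a in CANONICAL_PAIRS}


def _motif_sets(motif: str) -> list[str]:
    return [_IUPAC[c.upper()] for c in motif]


def _match_at(seq: str, i: int, sets: list[str]) -> bool:
    return all(seq[i + k] in sets[k] for k in range(len(sets)))


@dataclass
class BranchSite:
    """A branch-point call inside one intron (1-based intron offsets)."""

    a_pos: int  # position of the branch A within the intron
    offset_to_3ss: int  # intron length - a_pos
    motif_tier: str  # primary | secondary | alternate
    motif: str  # the matched 5-mer
    window_seq: str | None = None  # 11-base window when fully inside the intron


@dataclass
class PolypyrimidineTract:
    window_start_offset: int  # 1-based start within the intron
    seq: str
    t_count: int
    region: str  # five_to_branch | branch_to_three | no_branch


@dataclass
class SpliceJunction:
    chrom: str
    strand: str
    intron_start: int  # 1-based inclusive, intron only
    intron_end: int
    support: dict = field(default_factory=dict)  # sample -> read-pair count
    donor_dinucleotide: str = ""
    acceptor_dinucleotide: str = ""
    intron_seq: str = ""
    branch: BranchSite | None = None
    tract: PolypyrimidineTract | None = None
    scores: SpliceScores | None = None

    def key(self) -> tuple:
        return (self.chrom, self.strand, self.intron_start, self.intron_end)

    @property
    def pooled_support(self) -> int:
        return sum(self.support.values())

    @property
    def length(self) -> int:
        return self.intron_end - self.intron_start + 1


@dataclass
class JunctionFilterReport:
    n_input: int = 0
    n_no_branch: int = 0
    n_branch_too_far: int = 0
    n_overlap_corrected: int = 0
    n_n_excluded: int = 0

    @property
    def n_final(self) -> int:
        return (
            self.n_input
            - self.n_no_branch
            - self.n_branch_too_far
            - self.n_overlap_corrected
            - self.n_n_excluded
        )


def find_branch_site(
    intron_seq: str, secondary_motif: str = SECONDARY_MOTIF
) -> BranchSite | None:
    """Hierarchical 3'-most branch-motif search.

    Tiers are tried in order (primary, secondary, then the degenerate family
    as a union); within a tier the 3'-most match wins.  The search region
    excludes the final two intron bases so the terminal acceptor dinucleotide
    can never be consumed by a motif.  The branch point is the fourth position
    of the matched 5-mer.
    """
    seq = intron_seq.upper()
    limit = len(seq) - 2  # exclusive end of searchable region
    if limit < 5:
        return None
    tiers = [
        ("primary", [_motif_sets(PRIMARY_MOTIF)]),
        ("secondary", [_motif_sets(secondary_motif)]),
        ("alternate", [_motif_sets(m) for m in ALTERNATE_MOTIFS]),
    ]
    for tier_name, motif_list in tiers:
        for i in range(limit - 5, -1, -1):
            if any(_match_at(seq, i, sets) for sets in motif_list):
                a_pos = i + 4  # 1-based position of the 4th character
                window = None
                if i - 3 >= 0 and a_pos + 4 <= len(seq):
                    window = seq[a_pos - 7 : a_pos + 4]
                return BranchSite(
                    a_pos=a_pos,
                    offset_to_3ss=len(seq) - a_pos,
                    motif_tier=tier_name,
                    motif=seq[i : i + 5],
                    window_seq=window,
                )
    return None


def find_ppt(intron_seq: str, branch_a_pos: int | None) -> PolypyrimidineTract | None:
    """3'-most maximal-T window of 6 consecutive non-A bases with >= 3 T.

    The region label is relative to the branch A: a window ending strictly
    before it lies between the 5'ss and the branch; one starting after it lies
    between the branch and the 3'ss; windows straddling the branch position
    are assigned by their 3'-most base (they cannot contain the A itself).
    """
    seq = intron_seq.upper()
    best: tuple[int, int] | None = None  # (t_count, start index) best-so-far
    for i in range(len(seq) - 5):
        w = seq[i : i + 6]
        if "A" in w or "N" in w:
            continue
        t = w.count("T")
        if t < 3:
            continue
        if best is None or t > best[0] or (t == best[0] and i > best[1]):
            best = (t, i)
    if best is None:
        return None
    t, i = best
    start, end = i + 1, i + 6  # 1-based inclusive
    if branch_a_pos is None:
        region = "no_branch"
    elif end < branch_a_pos:
        region = "five_to_branch"
    elif start > branch_a_pos:
        region = "branch_to_three"
    else:
        region = "branch_to_three" if end > branch_a_pos else "five_to_branch"
    return PolypyrimidineTract(
        window_start_offset=start, seq=seq[i : i + 6], t_count=t, region=region
    )


def orient_dinucleotides(genome: dict[str, str], chrom, strand, start, end):
    """Donor/acceptor dinucleotides in transcription orientation."""
    seq = genome[chrom][start - 1 : end]
    if strand == "-":
        seq = revcomp(seq)
    return seq[:2], seq[-2:], seq


def infer_strand(genome: dict[str, str], chrom: str, start: int, end: int) -> str:
    """Strand of an intron span from its terminal dinucleotides.

    Returns '+', '-', or 'unknown' when neither orientation gives a
    canonical donor-acceptor pair.
    """
    seq = genome[chrom][start - 1 : end]
    pair = (seq[:2], seq[-2:])
    if pair in CANONICAL_PAIRS:
        return "+"
    if pair in _MINUS_PAIRS:
        return "-"
    return "unknown"


def extract_junctions(pairs, genome: dict[str, str], min_support: int = 2):
    """Collapse filtered aligned pairs into supported splice junctions.

    One junction per distinct (chrom, strand, intron span) with pooled
    support >= min_support; a pair counts once per junction even when both
    mates span it.  Intron sequences are extracted strand-aware.
    """
    seen: dict[tuple, dict[str, set]] = defaultdict(lambda: defaultdict(set))
    for pair in pairs:
        for (s, e) in pair.skips():
            strand = pair.strand
            if strand not in ("+", "-"):
                strand = infer_strand(genome, pair.chrom, s, e)
                if strand == "unknown":
                    continue
            seen[(pair.chrom, strand, s, e)][pair.sample].add(pair.pair_id)
    junctions = []
    for (chrom, strand, s, e), per_sample in sorted(seen.items()):
        support = {sample: len(ids) for sample, ids in sorted(per_sample.items())}
        if sum(support.values()) < min_support:
            continue
        junctions.append(make_junction(genome, chrom, strand, s, e, support))
    return junctions


def make_junction(genome, chrom, strand, start, end, support) -> SpliceJunction:
    if end - start + 1 < MIN_INTRON_LENGTH:
        raise ValueError(f"intron shorter than {MIN_INTRON_LENGTH} bp: {start}-{end}")
    if start < 1 or end > len(genome[chrom]):
        raise ValueError(f"intron {chrom}:{start}-{end} exceeds chromosome bounds")
    donor, acceptor, seq = orient_dinucleotides(genome, chrom, strand, start, end)
    return SpliceJunction(
        chrom=chrom,
        strand=strand,
        intron_start=start,
        intron_end=end,
        support=dict(support),
        donor_dinucleotide=donor,
        acceptor_dinucleotide=acceptor,
        intron_seq=seq,
    )


def junctions_from_counts(counts, genome: dict[str, str], min_support: int = 2):
    """Build junctions from a counts table (chrom, intron_start, intron_end,
    strand, sample, reads), pooling samples and applying the support floor."""
    grouped: dict[tuple, dict] = defaultdict(dict)
    for row in counts.itertuples(index=False):
        key = (row.chrom, row.strand, int(row.intron_start), int(row.intron_end))
        grouped[key][row.sample] = grouped[key].get(row.sample, 0) + int(row.reads)
    out = []
    for (chrom, strand, s, e), support in sorted(grouped.items()):
        if sum(support.values()) < min_support:
            continue
        out.append(make_junction(genome, chrom, strand, s, e, support))
    return out


def annotate_junctions(sjs, secondary_motif: str = SECONDARY_MOTIF):
    """Attach branch-site and polypyrimidine-tract calls in place."""
    for sj in sjs:
        sj.branch = find_branch_site(sj.intron_seq, secondary_motif)
        sj.tract = find_ppt(
            sj.intron_seq, sj.branch.a_pos if sj.branch else None
        )
    return sjs


def _overlap_candidates(a: SpliceJunction, b: SpliceJunction, shift: int) -> bool:
    """Same-length overlapping pair with starts within ``shift`` bp — the
    alignment-error signature targeted by the correction step."""
    return (
        a.chrom == b.chrom
        and a.strand == b.strand
        and a.length == b.length
        and a.key() != b.key()
        and 0 < abs(a.intron_start - b.intron_start) < shift
        and a.intron_start <= b.intron_end
        and b.intron_start <= a.intron_end
    )


def refine_junctions(
    sjs,
    five_scores: dict,
    max_branch_offset: int = 60,
    overlap_shift: int = 10,
):
    """Branch-distance filter, overlap correction, and N exclusion.

    ``five_scores`` maps junction keys to 5'ss scores used to decide which
    member of a same-length overlapping pair is the alignment error; the
    loser's support is added to the survivor.  Ties go to higher pooled
    support, then to the 5'-most junction.
    """
    report = JunctionFilterReport(n_input=len(sjs))
    kept = []
    for sj in sjs:
        if sj.branch is None:
            report.n_no_branch += 1
        elif sj.branch.offset_to_3ss > max_branch_offset:
            report.n_branch_too_far += 1
        else:
            kept.append(sj)

    # overlap correction: collapse erroneous same-length overlapping forms
    span_key = lambda j: (j.chrom, j.intron_start, j.intron_end, j.strand)
    alive: dict[tuple, SpliceJunction] = {j.key(): j for j in kept}
    changed = True
    while changed:
        changed = False
        ordered = sorted(alive.values(), key=span_key)
        for i, a in enumerate(ordered):
            if a.key() not in alive:
                continue
            for b in ordered[i + 1 :]:
                if b.chrom != a.chrom or b.intron_start > a.intron_end:
                    break
                if b.key() not in alive or not _overlap_candidates(a, b, overlap_shift):
                    continue
                loser, winner = _pick_erroneous(a, b, five_scores)
                for sample, n in loser.support.items():
                    winner.support[sample] = winner.support.get(sample, 0) + n
                del alive[loser.key()]
                report.n_overlap_corrected += 1
                changed = True
                if loser is a:
                    break
            else:
                continue

    final = []
    for sj in sorted(alive.values(), key=lambda j: j.key()):
        if "N" in sj.intron_seq.upper():
            report.n_n_excluded += 1
        else:
            final.append(sj)
    return final, report


def _pick_erroneous(a, b, five_scores):
    """Return (loser, winner): lower 5'ss score loses; ties broken by lower
    pooled support, then by 3'-most start (keep the 5'-most)."""
    sa = five_scores.get(a.key(), float("-inf"))
    sb = five_scores.get(b.key(), float("-inf"))
    if sa != sb:
        return (a, b) if sa < sb else (b, a)
    if a.pooled_support != b.pooled_support:
        return (a, b) if a.pooled_support < b.pooled_support else (b, a)
    return (b, a) if a.intron_start < b.intron_start else (a, b)


def junctions_to_table(sjs):
    """One row per junction with all annotations (tab-separated friendly)."""
    import pandas as pd

    rows = []
    for sj in sorted(sjs, key=lambda j: j.key()):
        row = {
            "chrom": sj.chrom,
            "strand": sj.strand,
            "intron_start": sj.intron_start,
            "intron_end": sj.intron_end,
            "length": sj.length,
            "donor": sj.donor_dinucleotide,
            "acceptor": sj.acceptor_dinucleotide,
            "pooled_support": sj.pooled_support,
        }
        for sample, n in sorted(sj.support.items()):
            row[f"reads_{sample}"] = n
        if sj.branch:
            row.update(
                branch_a_pos=sj.branch.a_pos,
                branch_offset_to_3ss=sj.branch.offset_to_3ss,
                branch_tier=sj.branch.motif_tier,
                branch_motif=sj.branch.motif,
            )
        if sj.tract:
            row.update(
                ppt_start=sj.tract.window_start_offset,
                ppt_seq=sj.tract.seq,
                ppt_t_count=sj.tract.t_count,
                ppt_region=sj.tract.region,
            )
        if sj.scores:
            row.update(
                five_score=sj.scores.five_score,
                three_score=sj.scores.three_score,
                branch_score=sj.scores.branch_score,
            )
        rows.append(row)
    return pd.DataFrame(rows)
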