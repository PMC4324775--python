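"""Filtering of raw spliced paired-end alignments.

Keeps uniquely mapped, strand-consistent pairs with a mate interval below
5 kbp, then trims unreliable terminal anchors:

* any terminal aligned block shorter than ``min_anchor`` (default 5 bp) is
  removed — short anchors are dominated by alignment error;
* when a read end runs a few bases past a candidate junction boundary (the
  acceptor within ``junction_window`` of the read 5' end, or the donor within
  it of the read 3' end), those bases most likely belong on the far side of
  the junction and are trimmed, provided the terminal anchor is longer than
  ``min_total_anchor``.

Negative intervals (overlapping mates) are allowed only when the overlapping
alignments agree base for base.  "Uniquely mapped" is operationalised as a
single reported placement (NH tag absent or equal to 1).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .junction_catalog import infer_strand

logger = logging.getLogger(__name__)

MAX_INTERVAL = 5000
MIN_SKIP = 10  # reference gaps >= this are introns; smaller gaps are merged


@dataclass
class AnchorPolicy:
    min_anchor: int = 5
    junction_window: int = 6
    min_total_anchor: int = 12

    def __post_init__(self):
        if min(self.min_anchor, self.junction_window, self.min_total_anchor) < 0:
            raise ValueError("anchor policy values must be >= 0")


@dataclass
class AlignedPair:
    """A uniquely mapped read pair, blocks 1-based inclusive per mate."""

    pair_id: str
    chrom: str
    mates: tuple  # (blocks_mate1, blocks_mate2), each sorted [(start, end)]
    strand: str = "unknown"  # transcript strand from donor-acceptor dinucleotides
    mate_reversed: tuple = (False, True)
    sample: str = "pooled"

    @property
    def interval_length(self) -> int:
        """Gap in bp between the mates' facing ends (negative = overlap)."""
        b1, b2 = self.mates
        if not b1 or not b2:
            return 0
        left, right = (b1, b2) if b1[0][0] <= b2[0][0] else (b2, b1)
        return right[0][0] - left[-1][1] - 1

    def skips(self):
        """Intron spans implied by within-mate reference gaps >= MIN_SKIP."""
        out = []
        for blocks in self.mates:
            for i in range(len(blocks) - 1):
                gap_start = blocks[i][1] + 1
                gap_end = blocks[i + 1][0] - 1
                if gap_end - gap_start + 1 >= MIN_SKIP:
                    out.append((gap_start, gap_end))
        return sorted(set(out))

    def aligned_span(self):
        spans = [b for blocks in self.mates for b in blocks]
        return min(s for s, _ in spans), max(e for _, e in spans)


def _blocks_from_segment(seg):
    """Merge pysam blocks separated by < MIN_SKIP (deletions) and convert to
    1-based inclusive."""
    merged = []
    for s0, e0 in seg.get_blocks():
        s, e = s0 + 1, e0  # 0-based half-open -> 1-based inclusive
        if merged and s - merged[-1][1] - 1 < MIN_SKIP:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _mate_strand(seg, genome) -> str:
    """Transcript strand implied by a mate's skips, 'conflict' on disagreement."""
    strands = set()
    blocks = _blocks_from_segment(seg)
    for i in range(len(blocks) - 1):
        s, e = blocks[i][1] + 1, blocks[i + 1][0] - 1
        if e - s + 1 >= MIN_SKIP:
            strands.add(infer_strand(genome, seg.reference_name, s, e))
    strands.discard("unknown")
    if len(strands) > 1:
        return "conflict"
    return strands.pop() if strands else "unknown"


def _mates_agree(seg1, seg2) -> bool:
    """Base-for-base agreement of overlapping mate alignments."""
    maps = []
    for seg in (seg1, seg2):
        ref2base = {}
        if seg.query_sequence:
            for qpos, rpos in seg.get_aligned_pairs(matches_only=True):
                ref2base[rpos] = seg.query_sequence[qpos]
        maps.append(ref2base)
    common = set(maps[0]) & set(maps[1])
    return all(maps[0][r] == maps[1][r] for r in common)


def filter_pairs(alignments, genome: dict[str, str], sample: str = "pooled"):
    """Filter a stream of pysam alignments to kept AlignedPairs + a tally.

    Rejection reasons tallied: multimapped, unpaired, different_chrom,
    interval (>= 5 kbp), overlap_contradiction, strand_conflict, malformed.
    """
    tally: Counter = Counter()
    by_name: dict[str, list] = defaultdict(list)
    for seg in alignments:
        try:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            by_name[seg.query_name].append(seg)
        except Exception:  # malformed record
            warnings.warn("skipping malformed alignment record")
            tally["malformed"] += 1

    kept = []
    for name, segs in sorted(by_name.items()):
        if len(segs) != 2:
            tally["unpaired"] += 1
            continue
        # deterministic mate order regardless of record order in the input
        segs = sorted(segs, key=lambda s: (not s.is_read1, s.reference_start))
        seg1, seg2 = segs
        nh = max(seg1.get_tag("NH") if seg1.has_tag("NH") else 1,
                 seg2.get_tag("NH") if seg2.has_tag("NH") else 1)
        if nh > 1:
            tally["multimapped"] += 1
            continue
        if seg1.reference_name != seg2.reference_name:
            tally["different_chrom"] += 1
            continue
        s1 = _mate_strand(seg1, genome)
        s2 = _mate_strand(seg2, genome)
        if "conflict" in (s1, s2) or (
            s1 != "unknown" and s2 != "unknown" and s1 != s2
        ):
            tally["strand_conflict"] += 1
            continue
        strand = s1 if s1 != "unknown" else s2
        pair = AlignedPair(
            pair_id=name,
            chrom=seg1.reference_name,
            mates=(_blocks_from_segment(seg1), _blocks_from_segment(seg2)),
            strand=strand,
            mate_reversed=(seg1.is_reverse, seg2.is_reverse),
            sample=sample,
        )
        if pair.interval_length >= MAX_INTERVAL:
            tally["interval"] += 1
            continue
        if pair.interval_length < 0 and not _mates_agree(seg1, seg2):
            tally["overlap_contradiction"] += 1
            continue
        kept.append(pair)
        tally["kept"] += 1
    return kept, dict(tally)


def filter_sam(path, genome: dict[str, str], sample: str = "pooled"):
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        return filter_pairs(fh, genome, sample=sample)


def _proximity_trim_allowed(anchor_len: int, policy: AnchorPolicy) -> bool:
    """Predicate for the junction-proximity trim (isolated on purpose: the
    rule is applied when the terminal anchor exceeds min_total_anchor)."""
    return anchor_len > policy.min_total_anchor


def _drop_short_terminals(blocks, policy: AnchorPolicy):
    changed = True
    while changed and blocks:
        changed = False
        if blocks[0][1] - blocks[0][0] + 1 < policy.min_anchor:
            blocks.pop(0)
            changed = True
        if blocks and blocks[-1][1] - blocks[-1][0] + 1 < policy.min_anchor:
            blocks.pop(-1)
            changed = True
    return blocks


def _trim_mate(blocks, sj_candidates, policy: AnchorPolicy):
    """Trim one mate's blocks; returns the new block list (possibly empty).

    Junction-proximity trimming is applied geometrically at both read ends:
    a read end extending at most ``junction_window`` bases into a candidate
    intron has those bases trimmed (the acceptor-near-5'-end and
    donor-near-3'-end cases are mirror images of this).  Iterates to a
    fixpoint so the operation is idempotent.
    """
    blocks = [tuple(b) for b in blocks]

    def trim_left(blocks):
        s, e = blocks[0]
        anchor = e - s + 1
        for (js, je) in sj_candidates:
            overlap = je - s + 1  # read bases inside the intron at its end
            if 1 <= overlap <= policy.junction_window and js <= s <= je:
                if _proximity_trim_allowed(anchor, policy):
                    if overlap < anchor:
                        blocks[0] = (s + overlap, e)
                    else:
                        blocks.pop(0)
                return blocks
        return blocks

    def trim_right(blocks):
        s, e = blocks[-1]
        anchor = e - s + 1
        for (js, je) in sj_candidates:
            overlap = e - js + 1  # read bases inside the intron at its start
            if 1 <= overlap <= policy.junction_window and js <= e <= je:
                if _proximity_trim_allowed(anchor, policy):
                    if overlap < anchor:
                        blocks[-1] = (s, e - overlap)
                    else:
                        blocks.pop(-1)
                return blocks
        return blocks

    prev = None
    while blocks and blocks != prev:
        prev = list(blocks)
        blocks = _drop_short_terminals(blocks, policy)
        if blocks and sj_candidates:
            blocks = trim_left(blocks)
        if blocks and sj_candidates:
            blocks = trim_right(blocks)
    return blocks


def trim_anchors(
    pair: AlignedPair,
    sj_candidates=(),
    policy: AnchorPolicy | None = None,
    tally: dict | None = None,
) -> AlignedPair | None:
    """Anchor-trim one pair against a candidate junction set.

    Returns a new AlignedPair, or None when trimming would empty both mates
    (tallied under 'mate_emptied'/'pair_emptied' when a tally is supplied).
    """
    policy = policy or AnchorPolicy()
    cands = sorted(set(map(tuple, sj_candidates)))
    new_mates = []
    for blocks in pair.mates:
        trimmed = _trim_mate(blocks, cands, policy)
        if not trimmed and tally is not None:
            tally["mate_emptied"] = tally.get("mate_emptied", 0) + 1
        new_mates.append(trimmed)
    new_mates = [m for m in new_mates if m]
    if not new_mates:
        if tally is not None:
            tally["pair_emptied"] = tally.get("pair_emptied", 0) + 1
        return None
    if len(new_mates) == 1:  # dropped mate: keep the survivor as both "mates"
        new_mates = [new_mates[0], []]
    return AlignedPair(
        pair_id=pair.pair_id,
        chrom=pair.chrom,
        mates=(new_mates[0], new_mates[1]),
        strand=pair.strand,
        mate_reversed=pair.mate_reversed,
        sample=pair.sample,
    )
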