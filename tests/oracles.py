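"""Independent brute-force oracles used by unit and acceptance tests.

Every oracle follows a different code path from the implementation it
checks: regex scans instead of table-driven matching, coordinate reflection
instead of donor/acceptor bookkeeping, codon walks instead of frame-indexed
scans.
"""

from __future__ import annotations

import re

_PRIMARY = "CT[AG]A[CT]"
_SECONDARY = "TT[AG]A[CT]"
_ALTERNATE = ("[ACGT]T[AG]A[CT]", "[CT]T[ACGT]A[CT]", "[CT]T[AG]A[ACGT]")

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def branch_oracle(seq: str):
    """(tier, 1-based A position) of the 3'-most branch motif, or None."""
    region = seq.upper()[: max(len(seq) - 2, 0)]
    for tier, patterns in (
        ("primary", (_PRIMARY,)),
        ("secondary", (_SECONDARY,)),
        ("alternate", _ALTERNATE),
    ):
        best = None
        for pat in patterns:
            for m in re.finditer(f"(?=({pat}))", region):
                if best is None or m.start() > best:
                    best = m.start()
        if best is not None:
            return tier, best + 4
    return None


def ppt_oracle(seq: str):
    """(1-based start, window) of the 3'-most maximal-T qualifying window."""
    seq = seq.upper()
    hits = []
    for i in range(len(seq) - 5):
        w = seq[i : i + 6]
        if "A" not in w and "N" not in w and w.count("T") >= 3:
            hits.append((w.count("T"), i, w))
    if not hits:
        return None
    tmax = max(t for t, _i, _w in hits)
    t, i, w = max(h for h in hits if h[0] == tmax)
    return i + 1, w


def _reflect(spans):
    """Mirror genomic spans so minus-strand junctions can be classified with
    the plus-strand coordinate rules."""
    return [(-e, -s) for s, e in spans]


def pair_oracle(span_a, span_b, strand):
    """Plus-strand coordinate rules after reflecting minus-strand spans."""
    (s1, e1), (s2, e2) = (
        (span_a, span_b) if strand == "+" else _reflect([span_a, span_b])
    )
    if (s1, e1) == (s2, e2):
        raise ValueError("identical junctions")
    if e1 == e2:
        return "A5SS"
    if s1 == s2:
        return "A3SS"
    if e1 < s2 or e2 < s1:
        return "disjoint"
    if (s1 < s2 and e2 < e1) or (s2 < s1 and e1 < e2):
        return "A5SS_AND_A3SS"
    return "A5SS_OR_A3SS"


def multi_oracle(spans, strand):
    """Event label for a cluster of >= 3 junction spans on one strand."""
    pts = spans if strand == "+" else _reflect(spans)
    if len({e for _s, e in pts}) == 1:
        return "MA5SS"
    if len({s for s, _e in pts}) == 1:
        return "MA3SS"
    if len(pts) == 3:
        for k in range(3):
            spanning = pts[k]
            inner = sorted(p for i, p in enumerate(pts) if i != k)
            (a1, a2), (b1, b2) = inner
            if a2 < b1 and spanning == (a1, b2):
                return "EXON_SKIPPING"
    from collections import Counter

    tallies = Counter(
        pair_oracle(spans[i], spans[j], strand)
        for i in range(len(spans))
        for j in range(i + 1, len(spans))
    )
    return (
        f"n={len(spans)};A5SS={tallies['A5SS']};A3SS={tallies['A3SS']};"
        f"AND={tallies['A5SS_AND_A3SS']};OR={tallies['A5SS_OR_A3SS']}"
    )


_STOPS = {"TAA", "TAG", "TGA"}


def orf_oracle(seq: str, strands=("+", "-")):
    """(aa length, complete) of the longest ORF over the given strands.

    Walks codons from every ATG to the first in-frame stop (complete) or the
    end of the readable frame (partial).
    """
    best = (0, False)
    for strand in strands:
        s = seq.upper() if strand == "+" else rc(seq.upper())
        for i in range(len(s) - 2):
            if s[i : i + 3] != "ATG":
                continue
            j = i
            complete = False
            while j + 3 <= len(s):
                codon = s[j : j + 3]
                if codon in _STOPS and j > i:
                    complete = True
                    break
                j += 3
            aa = (j - i) // 3
            if (aa, complete) != (0, False) and aa > best[0]:
                best = (aa, complete)
    return best
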