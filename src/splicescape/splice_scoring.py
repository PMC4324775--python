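"""Position-frequency and log-odds matrices for splice-site windows.

Three window types are scored, each anchored in transcription orientation:

* donor (5'ss): 13 bases = 3 exonic + 10 intronic, anchored at the
  exon|intron boundary;
* acceptor (3'ss): 17 bases = 14 intronic + 3 exonic, anchored at the
  intron|exon boundary;
* branch: 11 bases = 6 upstream + branch-point A + 4 downstream.

Frequencies are plain per-column counts/total — no pseudocount.  A base with
zero frequency maps to a -inf log-odds sentinel; any window that hits a
sentinel scores -inf and is flagged rather than silently rescaled.  Raw
(unscaled) bit scores are used throughout: a window's score is the sum over
positions of log2(freq/0.25) for the observed base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import revcomp

BASES = "ATGC"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: (exonic/upstream flank, intronic/core length) per site type
WINDOW_SHAPES = {"five": (3, 10), "three": (14, 3), "branch": (6, 5)}
WINDOW_LENGTHS = {"five": 13, "three": 17, "branch": 11}


@dataclass
class SiteWindows:
    """The three scoring windows of one junction, transcription-oriented.

    A window is ``None`` when unscorable (intron shorter than the intronic
    span of the window, or window running off the chromosome end).
    """

    five_ss: str | None
    three_ss: str | None
    branch: str | None


@dataclass
class FrequencyMatrix:
    """Per-position nucleotide frequencies; rows A,T,G,C; columns sum to 1."""

    site_type: str
    freqs: np.ndarray  # shape (4, L)

    @property
    def n_columns(self) -> int:
        return self.freqs.shape[1]


@dataclass
class LogOddsMatrix:
    """Base-2 log of frequency / 0.25 per position; -inf marks zero counts."""

    site_type: str
    entries: np.ndarray  # shape (4, L)

    @property
    def n_columns(self) -> int:
        return self.entries.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.entries, axis=0))


@dataclass
class SpliceScores:
    """Raw bit scores of one junction's three windows (None = unscorable)."""

    five_score: float | None = None
    three_score: float | None = None
    branch_score: float | None = None


def _slice(genome: dict[str, str], chrom: str, start: int, end: int) -> str | None:
    """1-based inclusive genomic slice; None when outside the chromosome."""
    seq = genome[chrom]
    if start < 1 or end > len(seq):
        return None
    return seq[start - 1 : end]


def extract_site_windows(sj, genome: dict[str, str]) -> SiteWindows:
    """Extract the donor/acceptor/branch windows of a junction.

    ``sj`` needs attributes chrom, strand, intron_start, intron_end and
    (for the branch window) a ``branch`` with a 1-based ``a_pos`` within the
    intron.  Donor and acceptor windows must not extend past the intron into
    the other side of it (introns shorter than a window's intronic span are
    unscorable for that window); the branch window may reach into flanking
    sequence.
    """
    chrom, strand = sj.chrom, sj.strand
    s, e = sj.intron_start, sj.intron_end
    ilen = e - s + 1

    def oriented(a: int, b: int) -> str | None:
        raw = _slice(genome, chrom, a, b)
        if raw is None:
            return None
        return raw if strand == "+" else revcomp(raw)

    five = three = None
    if ilen >= 10:
        if strand == "+":
            five = oriented(s - 3, s + 9)
        else:
            five = oriented(e - 9, e + 3)
    if ilen >= 14:
        if strand == "+":
            three = oriented(e - 13, e + 3)
        else:
            three = oriented(s - 3, s + 13)

    branch = None
    bp = getattr(sj, "branch", None)
    if bp is not None:
        # genomic position of the branch A from its 1-based intron offset
        if strand == "+":
            g = s + bp.a_pos - 1
            branch = oriented(g - 6, g + 4)
        else:
            g = e - bp.a_pos + 1
            branch = oriented(g - 4, g + 6)
    return SiteWindows(five_ss=five, three_ss=three, branch=branch)


def build_matrices(
    windows: list[str], site_type: str
) -> tuple[FrequencyMatrix, LogOddsMatrix]:
    """Count aligned windows into a frequency matrix and its log-odds form."""
    windows = [w for w in windows if w is not None]
    if not windows:
        raise ValueError(f"no scorable {site_type} windows")
    length = len(windows[0])
    counts = np.zeros((4, length), dtype=float)
    for w in windows:
        if len(w) != length:
            raise ValueError("window length mismatch")
        for j, base in enumerate(w):
            counts[_BASE_INDEX[base], j] += 1
    freqs = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore"):
        entries = np.log2(freqs / 0.25)
    return FrequencyMatrix(site_type, freqs), LogOddsMatrix(site_type, entries)


def score_window(seq: str, matrix: LogOddsMatrix) -> tuple[float, bool]:
    """Raw positional-sum score; second element flags a -inf sentinel hit."""
    if len(seq) != matrix.n_columns:
        raise ValueError(
            f"sequence length {len(seq)} != matrix columns {matrix.n_columns}"
        )
    total = 0.0
    for j, base in enumerate(seq):
        if base not in _BASE_INDEX:
            raise ValueError(f"non-ACGT base {base!r} at position {j}")
        total += matrix.entries[_BASE_INDEX[base], j]
    if math.isinf(total):
        return float("-inf"), True
    return total, False


def score_junctions(
    sjs, genome: dict[str, str]
) -> tuple[dict, dict[str, FrequencyMatrix], dict[str, LogOddsMatrix]]:
    """Build matrices from all junctions' windows, then score every junction.

    Returns ({junction key: SpliceScores}, frequency matrices, log-odds
    matrices keyed by site type).  Sentinel (-inf) scores are kept as -inf.
    """
    wins = {sj.key(): extract_site_windows(sj, genome) for sj in sjs}
    fmats: dict[str, FrequencyMatrix] = {}
    lmats: dict[str, LogOddsMatrix] = {}
    for site, attr in (("five", "five_ss"), ("three", "three_ss"), ("branch", "branch")):
        pool = [getattr(w, attr) for w in wins.values() if getattr(w, attr)]
        if pool:
            fmats[site], lmats[site] = build_matrices(pool, site)
    scores = {}
    for sj in sjs:
        w = wins[sj.key()]
        sc = SpliceScores()
        if w.five_ss and "five" in lmats:
            sc.five_score = score_window(w.five_ss, lmats["five"])[0]
        if w.three_ss and "three" in lmats:
            sc.three_score = score_window(w.three_ss, lmats["three"])[0]
        if w.branch and "branch" in lmats:
            sc.branch_score = score_window(w.branch, lmats["branch"])[0]
        scores[sj.key()] = sc
    return scores, fmats, lmats


def matrices_to_table(fmats, lmats):
    """Flatten matrices into rows (site_type, base, position, frequency, log_odds)."""
    import pandas as pd

    rows = []
    for site in sorted(fmats):
        f, lo = fmats[site], lmats[site]
        for i, base in enumerate(BASES):
            for j in range(f.n_columns):
                rows.append(
                    {
                        "site_type": site,
                        "base": base,
                        "position": j + 1,
                        "frequency": f.freqs[i, j],
                        "log_odds": lo.entries[i, j],
                    }
                )
    return pd.DataFrame(rows)
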