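"""Readers and writers for the plain-text formats used across the pipeline.

Internal coordinates are 1-based inclusive everywhere in this package;
conversion to the 0-based half-open convention of bedGraph/BED happens only
in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNRYacgtnry", "TGCANYRtgcanyr")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC R/Y aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


@dataclass
class GeneModel:
    """A gene with its exon structure, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    strand: str
    exons: list = field(default_factory=list)  # sorted [(start, end)]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> list:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]


def write_gff3(genes: list[GeneModel], path, source: str = "splicescape") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_gff3(path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = (
                line.rstrip("\n").split("\t")
            )
            fields = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = fields["ID"]
                genes[gid] = GeneModel(gid, chrom, strand, [])
            elif ftype == "exon":
                parent = fields["Parent"]
                if parent not in genes:  # exon-only GFF3
                    genes[parent] = GeneModel(parent, chrom, strand, [])
                genes[parent].exons.append((int(start), int(end)))
    for g in genes.values():
        g.exons.sort()
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))


def write_bedgraph(coverage: dict[str, np.ndarray], path) -> None:
    """Write per-base coverage as bedGraph (0-based half-open, zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(coverage):
            cov = np.asarray(coverage[chrom])
            if cov.size == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(cov)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [cov.size]))
            for s, e in zip(starts, ends):
                v = cov[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{int(v)}\n")


def read_bedgraph(path, lengths: dict[str, int] | None = None) -> dict[str, np.ndarray]:
    """Read bedGraph into per-chromosome int arrays.

    ``lengths`` sizes the arrays (needed to restore trailing zero runs); when
    omitted, each array ends at the last covered base.
    """
    raw: dict[str, list] = {}
    maxend: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split()[:4]
            s, e = int(s), int(e)
            raw.setdefault(chrom, []).append((s, e, int(float(v))))
            maxend[chrom] = max(maxend.get(chrom, 0), e)
    out: dict[str, np.ndarray] = {}
    sizes = dict(maxend)
    if lengths:
        for chrom, n in lengths.items():
            sizes[chrom] = max(n, maxend.get(chrom, 0))
    for chrom, n in sizes.items():
        arr = np.zeros(n, dtype=np.int64)
        for s, e, v in raw.get(chrom, []):
            arr[s:e] = v
        out[chrom] = arr
    return out
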