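"""Gene models and the GFF3 boundary.

All internal coordinates are 0-based, half-open genomic intervals; GFF3's
1-based closed convention is converted exactly once, at read/write time.
Transcript coordinates run 5'->3' along the spliced exon chain (reverse
order on the minus strand).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from intervaltree import IntervalTree

BIOTYPES = ("mRNA", "ncRNA", "lincRNA", "snoRNA")
PROGRAMS = ("spermatogenic", "oogenic", "both", "none")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneAnnotation:
    """A gene with biotype, strand, exon chain and optional 3'UTR."""

    gene_id: str
    biotype: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    utr3: tuple[int, int] | None = None
    program: str = "none"

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.program not in PROGRAMS:
            raise ValueError(f"unknown program {self.program!r}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if a >= b:
                raise ValueError(f"{self.gene_id}: empty exon {(a, b)}")
        for (_, b), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 < b:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if self.utr3 is not None:
            a, b = self.utr3
            covered = sum(
                max(0, min(b, eb) - max(a, ea)) for ea, eb in self.exons
            )
            if covered != b - a:
                raise ValueError(f"{self.gene_id}: utr3 not contained in exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def transcript_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    def _ordered_exons(self) -> list[tuple[int, int]]:
        # 5'->3' transcript order
        return self.exons if self.strand == "+" else self.exons[::-1]

    def transcript_to_genomic(self, offset: int) -> int:
        """Genomic position of transcript coordinate ``offset``."""
        if not 0 <= offset < self.transcript_length:
            raise IndexError(f"transcript offset {offset} out of range")
        for a, b in self._ordered_exons():
            n = b - a
            if offset < n:
                return a + offset if self.strand == "+" else b - 1 - offset
            offset -= n
        raise AssertionError("unreachable")

    def transcript_sequence(self, genome: dict[str, str]) -> str:
        chrom = genome[self.chromosome]
        parts = [chrom[a:b] for a, b in self.exons]
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)

    def utr3_transcript_interval(self) -> tuple[int, int] | None:
        """The 3'UTR as a half-open interval in transcript coordinates."""
        if self.utr3 is None:
            return None
        a, b = self.utr3
        offset = 0
        lo = hi = None
        for ea, eb in self._ordered_exons():
            o_a, o_b = max(a, ea), min(b, eb)
            if o_a < o_b:
                if self.strand == "+":
                    s = offset + (o_a - ea)
                else:
                    s = offset + (eb - o_b)
                e = s + (o_b - o_a)
                lo = s if lo is None else min(lo, s)
                hi = e if hi is None else max(hi, e)
            offset += eb - ea
        return (lo, hi) if lo is not None else None


class GeneIndex:
    """Strand-aware interval index over exons for read/peak assignment."""

    def __init__(self, genes: Iterable[GeneAnnotation]):
        self.genes: dict[str, GeneAnnotation] = {}
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
            tree = self._trees.setdefault((g.chromosome, g.strand), IntervalTree())
            for a, b in g.exons:
                tree[a:b] = g.gene_id

    def __len__(self) -> int:
        return len(self.genes)

    def overlapping_genes(
        self, chromosome: str, strand: str, start: int, end: int
    ) -> set[str]:
        """Gene ids with >=1 exon base overlapping [start, end) on strand."""
        tree = self._trees.get((chromosome, strand))
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}


def write_gff3(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    feature_of = {"mRNA": "mRNA", "ncRNA": "ncRNA",
                  "lincRNA": "lincRNA", "snoRNA": "snoRNA"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};biotype={g.biotype};program={g.program}"
            row = [g.chromosome, "fbfsubnet", "gene", str(g.start + 1),
                   str(g.end), ".", g.strand, ".", attrs]
            fh.write("\t".join(row) + "\n")
            tid = f"{g.gene_id}.t1"
            row[2] = feature_of[g.biotype]
            row[8] = f"ID={tid};Parent={g.gene_id};biotype={g.biotype}"
            fh.write("\t".join(row) + "\n")
            for i, (a, b) in enumerate(g.exons, 1):
                fh.write("\t".join([
                    g.chromosome, "fbfsubnet", "exon", str(a + 1), str(b),
                    ".", g.strand, ".", f"ID={tid}.e{i};Parent={tid}",
                ]) + "\n")
            if g.utr3 is not None:
                a, b = g.utr3
                fh.write("\t".join([
                    g.chromosome, "fbfsubnet", "three_prime_UTR",
                    str(a + 1), str(b), ".", g.strand, ".",
                    f"ID={tid}.utr3;Parent={tid}",
                ]) + "\n")


def read_gff3(path: str | Path) -> list[GeneAnnotation]:
    """Load gene models from GFF3 (as written by :func:`write_gff3`)."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneAnnotation] = []
    for gene in db.features_of_type("gene"):
        exons = []
        utr3 = None
        biotype = gene.attributes.get("biotype", ["mRNA"])[0]
        program = gene.attributes.get("program", ["none"])[0]
        for child in db.children(gene, level=None):
            if child.featuretype == "exon":
                exons.append((child.start - 1, child.end))
            elif child.featuretype == "three_prime_UTR":
                utr3 = (child.start - 1, child.end)
        genes.append(GeneAnnotation(
            gene_id=gene.id, biotype=biotype, chromosome=gene.seqid,
            strand=gene.strand, exons=exons, utr3=utr3, program=program,
        ))
    return genes


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
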