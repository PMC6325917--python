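"""Raw-read handling and error-tolerant duplicate collapsing.

iCLIP reads begin with a sample barcode followed by a random UMI; both are
stripped from the sequence, and the UMI is moved into the read name (after
the final underscore) so it survives alignment. After alignment, PCR
duplicates are collapsed per (chromosome, strand, start) position using the
directional UMI-clustering rule, which absorbs sequencing-error UMIs into
their abundant parents: an edge u -> v exists when Hamming(u, v) = 1,
count(u) >= 2 * count(v) - 1 and count(u) > count(v). The strict-majority
condition keeps equally-supported UMIs apart — without it two one-count
UMIs one mismatch apart would merge, collapsing distinct molecules and
making the operation non-idempotent.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RawReadLayout:
    """Positional layout of a raw iCLIP read."""

    sample_barcode_length: int = 4
    umi_length: int = 7
    three_prime_linker: str = "AGATCGGAAGAGC"
    rt_primer: str = ""

    def __post_init__(self) -> None:
        if self.sample_barcode_length < 0 or self.umi_length < 0:
            raise ValueError("lengths must be >= 0")
        for s in (self.three_prime_linker, self.rt_primer):
            if set(s) - set("ACGTN"):
                raise ValueError(f"linker/primer must be ACGTN, got {s!r}")


@dataclass(frozen=True)
class ProcessedRead:
    """An aligned read; 0-based half-open genomic interval, UMI in the name."""

    name: str
    chromosome: str
    strand: str
    start: int
    end: int
    umi: str
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name}: empty interval")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("UMI length mismatch")
    return sum(x != y for x, y in zip(a, b))


def _check_barcode_table(barcode_table: dict[str, str]) -> None:
    codes = list(barcode_table)
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate barcodes in table")
    if len({len(c) for c in codes}) > 1:
        raise ValueError("barcodes must share one length")
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            if hamming(a, b) < 2:
                raise ValueError(
                    f"barcodes {a} and {b} are closer than Hamming distance 2"
                )


def _trim_three_prime(seq: str, layout: RawReadLayout) -> str:
    for adapter in (layout.three_prime_linker, layout.rt_primer):
        if adapter:
            idx = seq.find(adapter)
            if idx >= 0:
                seq = seq[:idx]
    return seq


def demultiplex_and_extract(
    records: Iterable[tuple[str, str]],
    layout: RawReadLayout,
    barcode_table: dict[str, str],
) -> dict[str, list[tuple[str, str]]]:
    """Split raw reads by 5' barcode; move the UMI into the read name.

    ``records`` are (name, sequence) pairs (e.g. from Bio.SeqIO fastq
    records). Output sequences carry neither barcode, UMI, linker nor
    primer; reads with no exact barcode match land in the "undetermined"
    stream, so assigned + undetermined = input.
    """
    _check_barcode_table(barcode_table)
    bl = layout.sample_barcode_length
    ul = layout.umi_length
    out: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for sample in barcode_table.values():
        out[sample] = []
    out["undetermined"] = []
    for name, seq in records:
        barcode = seq[:bl]
        sample = barcode_table.get(barcode)
        if sample is None:
            out["undetermined"].append((name, seq))
            continue
        umi = seq[bl:bl + ul]
        insert = _trim_three_prime(seq[bl + ul:], layout)
        out[sample].append((f"{name}_{umi}", insert))
    return dict(out)


def parse_fastq(handle: TextIO | str) -> Iterator[tuple[str, str]]:
    """(name, sequence) pairs from a FASTQ stream, via Bio.SeqIO."""
    from Bio import SeqIO

    for rec in SeqIO.parse(handle, "fastq"):
        yield rec.description.split()[0], str(rec.seq).upper()


def umi_from_name(name: str) -> str:
    """The UMI dialect: everything after the final underscore."""
    return name.rsplit("_", 1)[-1]


def directional_clusters(counts: dict[str, int]) -> list[list[str]]:
    """Directional UMI clustering of a per-position UMI count table.

    Edges run from abundant to rare: u -> v iff Hamming(u, v) = 1,
    count(u) >= 2 * count(v) - 1 and count(u) > count(v). Each UMI joins
    the cluster of the first (most abundant, ties lexicographic) node that
    can reach it. Returns the clusters, each sorted by (-count, umi).
    """
    order = sorted(counts, key=lambda u: (-counts[u], u))
    assigned: dict[str, int] = {}
    clusters: list[list[str]] = []
    for u in order:
        if u in assigned:
            continue
        cid = len(clusters)
        clusters.append([u])
        assigned[u] = cid
        # BFS along directional edges into still-unassigned UMIs
        frontier = [u]
        while frontier:
            nxt = []
            for a in frontier:
                for b in order:
                    if b in assigned:
                        continue
                    if (hamming(a, b) == 1 and counts[a] > counts[b]
                            and counts[a] >= 2 * counts[b] - 1):
                        assigned[b] = cid
                        clusters[cid].append(b)
                        nxt.append(b)
            frontier = nxt
    for c in clusters:
        c.sort(key=lambda u: (-counts[u], u))
    return clusters


def collapse_duplicates(reads: Iterable[ProcessedRead]) -> list[ProcessedRead]:
    """One representative read per molecule.

    Reads are grouped by (chromosome, strand, start); within a group UMIs
    are clustered directionally and the representative of each cluster is
    the read carrying its highest-count (ties: lexicographically smallest)
    UMI. Reads missing a UMI are dropped with a logged warning count.
    Idempotent: collapsing a collapsed set changes nothing.
    """
    groups: dict[tuple[str, str, int], list[ProcessedRead]] = defaultdict(list)
    dropped = 0
    for r in reads:
        if not r.umi:
            dropped += 1
            continue
        groups[(r.chromosome, r.strand, r.start)].append(r)
    if dropped:
        logger.warning("dropped %d reads missing a UMI", dropped)
    out: list[ProcessedRead] = []
    for key in sorted(groups):
        group = groups[key]
        counts = Counter(r.umi for r in group)
        first_with_umi = {}
        for r in group:
            first_with_umi.setdefault(r.umi, r)
        for cluster in directional_clusters(dict(counts)):
            out.append(first_with_umi[cluster[0]])
    out.sort(key=lambda r: (r.chromosome, r.strand, r.start, r.umi))
    return out


def read_sam(path: str) -> list[ProcessedRead]:
    """Aligned reads from SAM/BAM; unmapped/secondary records are skipped."""
    import pysam

    reads = []
    with pysam.AlignmentFile(path, "r") as fh:
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            reads.append(ProcessedRead(
                name=a.query_name,
                chromosome=a.reference_name,
                strand="-" if a.is_reverse else "+",
                start=a.reference_start,
                end=a.reference_end,
                umi=umi_from_name(a.query_name),
            ))
    return reads
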