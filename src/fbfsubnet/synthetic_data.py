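"""Ground-truth-annotated synthetic iCLIP fixture sets.

The generator emulates the data regime the downstream analysis assumes:

* per-gene read counts proportional to RNA abundance times FBF binding
  frequency (binding frequency 1 for the no-antibody control);
* read pile-ups centred on a planted FBE-containing 3'UTR position;
* PCR duplicates sharing a molecule's UMI, re-emitted with rare per-base
  sequencing errors;
* a planted four-block binding structure (sperm-specific / gender-neutral
  x2 / oocyte-specific) across replicates of two germline genders.

Every dataset carries a truth table so downstream stages can be scored for
recovery rather than eyeballed. Seeded runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation, reverse_complement, write_fasta, write_gff3
from .preprocess import ProcessedRead

GENDERS = ("sperm", "oocyte")
ANTIBODIES = ("FBF", "control")
BLOCK_LABELS = ("I", "II", "III", "IV")

_CHROMS = ("chrI", "chrII", "chrIII", "chrIV", "chrV", "chrX")
_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Study-condition knobs for the synthetic iCLIP dataset.

    Defaults mirror the data regime of the real study at desk scale: a few
    hundred genes standing in for the >10,000-gene transcriptome, three
    replicates per gender, long-tailed abundances, and block proportions in
    the same ratio as the four observed blocks (sperm-specific block I,
    gender-neutral II and III, oocyte-specific IV) relative to all genes.
    """

    n_genes: int = 300
    frac_ncRNA: float = 0.05
    n_replicates_per_condition: int = 3
    library_size: int = 100_000
    block_proportions: tuple[float, float, float, float] = (0.05, 0.25, 0.015, 0.02)
    binding_rpm_range: tuple[float, float] = (2000.0, 20000.0)
    sperm_oocyte_fold: float = 4.0
    abundance_shape: float = 1.0
    duplicate_rate: float = 0.5
    umi_length: int = 7
    umi_error_rate: float = 0.01
    seed: int = 0
    # fraction of planted FBEs given an affinity-enhancing -1/-2 cytosine
    minus_c_fraction: float = 0.5
    # fraction of planted peaks that carry an FBE at all
    fbe_fraction: float = 1.0
    read_length: int = 35
    # no-antibody controls recover far less material than the FBF IP;
    # their expected library is this fraction of ``library_size``
    control_library_fraction: float = 0.1

    def validate(self) -> None:
        fracs = {
            "frac_ncRNA": self.frac_ncRNA,
            "duplicate_rate": self.duplicate_rate,
            "umi_error_rate": self.umi_error_rate,
            "minus_c_fraction": self.minus_c_fraction,
            "fbe_fraction": self.fbe_fraction,
            "control_library_fraction": self.control_library_fraction,
        }
        if self.control_library_fraction <= 0:
            raise ValueError("control_library_fraction must be > 0")
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if len(self.block_proportions) != 4:
            raise ValueError("block_proportions must have four entries")
        if any(p < 0 for p in self.block_proportions):
            raise ValueError("block_proportions must be non-negative")
        if sum(self.block_proportions) > 1.0 + 1e-12:
            raise ValueError("block_proportions must sum to <= 1")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.umi_length < 3:
            raise ValueError("umi_length must be >= 3")
        if self.n_genes > 0 and self.library_size < 10 * self.n_genes:
            raise ValueError("library_size must be >= 10 * n_genes")
        lo, hi = self.binding_rpm_range
        if not (0 < lo <= hi):
            raise ValueError("binding_rpm_range must be positive with lo <= hi")
        if self.sperm_oocyte_fold < 1:
            raise ValueError("sperm_oocyte_fold must be >= 1")
        if self.abundance_shape <= 0:
            raise ValueError("abundance_shape must be positive")
        if self.read_length < 10:
            raise ValueError("read_length must be >= 10")


@dataclass
class SyntheticTruth:
    """Per-gene ground truth for a generated dataset.

    ``expected_rpm[gender][gene]`` is the exactly realized expected
    reads-per-million for FBF samples of that germline gender (the values the
    Poisson draws are centred on, after normalizing total mass to 10^6);
    ``control_rpm`` is the abundance-only expectation shared by both genders'
    no-antibody controls.
    """

    gene_ids: list[str]
    block: dict[str, str]
    abundance: dict[str, float]
    expected_rpm: dict[str, dict[str, float]]
    control_rpm: dict[str, float]
    peak_transcript_offset: dict[str, int | None]
    peak_genomic_position: dict[str, int | None]
    has_fbe: dict[str, bool]

    def targets(self) -> list[str]:
        return [g for g in self.gene_ids if self.block[g] != "none"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.gene_ids:
            rows.append({
                "gene_id": g,
                "block": self.block[g],
                "abundance": self.abundance[g],
                "rpm_sperm": self.expected_rpm["sperm"][g],
                "rpm_oocyte": self.expected_rpm["oocyte"][g],
                "rpm_control": self.control_rpm[g],
                "peak_transcript_offset": self.peak_transcript_offset[g],
                "peak_genomic_position": self.peak_genomic_position[g],
                "has_fbe": self.has_fbe[g],
            })
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SimulatedSample:
    """One simulated aligned library plus its generator bookkeeping."""

    name: str
    gender: str
    antibody: str
    replicate: int
    reads: list[ProcessedRead]
    molecules_per_gene: dict[str, int]
    reads_per_gene: dict[str, int]

    @property
    def n_molecules(self) -> int:
        return sum(self.molecules_per_gene.values())

    @property
    def n_reads(self) -> int:
        return len(self.reads)


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


# positions whose mutation breaks the canonical octamer TGTNNNAT
_BREAK_OFFSETS = (1, 2, 6, 0, 7)
_REQUIRED = {0: "T", 1: "G", 2: "T", 6: "A", 7: "T"}


def _scrub_fbes(chrom: np.ndarray, protected: set[int],
                rng: np.random.Generator) -> None:
    """Mutate away every canonical FBE (both strands) not protected.

    ``protected`` holds genomic indices belonging to planted octamers; those
    bases are never touched. Iterates until no unprotected match remains.
    """
    import re

    plus = re.compile("TGT...AT")
    minus = re.compile("AT...ACA")  # revcomp of the canonical octamer
    for _ in range(50):
        seq = "".join(chrom)
        dirty = False
        for pat, is_minus in ((plus, False), (minus, True)):
            pos = 0
            while True:
                m = pat.search(seq, pos)
                if m is None:
                    break
                i = m.start()
                pos = i + 1
                span = range(i, i + 8)
                if all(j in protected for j in span):
                    continue
                for off in _BREAK_OFFSETS:
                    j = i + (7 - off if is_minus else off)
                    if j not in protected:
                        old = chrom[j]
                        choices = [b for b in "ACGT" if b != old]
                        chrom[j] = choices[rng.integers(0, 3)]
                        dirty = True
                        break
        if not dirty:
            return
        # re-scan: a mutation can in principle create a new match
    raise RuntimeError("could not scrub background FBEs")


def generate_transcriptome(
    config: SyntheticConfig,
) -> tuple[list[GeneAnnotation], dict[str, str], SyntheticTruth]:
    """Build gene models, genome sequence and per-gene ground truth.

    Target genes (blocks I-IV) carry one planted canonical FBE octamer at the
    recorded peak position inside their 3'UTR; a ``minus_c_fraction`` of those
    additionally get a cytosine one or two bases upstream. Background
    sequence is scrubbed of canonical FBEs on both strands, so a motif scan
    finds planted sites and nothing else.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    if config.n_genes == 0:
        truth = SyntheticTruth([], {}, {}, {g: {} for g in GENDERS}, {}, {}, {}, {})
        return [], {}, truth

    n = config.n_genes
    n_nc = int(round(config.frac_ncRNA * n))
    block_counts = [int(round(p * (n - n_nc))) for p in config.block_proportions]
    if sum(block_counts) > n - n_nc:
        raise ValueError("block proportions leave no room for mRNA genes")

    # biotypes: ncRNAs last so target blocks land on mRNAs
    biotypes = ["mRNA"] * (n - n_nc)
    nc_kinds = ["ncRNA", "lincRNA", "snoRNA"]
    biotypes += [nc_kinds[i % 3] for i in range(n_nc)]

    blocks: list[str] = []
    for label, c in zip(BLOCK_LABELS, block_counts):
        blocks += [label] * c
    blocks += ["none"] * (n - len(blocks))

    genes: list[GeneAnnotation] = []
    chrom_cursor: dict[str, int] = {c: 0 for c in _CHROMS}
    gene_meta: list[dict] = []
    min_exon = max(2 * config.read_length + 60, 200)

    for i in range(n):
        gene_id = f"gene{i:05d}"
        biotype = biotypes[i]
        block = blocks[i]
        chrom = _CHROMS[i % len(_CHROMS)]
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        n_exons = int(rng.integers(1, 3)) if biotype == "mRNA" else 1
        exon_lens = [int(rng.integers(min_exon, 900)) for _ in range(n_exons)]
        utr_len = int(rng.integers(160, 400)) if biotype == "mRNA" else 0
        exon_lens[-1 if strand == "+" else 0] = max(
            exon_lens[-1 if strand == "+" else 0], utr_len + min_exon
        )
        start = chrom_cursor[chrom] + int(rng.integers(100, 300))
        exons = []
        pos = start
        for L in exon_lens:
            exons.append((pos, pos + L))
            pos += L + int(rng.integers(60, 200))
        chrom_cursor[chrom] = exons[-1][1]
        utr3 = None
        if biotype == "mRNA":
            # 3'UTR = trailing ``utr_len`` bases of the transcript
            if strand == "+":
                a, b = exons[-1]
                utr3 = (b - utr_len, b)
            else:
                a, b = exons[0]
                utr3 = (a, a + utr_len)
        genes.append(GeneAnnotation(
            gene_id=gene_id, biotype=biotype, chromosome=chrom,
            strand=strand, exons=exons, utr3=utr3,
        ))
        gene_meta.append({"block": block})

    # genome sequence
    genome_arrays = {
        c: _random_seq(rng, chrom_cursor[c] + 200) for c in _CHROMS
        if chrom_cursor[c] > 0
    }

    # plant FBEs and record peak positions
    peak_offsets: dict[str, int | None] = {}
    peak_positions: dict[str, int | None] = {}
    has_fbe: dict[str, bool] = {}
    protected: dict[str, set[int]] = {c: set() for c in genome_arrays}
    margin = config.read_length // 2 + 30

    for g, meta in zip(genes, gene_meta):
        block = meta["block"]
        if block == "none":
            peak_offsets[g.gene_id] = None
            peak_positions[g.gene_id] = None
            has_fbe[g.gene_id] = False
            continue
        tiv = g.utr3_transcript_interval()
        if tiv is None:
            raise ValueError(f"{g.gene_id}: target gene lacks a 3'UTR")
        lo = max(tiv[0] + 2, margin)
        hi = min(tiv[1] - 8, g.transcript_length - margin)
        if hi <= lo:
            raise ValueError(
                f"{g.gene_id}: 3'UTR too short to fit a planted FBE"
            )
        offset = int(rng.integers(lo, hi))
        peak_offsets[g.gene_id] = offset
        peak_positions[g.gene_id] = g.transcript_to_genomic(offset)
        planted = bool(rng.random() < config.fbe_fraction)
        has_fbe[g.gene_id] = planted
        if not planted:
            continue
        middle = "".join(_BASES[rng.integers(0, 4, size=3)])
        octamer = "TGT" + middle + "AT"
        chrom_arr = genome_arrays[g.chromosome]
        # write octamer (transcript sense) into the genome
        for k, base in enumerate(octamer):
            gpos = g.transcript_to_genomic(offset + k)
            chrom_arr[gpos] = base if g.strand == "+" else reverse_complement(base)
            protected[g.chromosome].add(gpos)
        # upstream -1/-2 cytosine, or guarantee neither
        with_c = bool(rng.random() < config.minus_c_fraction)
        which = int(rng.integers(1, 3))  # 1 or 2 bases upstream
        for d in (1, 2):
            gpos = g.transcript_to_genomic(offset - d)
            base = "C" if (with_c and d == which) else "ACGT"[rng.integers(0, 3)]
            if base == "C" and not (with_c and d == which):  # never accidental C
                base = "A"
            chrom_arr[gpos] = base if g.strand == "+" else reverse_complement(base)
            protected[g.chromosome].add(gpos)

    # splice junctions can assemble an FBE invisible at the genome level;
    # alternate genome-level and transcript-level scrubs until both are clean
    import re as _re

    canon = _re.compile("TGT...AT")
    for _ in range(10):
        for c, arr in genome_arrays.items():
            _scrub_fbes(arr, protected[c], rng)
        dirty = False
        for g in genes:
            arr = genome_arrays[g.chromosome]
            tseq = "".join(
                "".join(arr[a:b]) for a, b in g.exons
            )
            if g.strand == "-":
                tseq = reverse_complement(tseq)
            for m in canon.finditer(tseq):
                gpos = [g.transcript_to_genomic(m.start() + k) for k in range(8)]
                if all(p in protected[g.chromosome] for p in gpos):
                    continue
                for off in _BREAK_OFFSETS:
                    p = gpos[off]
                    if p not in protected[g.chromosome]:
                        want = _REQUIRED.get(off, "A")
                        choices = [b for b in "ACGT" if b != want]
                        base = choices[rng.integers(0, 3)]
                        arr[p] = (base if g.strand == "+"
                                  else reverse_complement(base))
                        dirty = True
                        break
        if not dirty:
            break
    genome = {c: "".join(arr) for c, arr in genome_arrays.items()}

    # abundances and expected RPM per condition
    abundance = np.exp(rng.normal(0.0, config.abundance_shape, size=n))
    lo, hi = config.binding_rpm_range
    log_lo, log_hi = math.log(lo), math.log(hi)
    base_rpm = np.zeros(n)
    for i, meta in enumerate(gene_meta):
        if meta["block"] == "none":
            continue
        if meta["block"] == "III":
            # block III RNAs are abundant, high-frequency targets
            u = rng.uniform(0.7, 1.0)
        else:
            u = rng.uniform(0.0, 1.0)
        base_rpm[i] = math.exp(log_lo + u * (log_hi - log_lo))

    fold = config.sperm_oocyte_fold
    rpm = {"sperm": np.zeros(n), "oocyte": np.zeros(n)}
    for i, meta in enumerate(gene_meta):
        b = meta["block"]
        if b == "I":
            rpm["sperm"][i], rpm["oocyte"][i] = base_rpm[i], base_rpm[i] / fold
        elif b == "IV":
            rpm["sperm"][i], rpm["oocyte"][i] = base_rpm[i] / fold, base_rpm[i]
        elif b in ("II", "III"):
            rpm["sperm"][i] = rpm["oocyte"][i] = base_rpm[i]

    gene_ids = [g.gene_id for g in genes]
    expected_rpm: dict[str, dict[str, float]] = {}
    for gender in GENDERS:
        target_mass = rpm[gender].sum()
        if target_mass >= 1e6:
            raise ValueError("planted binding mass exceeds the library")
        nontarget = np.array([m["block"] == "none" for m in gene_meta])
        weights = rpm[gender].copy()
        ab_nt = abundance * nontarget
        if ab_nt.sum() > 0:
            # background fills the remaining library mass by abundance
            weights += (1e6 - target_mass) * ab_nt / ab_nt.sum()
        expected_rpm[gender] = dict(zip(gene_ids, weights))
    control = 1e6 * abundance / abundance.sum()
    truth = SyntheticTruth(
        gene_ids=gene_ids,
        block={g: m["block"] for g, m in zip(gene_ids, gene_meta)},
        abundance=dict(zip(gene_ids, abundance)),
        expected_rpm=expected_rpm,
        control_rpm=dict(zip(gene_ids, control)),
        peak_transcript_offset=peak_offsets,
        peak_genomic_position=peak_positions,
        has_fbe=has_fbe,
    )

    # program labels: blocks imply their gamete program; background mixed
    prog_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    for g, meta in zip(genes, gene_meta):
        b = meta["block"]
        if b == "I":
            g.program = "spermatogenic"
        elif b == "IV":
            g.program = "oogenic"
        elif b in ("II", "III"):
            g.program = "both"
        else:
            g.program = ["both", "spermatogenic", "oogenic", "none"][
                prog_rng.choice(4, p=[0.4, 0.2, 0.2, 0.2])
            ]
    return genes, genome, truth


def _mutate_umi(umi: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return umi
    chars = list(umi)
    for i, c in enumerate(chars):
        if rng.random() < error_rate:
            alt = [b for b in "ACGT" if b != c]
            chars[i] = alt[rng.integers(0, 3)]
    return "".join(chars)


def simulate_iclip_reads(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    annotation: Sequence[GeneAnnotation],
    gender: str,
    antibody: str,
    replicate: int,
) -> SimulatedSample:
    """Simulate one aligned iCLIP library.

    Unique-molecule counts per gene are Poisson with mean proportional to
    abundance x binding frequency (binding frequency 1 for the control). FBF
    reads on target genes pile around the planted peak (discretized Gaussian,
    sd 10 nt); control and non-target reads fall uniformly over exons. Each
    molecule gets a random UMI; PCR duplicates re-emit it with per-base error
    ``umi_error_rate``.
    """
    config.validate()
    if gender not in GENDERS:
        raise ValueError(f"unknown gender {gender!r}")
    if antibody not in ANTIBODIES:
        raise ValueError(f"unknown antibody {antibody!r}")
    cond_idx = GENDERS.index(gender) * len(ANTIBODIES) + ANTIBODIES.index(antibody)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 100 + cond_idx, replicate])
    )
    genes = {g.gene_id: g for g in annotation}
    name = f"{antibody}_{gender}_rep{replicate}"
    rl = config.read_length
    reads: list[ProcessedRead] = []
    molecules_per_gene: dict[str, int] = {}
    reads_per_gene: dict[str, int] = {}

    for gid in truth.gene_ids:
        gene = genes[gid]
        if antibody == "FBF":
            mu = config.library_size * truth.expected_rpm[gender][gid] / 1e6
        else:
            mu = (config.library_size * config.control_library_fraction
                  * truth.control_rpm[gid] / 1e6)
        n_mol = int(rng.poisson(mu))
        molecules_per_gene[gid] = n_mol
        if n_mol == 0:
            reads_per_gene[gid] = 0
            continue
        peaked = antibody == "FBF" and truth.block[gid] != "none"
        L = gene.transcript_length
        if peaked:
            center = truth.peak_transcript_offset[gid]
            starts = np.rint(
                center - rl / 2 + rng.normal(0.0, 10.0, size=n_mol)
            ).astype(int)
            starts = np.clip(starts, 0, L - rl)
        else:
            # uniform over exons; reads stay within one exon
            exon_lens = np.array([b - a for a, b in gene.exons], dtype=float)
            w = np.maximum(exon_lens - rl + 1, 1.0)
            exon_idx = rng.choice(len(w), size=n_mol, p=w / w.sum())
            offsets = np.cumsum([0] + [b - a for a, b in gene._ordered_exons()])
            starts = np.empty(n_mol, dtype=int)
            ordered = gene._ordered_exons()
            for j, ei in enumerate(exon_idx):
                a, b = gene.exons[ei]
                oi = ordered.index((a, b))
                span = max(b - a - rl, 0)
                starts[j] = offsets[oi] + int(rng.integers(0, span + 1))
        n_read = 0
        for m_i, s in enumerate(starts):
            s = int(s)
            g5 = gene.transcript_to_genomic(s)
            if gene.strand == "+":
                g_start, g_end = g5, g5 + rl
            else:
                g_start, g_end = g5 - rl + 1, g5 + 1
            umi = "".join(_BASES[rng.integers(0, 4, size=config.umi_length)])
            d = config.duplicate_rate
            copies = 1 + (int(rng.poisson(d / (1 - d))) if d > 0 else 0)
            for c_i in range(copies):
                obs = umi if c_i == 0 else _mutate_umi(umi, config.umi_error_rate, rng)
                reads.append(ProcessedRead(
                    name=f"{name}.{gid}.m{m_i}.d{c_i}_{obs}",
                    chromosome=gene.chromosome,
                    strand=gene.strand,
                    start=g_start,
                    end=g_end,
                    umi=obs,
                ))
                n_read += 1
        reads_per_gene[gid] = n_read
    return SimulatedSample(
        name=name, gender=gender, antibody=antibody, replicate=replicate,
        reads=reads, molecules_per_gene=molecules_per_gene,
        reads_per_gene=reads_per_gene,
    )


def simulate_study(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    annotation: Sequence[GeneAnnotation],
    n_control_replicates: int | None = None,
) -> dict[str, SimulatedSample]:
    """All FBF and control libraries for both germline genders."""
    n_control = n_control_replicates or config.n_replicates_per_condition
    samples: dict[str, SimulatedSample] = {}
    for gender in GENDERS:
        for antibody, n_rep in (("FBF", config.n_replicates_per_condition),
                                ("control", n_control)):
            for rep in range(1, n_rep + 1):
                s = simulate_iclip_reads(config, truth, annotation, gender,
                                         antibody, rep)
                samples[s.name] = s
    return samples


def write_sam(
    reads: Iterable[ProcessedRead],
    chrom_lengths: dict[str, int],
    path: str | Path,
    read_sequences: dict[str, str] | None = None,
) -> None:
    """Write aligned reads as plain-text SAM (UMI in the read name)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(L)} for c, L in chrom_lengths.items()],
    }
    ref_id = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.flag = 0 if r.strand == "+" else 16
            a.reference_id = ref_id[r.chromosome]
            a.reference_start = r.start
            a.mapping_quality = 255
            length = r.end - r.start
            a.cigarstring = f"{length}M"
            if read_sequences is not None and r.name in read_sequences:
                a.query_sequence = read_sequences[r.name]
                a.query_qualities = pysam.qualitystring_to_array("I" * length)
            out.write(a)


def read_sequence_for(read: ProcessedRead, genome: dict[str, str]) -> str:
    seq = genome[read.chromosome][read.start:read.end]
    return seq if read.strand == "+" else reverse_complement(seq)


def to_raw_fastq_records(
    reads: Iterable[ProcessedRead],
    genome: dict[str, str],
    barcode: str,
    three_prime_linker: str = "AGATCGGAAGAGC",
) -> list[tuple[str, str]]:
    """Raw-read mode: 5' sample barcode + UMI prepended, linker appended.

    Returns (name, sequence) pairs; the name keeps the generator's molecule
    bookkeeping so demultiplexing round-trips can be scored.
    """
    out = []
    for r in reads:
        insert = read_sequence_for(r, genome)
        out.append((r.name, barcode + r.umi + insert + three_prime_linker))
    return out


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_dataset(
    outdir: str | Path,
    config: SyntheticConfig,
    genes: Sequence[GeneAnnotation],
    genome: dict[str, str],
    truth: SyntheticTruth,
    samples: dict[str, SimulatedSample],
) -> dict[str, Path]:
    """Serialize a complete fixture set (FASTA/GFF3/SAM/TSV) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    write_fasta(genome, paths["genome"])
    paths["annotation"] = outdir / "annotation.gff3"
    write_gff3(genes, paths["annotation"])
    paths["truth"] = outdir / "truth.tsv"
    truth.write_tsv(paths["truth"])
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    for name, sample in samples.items():
        p = outdir / f"{name}.sam"
        write_sam(sample.reads, chrom_lengths, p)
        paths[name] = p
    return paths


def make_binding_matrix_fixture(
    n_rnas: int = 2000,
    n_samples: int = 12,
    between_block_shift: float = 4.0,
    noise_sd: float = 0.5,
    block_fractions: tuple[float, float, float, float] = (0.05, 0.25, 0.015, 0.02),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """A planted four-block log2 binding matrix plus true labels.

    Columns alternate genders (first half sperm, second half oocyte) to mimic
    control-subtracted log2 RPM profiles: block I high in sperm only, block
    II moderate everywhere, block III high everywhere, block IV high in
    oocyte only, background low everywhere.
    """
    rng = np.random.default_rng(seed)
    half = n_samples // 2
    s = between_block_shift
    profiles = {
        "I": np.r_[np.full(half, s), np.full(n_samples - half, 0.0)],
        "II": np.full(n_samples, s / 2),
        "III": np.full(n_samples, 2 * s),
        "IV": np.r_[np.full(half, 0.0), np.full(n_samples - half, s)],
        "none": np.full(n_samples, 0.0),
    }
    counts = [int(round(f * n_rnas)) for f in block_fractions]
    labels = []
    for lab, c in zip(BLOCK_LABELS, counts):
        labels += [lab] * c
    labels += ["none"] * (n_rnas - len(labels))
    rows = np.stack([profiles[lab] for lab in labels])
    rows = rows + rng.normal(0.0, noise_sd, size=rows.shape)
    cols = [f"FBF_sperm_rep{i+1}" for i in range(half)] + [
        f"FBF_oocyte_rep{i+1}" for i in range(n_samples - half)
    ]
    idx = [f"rna{i:05d}" for i in range(n_rnas)]
    return (pd.DataFrame(rows, index=idx, columns=cols),
            pd.Series(labels, index=idx, name="block"))


def simulate_nb_counts(
    mu: float | np.ndarray,
    alpha: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Negative-binomial draws with mean mu and variance mu + alpha*mu^2."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n,)) if np.isscalar(mu) else mu
    if alpha <= 0:
        return rng.poisson(mu, size=(n,) if np.isscalar(mu) else None)
    size = 1.0 / alpha
    p = size / (size + np.asarray(mu, dtype=float))
    return rng.negative_binomial(size, p)


def generate_ortholog_fixture(
    worm_genes: Sequence[str],
    worm_targets: set[str],
    n_mammal: int | None = None,
    mammal_per_worm: float = 1.3,
    target_transfer: float = 0.6,
    background_rate: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, set[str]]:
    """A synthetic worm-mammal ortholog map plus a mammal PUF target list.

    Most worm genes get a single mammalian ortholog (1 + Poisson extras,
    mean ``mammal_per_worm``), keeping the bipartite graph sparse so
    ortholog groups stay small instead of collapsing into one giant
    component. Mammal orthologs of worm FBF targets are themselves targeted
    with probability ``target_transfer``; other mammal genes at
    ``background_rate``. Returns (edge table, mammal target set).
    """
    rng = np.random.default_rng(seed)
    if n_mammal is None:
        n_mammal = 2 * len(worm_genes)
    mammal = [f"HUM{i:05d}" for i in range(n_mammal)]
    extra = max(mammal_per_worm - 1.0, 0.0)
    edges = []
    for w in worm_genes:
        k = 1 + int(rng.poisson(extra))
        partners = rng.choice(n_mammal, size=min(k, n_mammal), replace=False)
        for j in partners:
            edges.append((w, mammal[j]))
    mammal_of_targets = {m for w, m in edges if w in worm_targets}
    mam_targets = {
        m for m in mammal
        if rng.random() < (target_transfer if m in mammal_of_targets
                           else background_rate)
    }
    df = pd.DataFrame(edges, columns=["worm_gene", "mammal_gene"]).drop_duplicates()
    return df, mam_targets
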