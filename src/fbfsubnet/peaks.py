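"""Peak calling against a Gaussian no-antibody null.

Candidate pile-ups are detected by a raw-coverage threshold; for each
candidate, reads in the 500-bp window around the summit are placed in ten
50-bp bins for both the FBF library and the no-antibody control. The
control bin heights (per-million scale, pooled over control replicates) fit
a Gaussian, and the peak's p-value is the upper-tail probability of the
summit-bin height under that null. p-values are Benjamini-Hochberg
corrected (FDR 1% by default) and two reads-in-peak ratio cutoffs are then
applied: per-million height >= 2x control and raw height >= 10x control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneIndex, reverse_complement
from .motif import FBEMatch, scan_fbe
from .preprocess import ProcessedRead


@dataclass
class CoverageTrack:
    """Per-base read coverage and read-start counts, per (chromosome, strand)."""

    coverage: dict[tuple[str, str], np.ndarray]
    starts: dict[tuple[str, str], np.ndarray]
    library_size: int

    def chrom_length(self, chromosome: str) -> int:
        lens = [len(a) for (c, _), a in self.coverage.items() if c == chromosome]
        return max(lens) if lens else 0


def build_coverage(
    reads: Iterable[ProcessedRead],
    chrom_lengths: Mapping[str, int] | None = None,
) -> CoverageTrack:
    """Coverage over [start, end) per read; start counts kept alongside.

    Sum of coverage equals the sum of read lengths (conservation).
    """
    reads = list(reads)
    if chrom_lengths is None:
        chrom_lengths = {}
        for r in reads:
            chrom_lengths[r.chromosome] = max(
                chrom_lengths.get(r.chromosome, 0), r.end
            )
    cov: dict[tuple[str, str], np.ndarray] = {}
    sta: dict[tuple[str, str], np.ndarray] = {}
    for r in reads:
        key = (r.chromosome, r.strand)
        if key not in cov:
            n = chrom_lengths[r.chromosome]
            cov[key] = np.zeros(n, dtype=np.int64)
            sta[key] = np.zeros(n, dtype=np.int64)
        cov[key][r.start:r.end] += 1
        sta[key][r.start] += 1
    return CoverageTrack(coverage=cov, starts=sta, library_size=len(reads))


@dataclass(frozen=True)
class Summit:
    chromosome: str
    strand: str
    position: int
    height: int


def find_candidate_peaks(
    track: CoverageTrack, min_height_raw: int = 5, merge_distance: int = 50
) -> list[Summit]:
    """Summits of maximal coverage runs >= ``min_height_raw``.

    One summit per run, at the argmax (leftmost on ties); summits closer
    than ``merge_distance`` are merged keeping the higher (leftmost on ties).
    """
    if min_height_raw < 1:
        raise ValueError("min_height_raw must be >= 1")
    out: list[Summit] = []
    for (chrom, strand) in sorted(track.coverage):
        cov = track.coverage[(chrom, strand)]
        above = cov >= min_height_raw
        if not above.any():
            continue
        flanked = np.r_[False, above, False].astype(np.int8)
        run_starts = np.flatnonzero(np.diff(flanked) == 1)
        run_ends = np.flatnonzero(np.diff(flanked) == -1)
        summits: list[Summit] = []
        for a, b in zip(run_starts, run_ends):
            pos = a + int(np.argmax(cov[a:b]))
            summits.append(Summit(chrom, strand, pos, int(cov[pos])))
        # merge nearby summits, keeping the higher (leftmost on ties)
        merged: list[Summit] = []
        for s in summits:
            if merged and s.position - merged[-1].position < merge_distance:
                if s.height > merged[-1].height:
                    merged[-1] = s
            else:
                merged.append(s)
        out.extend(merged)
    return out


@dataclass(frozen=True)
class GaussianNull:
    """Gaussian fit to control bin heights on the per-million scale."""

    mu: float
    sigma: float
    n_bins: int

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.n_bins < 1:
            raise ValueError("invalid GaussianNull")


def _window_bins(window: tuple[int, int], bin_size: int) -> list[tuple[int, int]]:
    a, b = window
    return [(x, min(x + bin_size, b)) for x in range(a, b, bin_size)]


def fit_control_null(
    control_tracks: "CoverageTrack | Sequence[CoverageTrack]",
    chromosome: str,
    strand: str,
    window: tuple[int, int],
    bin_size: int = 50,
) -> GaussianNull:
    """Gaussian null from control read starts in 50-bp bins over a window.

    Bin height = reads starting in the bin, scaled to per-million by each
    control replicate's own library size; heights pooled across replicates.
    mu and sigma are the sample mean and sample (n-1) standard deviation of
    the pooled heights. Window bins truncated at chromosome edges keep
    their (shorter) span; n_bins records the pooled count.
    """
    if isinstance(control_tracks, CoverageTrack):
        control_tracks = [control_tracks]
    heights: list[float] = []
    for track in control_tracks:
        scale = 1e6 / track.library_size if track.library_size else 0.0
        starts = track.starts.get((chromosome, strand))
        for a, b in _window_bins(window, bin_size):
            if starts is None:
                heights.append(0.0)
            else:
                a_c, b_c = max(a, 0), min(b, len(starts))
                raw = int(starts[a_c:b_c].sum()) if b_c > a_c else 0
                heights.append(raw * scale)
    arr = np.asarray(heights, dtype=float)
    sigma = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return GaussianNull(mu=float(arr.mean()), sigma=sigma, n_bins=len(arr))


def peak_pvalue(
    height_rpm: float, null: GaussianNull, sigma_floor: float
) -> float:
    """Upper-tail Gaussian probability of the peak-bin height under the null."""
    if sigma_floor <= 0:
        raise ValueError("sigma_floor must be > 0")
    sigma = max(null.sigma, sigma_floor)
    return float(stats.norm.sf(height_rpm, loc=null.mu, scale=sigma))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class Peak:
    """A candidate binding site and its statistics."""

    chromosome: str
    strand: str
    summit: int
    window: tuple[int, int]
    height_raw: int
    height_rpm: float
    control_raw: int
    control_rpm: float
    p_value: float
    p_adjusted: float = float("nan")
    gene_id: str = "unassigned"
    fbe: list[FBEMatch] = field(default_factory=list)
    fbe_summit: list[FBEMatch] = field(default_factory=list)
    rank: int = 0
    null: GaussianNull | None = None


def adjust_and_filter(
    peaks: list[Peak],
    fdr: float = 0.01,
    rpm_ratio_min: float = 2.0,
    raw_ratio_min: float = 10.0,
    eps_raw: float = 1.0,
    eps_rpm: float | None = None,
    control_library_size: int | None = None,
) -> list[Peak]:
    """BH-correct over all candidates, then apply the two ratio cutoffs.

    Survivors satisfy p_adjusted <= fdr, per-million height >=
    ``rpm_ratio_min`` x control (pseudocounted), and raw height >=
    ``raw_ratio_min`` x control (pseudocounted). The pseudocounts are the
    one-read equivalents, so zero-control peaks remain testable.
    """
    if not peaks:
        return []
    if eps_rpm is None:
        eps_rpm = 1e6 / control_library_size if control_library_size else 1.0
    padj = bh_adjust([p.p_value for p in peaks])
    for p, q in zip(peaks, padj):
        p.p_adjusted = float(q)
    out = []
    for p in peaks:
        if p.p_adjusted > fdr:
            continue
        if p.height_rpm < rpm_ratio_min * max(p.control_rpm, eps_rpm):
            continue
        if p.height_raw < raw_ratio_min * max(p.control_raw, eps_raw):
            continue
        out.append(p)
    return out


@dataclass
class PeakConfig:
    """Knobs of the peak caller; defaults are the study's stated cutoffs."""

    min_height_raw: int = 5
    window_size: int = 500
    bin_size: int = 50
    merge_distance: int = 50
    fdr: float = 0.01
    rpm_ratio_min: float = 2.0
    raw_ratio_min: float = 10.0
    sigma_floor: float | None = None  # default: one read per million of control
    pooled_null: bool = False  # fit one genome-wide null instead of per-window
    summit_flank: int = 25  # half-width of the "under the peak" FBE region


def _sense_window_sequence(
    genome: Mapping[str, str], chromosome: str, strand: str,
    start: int, end: int,
) -> str:
    seq = genome[chromosome][max(start, 0):end]
    return seq if strand == "+" else reverse_complement(seq)


def call_peaks(
    fbf_reads: Sequence[ProcessedRead],
    control_replicates: Sequence[Sequence[ProcessedRead]],
    annotation: GeneIndex,
    genome: Mapping[str, str] | None = None,
    config: PeakConfig | None = None,
) -> list[Peak]:
    """Full peak calling: candidates, Gaussian null, BH, ratio cutoffs.

    Survivors are gene-assigned (peak-assignment mode: ncRNA priority),
    FBE-annotated over the sense-strand window sequence when ``genome`` is
    given, and ranked by descending per-million height (ties broken by
    coordinate).
    """
    cfg = config or PeakConfig()
    chrom_lengths: dict[str, int] = {}
    if genome is not None:
        chrom_lengths = {c: len(s) for c, s in genome.items()}
    fbf_track = build_coverage(fbf_reads, chrom_lengths or None)
    control_tracks = [
        build_coverage(r, chrom_lengths or None) for r in control_replicates
    ]
    control_total = sum(t.library_size for t in control_tracks)
    sigma_floor = cfg.sigma_floor
    if sigma_floor is None:
        nonzero = [t.library_size for t in control_tracks if t.library_size]
        sigma_floor = 1e6 / min(nonzero) if nonzero else 1.0

    summits = find_candidate_peaks(fbf_track, cfg.min_height_raw,
                                   cfg.merge_distance)
    half = cfg.window_size // 2
    fbf_scale = 1e6 / fbf_track.library_size if fbf_track.library_size else 0.0
    pooled_nulls: dict[tuple[str, str], GaussianNull] = {}

    peaks: list[Peak] = []
    for s in summits:
        key = (s.chromosome, s.strand)
        clen = len(fbf_track.coverage[key])
        # anchor the tiling so the summit bin is centred on the summit:
        # read 5' starts sit ~half a read upstream of the coverage maximum,
        # and a boundary-anchored bin would systematically miss them
        w_start = max(s.position - half + cfg.bin_size // 2, 0)
        w_end = min(w_start + cfg.window_size, clen)
        w_start = max(w_end - cfg.window_size, 0)
        # summit bin within the window tiling
        bin_idx = (s.position - w_start) // cfg.bin_size
        b_a = w_start + bin_idx * cfg.bin_size
        b_b = min(b_a + cfg.bin_size, w_end)
        height_raw = int(fbf_track.starts[key][b_a:b_b].sum())
        height_rpm = height_raw * fbf_scale
        if cfg.pooled_null:
            if key not in pooled_nulls:
                pooled_nulls[key] = fit_control_null(
                    control_tracks, s.chromosome, s.strand, (0, clen),
                    cfg.bin_size,
                )
            null = pooled_nulls[key]
        else:
            null = fit_control_null(
                control_tracks, s.chromosome, s.strand, (w_start, w_end),
                cfg.bin_size,
            )
        control_raw = 0
        for t in control_tracks:
            st = t.starts.get(key)
            if st is not None:
                control_raw += int(st[b_a:b_b].sum())
        control_rpm = control_raw * 1e6 / control_total if control_total else 0.0
        peaks.append(Peak(
            chromosome=s.chromosome, strand=s.strand, summit=s.position,
            window=(w_start, w_end), height_raw=height_raw,
            height_rpm=height_rpm, control_raw=control_raw,
            control_rpm=control_rpm,
            p_value=peak_pvalue(height_rpm, null, sigma_floor),
            null=null,
        ))

    kept = adjust_and_filter(
        peaks, fdr=cfg.fdr, rpm_ratio_min=cfg.rpm_ratio_min,
        raw_ratio_min=cfg.raw_ratio_min,
        control_library_size=control_total or None,
    )
    for p in kept:
        probe = ProcessedRead(
            name="peak", chromosome=p.chromosome, strand=p.strand,
            start=p.summit, end=p.summit + 1, umi="N",
        )
        from .counts import assign_read_to_gene

        p.gene_id = assign_read_to_gene(probe, annotation, mode="peak_assignment")
        if genome is not None:
            p.fbe = scan_fbe(_sense_window_sequence(
                genome, p.chromosome, p.strand, p.window[0], p.window[1]
            ))
            f = cfg.summit_flank
            p.fbe_summit = scan_fbe(_sense_window_sequence(
                genome, p.chromosome, p.strand,
                max(p.summit - f, 0), p.summit + f + 8,
            ))
    kept.sort(key=lambda p: (-p.height_rpm, p.chromosome, p.summit))
    for i, p in enumerate(kept, start=1):
        p.rank = i
    return kept


def write_peaks_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """BED6+ export: window interval, gene, per-million height, statistics."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tsummit\t"
                 "height_raw\tcontrol_raw\tcontrol_rpm\tp_value\t"
                 "p_adjusted\tn_fbe\tn_fbe_summit\trank\n")
        for p in peaks:
            fh.write("\t".join(str(x) for x in (
                p.chromosome, p.window[0], p.window[1], p.gene_id,
                f"{p.height_rpm:.4f}", p.strand, p.summit, p.height_raw,
                p.control_raw, f"{p.control_rpm:.4f}", f"{p.p_value:.6g}",
                f"{p.p_adjusted:.6g}", len(p.fbe), len(p.fbe_summit), p.rank,
            )) + "\n")
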