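"""Read-to-gene assignment, counts matrices and replicate handling.

A read is assigned to a gene iff it overlaps (>=1 shared base, same strand)
an exon of that gene. When counting reads-per-gene, reads overlapping exons
of two or more genes are discarded as ambiguous; when assigning *peaks*, a
peak overlapping both an mRNA and a single ncRNA-biotype gene goes to the
ncRNA (ncRNA priority). Reads-per-million (RPM) over the per-sample library
of assigned reads is the binding-frequency proxy used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneIndex
from .preprocess import ProcessedRead

NC_BIOTYPES = {"ncRNA", "lincRNA", "snoRNA"}

#: FBF-1/FBF-2 concatenation orders used to build the combined "FBF"
#: replicates: oogenic 25deg pairs FBF-1 rep i with FBF-2 rep j as (i, j).
OOGENIC_PAIRING: list[tuple[int, int]] = [(1, 3), (2, 2), (3, 1)]
SPERMATOGENIC_PAIRING: list[tuple[int, int]] = [(2, 1), (1, 2), (3, 3)]


def assign_read_to_gene(
    read: ProcessedRead,
    annotation: GeneIndex,
    mode: str = "counting",
) -> str:
    """Gene id for a read, or "unassigned" / "ambiguous".

    counting mode: exactly one exon-overlapping gene -> that gene; two or
    more -> "ambiguous"; none -> "unassigned". peak_assignment mode: if the
    overlapped genes include exactly one ncRNA-biotype gene it wins;
    otherwise the counting rule applies.
    """
    if mode not in ("counting", "peak_assignment"):
        raise ValueError(f"unknown mode {mode!r}")
    hits = annotation.overlapping_genes(
        read.chromosome, read.strand, read.start, read.end
    )
    if not hits:
        return "unassigned"
    if len(hits) == 1:
        return next(iter(hits))
    if mode == "peak_assignment":
        nc = [g for g in hits if annotation.genes[g].biotype in NC_BIOTYPES]
        if len(nc) == 1:
            return nc[0]
    return "ambiguous"


@dataclass
class CountsMatrix:
    """Genes x samples integer counts with per-sample library sizes."""

    counts: pd.DataFrame  # index: gene ids; columns: sample labels
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.library_sizes = self.library_sizes.astype(np.int64)
        if list(self.counts.columns) != list(self.library_sizes.index):
            raise ValueError("library_sizes must match the sample columns")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if (self.counts.sum(axis=0) > self.library_sizes).any():
            raise ValueError("column sums exceed library sizes")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.loc["__library_size__"] = self.library_sizes
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountsMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        lib = df.loc["__library_size__"]
        return cls(df.drop(index="__library_size__"), lib)


def build_counts_matrix(
    reads_per_sample: Mapping[str, Iterable[ProcessedRead]],
    annotation: GeneIndex,
) -> CountsMatrix:
    """Count deduplicated reads per gene in counting mode.

    library_size of a sample is its total *assigned* reads. Per sample,
    assigned + ambiguous + unassigned equals the input read count; counting
    is order-independent.
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    gene_ids = sorted(annotation.genes)
    data = {}
    libs = {}
    for sample, reads in reads_per_sample.items():
        col = dict.fromkeys(gene_ids, 0)
        assigned = 0
        for r in reads:
            g = assign_read_to_gene(r, annotation, mode="counting")
            if g not in ("unassigned", "ambiguous"):
                col[g] += 1
                assigned += 1
        data[sample] = col
        libs[sample] = assigned
    counts = pd.DataFrame(data, index=gene_ids)
    return CountsMatrix(counts, pd.Series(libs)[counts.columns])


def normalize_rpm(matrix: CountsMatrix) -> pd.DataFrame:
    """Reads-per-million: count * 1e6 / library_size, per sample."""
    zero = matrix.library_sizes[matrix.library_sizes == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return matrix.counts * 1e6 / matrix.library_sizes


def combine_replicates(
    matrix_a: CountsMatrix,
    matrix_b: CountsMatrix,
    pairing: Sequence[tuple[int, int]],
    prefix: str = "FBF",
) -> CountsMatrix:
    """Concatenate paired replicate columns of two single-protein matrices.

    ``pairing`` lists 1-based (replicate_a, replicate_b) pairs; combined
    column i sums matrix_a's column pairing[i][0] with matrix_b's column
    pairing[i][1], and library sizes add. The default orders for the real
    study are :data:`OOGENIC_PAIRING` and :data:`SPERMATOGENIC_PAIRING`.
    """
    if list(matrix_a.counts.index) != list(matrix_b.counts.index):
        raise ValueError("gene sets differ between the matrices")
    a_used = [i for i, _ in pairing]
    b_used = [j for _, j in pairing]
    if sorted(a_used) != sorted(set(a_used)) or sorted(b_used) != sorted(set(b_used)):
        raise ValueError("pairing must be a bijection between replicate indices")
    cols = {}
    libs = {}
    for k, (i, j) in enumerate(pairing, start=1):
        ca = matrix_a.counts.iloc[:, i - 1]
        cb = matrix_b.counts.iloc[:, j - 1]
        name = f"{prefix}_rep{k}"
        cols[name] = ca + cb
        libs[name] = (matrix_a.library_sizes.iloc[i - 1]
                      + matrix_b.library_sizes.iloc[j - 1])
    counts = pd.DataFrame(cols)
    return CountsMatrix(counts, pd.Series(libs)[counts.columns])


@dataclass
class CorrelationReport:
    """Spearman rho between samples plus a within- vs between-gender t-test."""

    rho: pd.DataFrame
    within_sperm: list[float]
    within_oocyte: list[float]
    between: list[float]
    t_statistic: float
    p_value: float

    @property
    def within(self) -> list[float]:
        return self.within_sperm + self.within_oocyte

    def to_json_dict(self) -> dict:
        return {
            "rho": self.rho.to_dict(),
            "within_sperm_mean": float(np.mean(self.within_sperm)) if self.within_sperm else None,
            "within_oocyte_mean": float(np.mean(self.within_oocyte)) if self.within_oocyte else None,
            "between_mean": float(np.mean(self.between)) if self.between else None,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
        }


def correlation_report(
    matrix: CountsMatrix,
    gender_labels: Mapping[str, str],
) -> CorrelationReport:
    """Pairwise Spearman rho over reads-per-gene, grouped by germline gender.

    Within-gender pairs (both sperm or both oocyte) are pooled and compared
    against between-gender pairs with a two-sample, two-tailed t-test. A
    constant column leaves its pairs as NaN (rho undefined), excluded from
    the pooled sets.
    """
    samples = matrix.samples
    for s in samples:
        if gender_labels.get(s) not in ("sperm", "oocyte"):
            raise ValueError(f"sample {s} lacks a sperm/oocyte label")
    for gender in ("sperm", "oocyte"):
        if sum(gender_labels[s] == gender for s in samples) < 2:
            raise ValueError(f"need >=2 samples of gender {gender}")
    rho = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    within_sperm, within_oocyte, between = [], [], []
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            xa, xb = matrix.counts[a], matrix.counts[b]
            if xa.nunique() <= 1 or xb.nunique() <= 1:
                r = np.nan
            else:
                r = stats.spearmanr(xa, xb).statistic
            rho.loc[a, b] = rho.loc[b, a] = r
            if np.isnan(r):
                continue
            ga, gb = gender_labels[a], gender_labels[b]
            if ga != gb:
                between.append(float(r))
            elif ga == "sperm":
                within_sperm.append(float(r))
            else:
                within_oocyte.append(float(r))
    within = within_sperm + within_oocyte
    t, p = stats.ttest_ind(within, between, equal_var=True)
    return CorrelationReport(
        rho=rho, within_sperm=within_sperm, within_oocyte=within_oocyte,
        between=between, t_statistic=float(t), p_value=float(p),
    )
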