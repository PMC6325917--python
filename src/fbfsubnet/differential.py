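"""Gender-differential FBF binding on reads-per-gene.

A negative-binomial Wald test over replicate reads-per-gene, with
median-of-ratios library normalization, a method-of-moments dispersion
estimate moderated by a 1/mean trend, and Benjamini-Hochberg correction.
Genes enter the test only if they belong to a gamete program (spermatogenic,
oogenic or both) and average at least 20 raw reads over the designated
samples; calls require adjusted p < 0.01 and a twofold change, matching the
thresholds the analysis design fixes. The GLM internals of dedicated
differential-expression packages are deliberately not replicated; the
comparison design, filters and thresholds are the point here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CountsMatrix
from .peaks import bh_adjust

logger = logging.getLogger(__name__)

_ALPHA_FLOOR = 1e-8


def filter_testable_genes(
    matrix: CountsMatrix,
    programs: Mapping[str, str],
    min_mean_reads: float = 20.0,
    samples: Sequence[str] | None = None,
) -> list[str]:
    """Genes in a gamete program with mean raw count >= ``min_mean_reads``.

    The mean is taken over ``samples`` (default: all columns); the program
    restriction keeps genes labeled spermatogenic, oogenic or both.
    """
    cols = list(samples) if samples is not None else matrix.samples
    means = matrix.counts[cols].mean(axis=1)
    keep = []
    for g in matrix.genes:
        if programs.get(g, "none") not in ("spermatogenic", "oogenic", "both"):
            continue
        if means[g] >= min_mean_reads:
            keep.append(g)
    return keep


def estimate_size_factors(matrix: CountsMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    factor_s = median over genes (nonzero in every sample) of
    count(g, s) / geometric_mean_g(count).
    """
    counts = matrix.counts.to_numpy(dtype=float)
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; consider a pseudocount"
        )
    ref = counts[nonzero]
    log_gmean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_gmean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors /= np.exp(np.log(factors).mean())  # geometric mean 1
    return pd.Series(factors, index=matrix.samples, name="size_factor")


@dataclass
class DifferentialResult:
    gene_id: str
    base_mean: float
    log2_fold_change: float  # sperm over oocyte
    p_value: float
    p_adjusted: float = float("nan")
    call: str = "ns"
    dispersion: float = float("nan")


def _fit_dispersion_trend(
    base_mean: np.ndarray, alpha_mom: np.ndarray
) -> np.ndarray:
    """Least-squares fit of alpha ~ a1/mu + a0 on the MoM estimates.

    Fit on genes with informative (above-floor) estimates; coefficients
    clipped non-negative. Falls back to the median estimate when too few
    genes inform the fit.
    """
    ok = alpha_mom > 10 * _ALPHA_FLOOR
    if ok.sum() < 10:
        level = float(np.median(alpha_mom[ok])) if ok.any() else 0.01
        return np.full_like(base_mean, max(level, 1e-4))
    X = np.c_[1.0 / base_mean[ok], np.ones(ok.sum())]
    coef, *_ = np.linalg.lstsq(X, alpha_mom[ok], rcond=None)
    a1, a0 = np.maximum(coef, 0.0)
    trend = a1 / base_mean + a0
    return np.maximum(trend, 1e-6)


def test_differential_binding(
    matrix: CountsMatrix,
    factors: pd.Series,
    design: Mapping[str, str],
    genes: Sequence[str] | None = None,
    pseudocount: float = 0.5,
) -> list[DifferentialResult]:
    """Per-gene NB Wald test of sperm vs oocyte binding frequency.

    Normalized counts are count / size factor. Dispersion alpha is the
    method-of-moments estimate pooled within gender (floored at 1e-8) and
    moderated against a fitted a1/mu + a0 trend by taking the larger of the
    two — a conservative choice that keeps the test calibrated when three
    replicates leave the per-gene estimate at the floor. The Wald statistic
    is log2FC / se(log2FC) under NB variance mu + alpha*mu^2, referred to a
    standard normal, two-sided; BH correction runs across tested genes.
    Genes with all-zero counts in both genders are excluded and logged.
    """
    samples = matrix.samples
    sperm = [s for s in samples if design.get(s) == "sperm"]
    oocyte = [s for s in samples if design.get(s) == "oocyte"]
    if len(sperm) < 2 or len(oocyte) < 2:
        raise ValueError("need >=2 replicates per gender")
    test_genes = list(genes) if genes is not None else matrix.genes
    norm = matrix.counts.loc[test_genes].to_numpy(dtype=float) / \
        factors[samples].to_numpy()
    idx_s = [samples.index(s) for s in sperm]
    idx_o = [samples.index(s) for s in oocyte]
    ns_, no_ = len(idx_s), len(idx_o)

    all_zero = norm.sum(axis=1) == 0
    if all_zero.any():
        logger.info("excluding %d all-zero genes", int(all_zero.sum()))
    keep = ~all_zero
    norm = norm[keep]
    kept_genes = [g for g, k in zip(test_genes, keep) if k]

    m_s = norm[:, idx_s].mean(axis=1)
    m_o = norm[:, idx_o].mean(axis=1)
    v_s = norm[:, idx_s].var(axis=1, ddof=1)
    v_o = norm[:, idx_o].var(axis=1, ddof=1)
    base_mean = norm.mean(axis=1)

    # method-of-moments dispersion pooled within gender:
    # var = mu + alpha mu^2  =>  alpha = (var - mu) / mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (ns_ - 1) * (v_s - m_s) + (no_ - 1) * (v_o - m_o)
        den = (ns_ - 1) * m_s**2 + (no_ - 1) * m_o**2
        alpha_mom = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    alpha_mom = np.maximum(alpha_mom, _ALPHA_FLOOR)
    trend = _fit_dispersion_trend(np.maximum(base_mean, 1e-8), alpha_mom)
    alpha = np.maximum(alpha_mom, trend)

    d = pseudocount
    lfc = np.log2(m_s + d) - np.log2(m_o + d)
    var_mean_s = (m_s + alpha * m_s**2) / ns_
    var_mean_o = (m_o + alpha * m_o**2) / no_
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_mean_s / (m_s + d) ** 2 + var_mean_o / (m_o + d) ** 2
    ) / ln2
    se = np.maximum(se, 1e-12)
    z = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    padj = bh_adjust(p)

    return [
        DifferentialResult(
            gene_id=g, base_mean=float(bm), log2_fold_change=float(l),
            p_value=float(pv), p_adjusted=float(pa), dispersion=float(a),
        )
        for g, bm, l, pv, pa, a in zip(kept_genes, base_mean, lfc, p, padj, alpha)
    ]


def call_gender_enriched(
    results: Sequence[DifferentialResult],
    padj_max: float = 0.01,
    min_fold: float = 2.0,
    strict_fold: bool = False,
) -> list[DifferentialResult]:
    """Label results sperm_enriched / oocyte_enriched / ns in place.

    sperm_enriched: log2FC >= log2(min_fold) (strictly > when
    ``strict_fold``) and adjusted p < ``padj_max``; oocyte_enriched is
    symmetric.
    """
    thr = np.log2(min_fold)
    for r in results:
        big = (abs(r.log2_fold_change) > thr if strict_fold
               else abs(r.log2_fold_change) >= thr)
        if big and r.p_adjusted < padj_max:
            r.call = ("sperm_enriched" if r.log2_fold_change > 0
                      else "oocyte_enriched")
        else:
            r.call = "ns"
    return list(results)


def results_to_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": r.gene_id, "baseMean": r.base_mean,
        "log2FoldChange": r.log2_fold_change, "pvalue": r.p_value,
        "padj": r.p_adjusted, "call": r.call, "dispersion": r.dispersion,
    } for r in results])


def write_results(results: Sequence[DifferentialResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
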