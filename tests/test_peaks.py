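"""Peak statistics: coverage, candidates, Gaussian null, BH, ratio cutoffs."""

import math

import numpy as np
import pytest
from scipy import special

from fbfsubnet.annotation import GeneAnnotation, GeneIndex
from fbfsubnet.peaks import (CoverageTrack, GaussianNull, Peak, PeakConfig,
                             adjust_and_filter, bh_adjust, build_coverage,
                             call_peaks, find_candidate_peaks,
                             fit_control_null, peak_pvalue)
from fbfsubnet.preprocess import ProcessedRead


def _read(start, end=None, chrom="chr1", strand="+", name="r"):
    return ProcessedRead(name=name, chromosome=chrom, strand=strand,
                         start=start, end=end or start + 35, umi="AAAA")


def _track_from_starts(starts, chrom_len=2000, library=None):
    reads = [_read(s, name=f"r{i}") for i, s in enumerate(starts)]
    t = build_coverage(reads, {"chr1": chrom_len})
    if library is not None:
        t.library_size = library
    return t


class TestCoverage:
    def test_single_read(self):
        t = build_coverage([_read(100)], {"chr1": 500})
        cov = t.coverage[("chr1", "+")]
        assert cov[100:135].sum() == 35
        assert cov.sum() == 35
        assert t.starts[("chr1", "+")][100] == 1

    def test_depth_two_without_dedup(self):
        t = build_coverage([_read(100), _read(100)], {"chr1": 500})
        assert t.coverage[("chr1", "+")][110] == 2

    def test_conservation(self):
        rng = np.random.default_rng(0)
        reads = [_read(int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 900, 200),
                                 rng.integers(20, 50, 200))]
        t = build_coverage(reads, {"chr1": 1000})
        total = sum(a.sum() for a in t.coverage.values())
        assert total == sum(r.end - r.start for r in reads)


class TestCandidates:
    def test_flat_zero(self):
        t = _track_from_starts([])
        assert find_candidate_peaks(t, 5) == []

    def test_single_pile_summit_at_argmax(self):
        starts = [1000 - 17] * 12  # triangular pile peaking at ~1000
        t = _track_from_starts(starts)
        (s,) = find_candidate_peaks(t, 5)
        assert s.position == 983  # plateau of height 12: leftmost argmax
        assert s.height == 12

    def test_two_equal_maxima_merge_to_left(self):
        # two runs 30 bp apart with equal heights merge, keeping the left
        starts = [100] * 6 + [130] * 6
        t = CoverageTrack(
            coverage={("chr1", "+"): np.zeros(500, dtype=np.int64)},
            starts={("chr1", "+"): np.zeros(500, dtype=np.int64)},
            library_size=12,
        )
        t.coverage[("chr1", "+")][100:110] = 6
        t.coverage[("chr1", "+")][130:140] = 6
        (s,) = find_candidate_peaks(t, 5)
        assert s.position == 100

    def test_distant_summits_not_merged(self):
        t = CoverageTrack(
            coverage={("chr1", "+"): np.zeros(500, dtype=np.int64)},
            starts={("chr1", "+"): np.zeros(500, dtype=np.int64)},
            library_size=12,
        )
        t.coverage[("chr1", "+")][100:105] = 6
        t.coverage[("chr1", "+")][300:305] = 8
        assert len(find_candidate_peaks(t, 5)) == 2


class TestGaussianNull:
    def test_hand_computed_moments(self):
        # one control replicate, library 1e6, bin heights 0,1,2,1,0,1,2,1,0,2
        heights = [0, 1, 2, 1, 0, 1, 2, 1, 0, 2]
        starts = []
        for i, h in enumerate(heights):
            starts += [i * 50 + 10] * h
        t = _track_from_starts(starts, chrom_len=600, library=1_000_000)
        null = fit_control_null(t, "chr1", "+", (0, 500))
        assert null.mu == pytest.approx(1.0)
        assert null.sigma == pytest.approx(0.8165, abs=1e-4)
        assert null.n_bins == 10

    def test_constant_bins_zero_sigma(self):
        starts = [i * 50 + 5 for i in range(10)] * 5
        t = _track_from_starts(starts, chrom_len=600, library=1_000_000)
        null = fit_control_null(t, "chr1", "+", (0, 500))
        assert null.mu == pytest.approx(5.0)
        assert null.sigma == 0.0

    def test_per_million_scale_invariance(self):
        heights = [0, 1, 2, 1, 0, 1, 2, 1, 0, 2]
        starts = []
        for i, h in enumerate(heights):
            starts += [i * 50 + 10] * h
        t1 = _track_from_starts(starts, chrom_len=600, library=1_000_000)
        t2 = _track_from_starts([s for s in starts for _ in range(2)],
                                chrom_len=600, library=2_000_000)
        n1 = fit_control_null(t1, "chr1", "+", (0, 500))
        n2 = fit_control_null(t2, "chr1", "+", (0, 500))
        assert n1.mu == pytest.approx(n2.mu)
        assert n1.sigma == pytest.approx(n2.sigma)


class TestPValue:
    def test_height_at_mean_is_half(self):
        null = GaussianNull(mu=3.0, sigma=1.0, n_bins=10)
        assert peak_pvalue(3.0, null, 0.1) == pytest.approx(0.5)

    def test_hand_computed_tail(self):
        # z = (5 - 1) / 0.8165 = 4.899; erfc oracle
        null = GaussianNull(mu=1.0, sigma=0.8165, n_bins=10)
        p = peak_pvalue(5.0, null, 0.01)
        z = (5.0 - 1.0) / 0.8165
        oracle = 0.5 * special.erfc(z / math.sqrt(2))
        assert p == pytest.approx(oracle, rel=1e-12)
        assert p == pytest.approx(4.8e-7, rel=0.02)

    def test_monotone_decreasing_in_height(self):
        null = GaussianNull(mu=1.0, sigma=0.5, n_bins=10)
        ps = [peak_pvalue(h, null, 0.1) for h in np.linspace(0, 50, 40)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-12

    def test_sigma_floor_applies(self):
        null = GaussianNull(mu=0.0, sigma=0.0, n_bins=10)
        assert 0 < peak_pvalue(5.0, null, 1.0) < 1e-5


def brute_force_bh(p):
    """min over j >= i of m*p(j)/j, capped at 1 — the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            min(m * p[order[j - 1]] / j, 1.0) for j in range(rank_i, m + 1)
        ]
        adj[idx] = min(candidates)
    return adj


class TestBH:
    def test_worked_example(self):
        got = bh_adjust([0.001, 0.008, 0.039, 0.041])
        assert got == pytest.approx([0.004, 0.016, 0.041, 0.041])

    def test_fixed_point(self):
        assert bh_adjust([0.03, 0.03, 0.03]) == pytest.approx([0.03] * 3)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(1, 60))
            p = rng.uniform(0, 1, n)
            assert bh_adjust(p) == pytest.approx(brute_force_bh(p))


def _peak(p_value, height_rpm=100.0, height_raw=50, control_rpm=1.0,
          control_raw=0, summit=100):
    return Peak(chromosome="chr1", strand="+", summit=summit,
                window=(summit - 250, summit + 250), height_raw=height_raw,
                height_rpm=height_rpm, control_raw=control_raw,
                control_rpm=control_rpm, p_value=p_value)


class TestAdjustAndFilter:
    def test_empty(self):
        assert adjust_and_filter([]) == []

    def test_ratio_rejection(self):
        p = _peak(1e-4, height_rpm=30.0, control_rpm=20.0)
        assert adjust_and_filter([p], control_library_size=1_000_000) == []
        p2 = _peak(1e-4, height_rpm=50.0, control_rpm=20.0, height_raw=50,
                   control_raw=2)
        assert adjust_and_filter([p2], control_library_size=1_000_000) == [p2]

    def test_raw_tenfold_rejection(self):
        p = _peak(1e-4, height_rpm=500.0, control_rpm=1.0, height_raw=9,
                  control_raw=0)
        # pseudocount 1: raw height must reach 10
        assert adjust_and_filter([p], control_library_size=1_000_000) == []

    def test_fdr_boundary(self):
        keep = _peak(0.005)
        drop = _peak(0.9)
        out = adjust_and_filter([keep, drop], control_library_size=1_000_000)
        assert out == [keep]
        assert keep.p_adjusted >= keep.p_value


@pytest.fixture(scope="module")
def called_dataset(small_dataset):
    from fbfsubnet.preprocess import collapse_duplicates

    samples = small_dataset["samples"]
    fbf = [r for s in samples.values()
           if s.antibody == "FBF" and s.gender == "sperm"
           for r in collapse_duplicates(s.reads)]
    controls = [collapse_duplicates(s.reads) for s in samples.values()
                if s.antibody == "control" and s.gender == "sperm"]
    called = call_peaks(fbf, controls, small_dataset["index"],
                        small_dataset["genome"], PeakConfig())
    return called


class TestCallPeaks:
    def test_called_genes_are_planted_targets(self, small_dataset, called_dataset):
        truth = small_dataset["truth"]
        targets = set(truth.targets())
        assert called_dataset, "no peaks called on the planted fixture"
        assert {p.gene_id for p in called_dataset} <= targets

    def test_summits_near_planted_positions(self, small_dataset, called_dataset):
        truth = small_dataset["truth"]
        for p in called_dataset:
            planted = truth.peak_genomic_position[p.gene_id]
            assert abs(p.summit - planted) <= 50

    def test_rank_is_deterministic_and_height_ordered(self, called_dataset):
        heights = [p.height_rpm for p in called_dataset]
        assert heights == sorted(heights, reverse=True)
        assert [p.rank for p in called_dataset] == \
            list(range(1, len(called_dataset) + 1))

    def test_read_order_invariance(self, small_dataset):
        from fbfsubnet.preprocess import collapse_duplicates

        samples = small_dataset["samples"]
        fbf = [r for s in samples.values()
               if s.antibody == "FBF" and s.gender == "oocyte"
               for r in collapse_duplicates(s.reads)]
        controls = [collapse_duplicates(s.reads) for s in samples.values()
                    if s.antibody == "control" and s.gender == "oocyte"]
        a = call_peaks(fbf, controls, small_dataset["index"],
                       small_dataset["genome"])
        b = call_peaks(list(reversed(fbf)), controls,
                       small_dataset["index"], small_dataset["genome"])
        assert [(p.gene_id, p.summit, p.rank) for p in a] == \
            [(p.gene_id, p.summit, p.rank) for p in b]

    def test_fbe_annotation_present(self, called_dataset):
        with_fbe = sum(1 for p in called_dataset if p.fbe)
        assert with_fbe == len(called_dataset)
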