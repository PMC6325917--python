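"""Read-to-gene assignment rules, counts matrices, RPM, replicate handling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fbfsubnet.annotation import GeneAnnotation, GeneIndex
from fbfsubnet.counts import (OOGENIC_PAIRING, SPERMATOGENIC_PAIRING,
                              CountsMatrix, assign_read_to_gene,
                              build_counts_matrix, combine_replicates,
                              correlation_report, normalize_rpm)
from fbfsubnet.preprocess import ProcessedRead


def _read(chrom="chr1", strand="+", start=0, end=35, name="r"):
    return ProcessedRead(name=name, chromosome=chrom, strand=strand,
                         start=start, end=end, umi="AAAA")


@pytest.fixture(scope="module")
def toy_index():
    genes = [
        # two-exon mRNA with an intron at [300, 500)
        GeneAnnotation("mrna1", "mRNA", "chr1", "+",
                       exons=[(100, 300), (500, 800)], utr3=(700, 800)),
        # ncRNA overlapping mrna1's second exon
        GeneAnnotation("nc1", "ncRNA", "chr1", "+", exons=[(600, 700)]),
        # minus-strand gene under mrna1's first exon
        GeneAnnotation("mrna2", "mRNA", "chr1", "-",
                       exons=[(150, 400)], utr3=(150, 250)),
    ]
    return GeneIndex(genes)


class TestAssignment:
    def test_intronic_read_is_unassigned(self, toy_index):
        # inside mrna1's intron: overlap requires an exon, not the gene span
        r = _read(start=350, end=385)
        assert assign_read_to_gene(r, toy_index, "counting") == "unassigned"

    def test_single_gene_exon_overlap(self, toy_index):
        r = _read(start=290, end=325)  # spans exon edge; >=1 base suffices
        assert assign_read_to_gene(r, toy_index, "counting") == "mrna1"

    def test_mrna_ncrna_overlap_ambiguous_when_counting(self, toy_index):
        r = _read(start=620, end=655)
        assert assign_read_to_gene(r, toy_index, "counting") == "ambiguous"

    def test_mrna_ncrna_overlap_goes_to_ncrna_for_peaks(self, toy_index):
        r = _read(start=620, end=655)
        assert assign_read_to_gene(r, toy_index, "peak_assignment") == "nc1"

    def test_strand_discipline(self, toy_index):
        plus = _read(start=200, end=235, strand="+")
        minus = _read(start=200, end=235, strand="-")
        assert assign_read_to_gene(plus, toy_index, "counting") == "mrna1"
        assert assign_read_to_gene(minus, toy_index, "counting") == "mrna2"


class TestCountsMatrix:
    def test_empty_reads_zero_matrix(self, toy_index):
        m = build_counts_matrix({"a": [], "b": []}, toy_index)
        assert m.counts.shape == (3, 2)
        assert (m.counts.values == 0).all()
        assert (m.library_sizes == 0).all()

    def test_single_gene_counts_and_library(self, toy_index):
        reads = [_read(start=500 + 10 * i, end=535 + 10 * i, name=f"r{i}")
                 for i in range(7)]
        m = build_counts_matrix({"s": reads}, toy_index)
        assert m.counts.loc["mrna1", "s"] == 7
        assert m.library_sizes["s"] == 7

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            build_counts_matrix({"s": []}, GeneIndex([]))

    def test_conservation_and_order_independence(self, small_dataset):
        index = small_dataset["index"]
        sample = small_dataset["samples"]["control_oocyte_rep1"]
        reads = sample.reads[:800]
        labels = [assign_read_to_gene(r, index, "counting") for r in reads]
        n_assigned = sum(1 for x in labels
                         if x not in ("unassigned", "ambiguous"))
        n_amb = labels.count("ambiguous")
        n_un = labels.count("unassigned")
        assert n_assigned + n_amb + n_un == len(reads)
        m1 = build_counts_matrix({"s": reads}, index)
        m2 = build_counts_matrix({"s": list(reversed(reads))}, index)
        pd.testing.assert_frame_equal(m1.counts, m2.counts)

    def test_counts_match_generator_truth(self, small_dataset):
        """Per-gene counts equal the generator's molecule bookkeeping."""
        from fbfsubnet.preprocess import collapse_duplicates

        cfg = small_dataset["config"]
        index = small_dataset["index"]
        sample = small_dataset["samples"]["FBF_oocyte_rep2"]
        dedup = collapse_duplicates(sample.reads)
        m = build_counts_matrix({"s": dedup}, index)
        truth_per_gene = {}
        for r in dedup:
            gid = r.name.split(".")[1]
            truth_per_gene[gid] = truth_per_gene.get(gid, 0) + 1
        mismatches = sum(
            1 for g in m.genes
            if m.counts.loc[g, "s"] != truth_per_gene.get(g, 0)
        )
        # reads of genes overlapping another gene's exons are discarded as
        # ambiguous, so equality is required only for cleanly assigned genes
        assert mismatches <= 0.1 * len(m.genes)


class TestRPM:
    def test_arithmetic(self):
        cm = CountsMatrix(pd.DataFrame({"s": [50, 0]}, index=["g1", "g2"]),
                          pd.Series({"s": 2_000_000}))
        rpm = normalize_rpm(cm)
        assert rpm.loc["g1", "s"] == pytest.approx(25.0)
        assert rpm.loc["g2", "s"] == 0.0

    def test_column_sum_identity(self):
        counts = pd.DataFrame({"a": [3, 7], "b": [1, 9]}, index=["g1", "g2"])
        cm = CountsMatrix(counts, counts.sum())
        assert normalize_rpm(cm).sum().tolist() == pytest.approx([1e6, 1e6])

    def test_zero_library_names_sample(self):
        cm = CountsMatrix(pd.DataFrame({"bad": [0]}, index=["g"]),
                          pd.Series({"bad": 0}))
        with pytest.raises(ValueError, match="bad"):
            normalize_rpm(cm)


class TestCombineReplicates:
    def _matrix(self, cols):
        df = pd.DataFrame(cols, index=["g1", "g2", "g3"])
        return CountsMatrix(df, df.sum())

    def test_identity_pairing_doubles(self):
        m = self._matrix({"r1": [1, 2, 3]})
        c = combine_replicates(m, m, [(1, 1)])
        assert c.counts.iloc[:, 0].tolist() == [2, 4, 6]
        assert c.library_sizes.iloc[0] == 12

    def test_oogenic_default_pairing(self):
        fbf1 = self._matrix({"f1r1": [1, 0, 0], "f1r2": [2, 0, 0],
                             "f1r3": [4, 0, 0]})
        fbf2 = self._matrix({"f2r1": [8, 0, 0], "f2r2": [16, 0, 0],
                             "f2r3": [32, 0, 0]})
        c = combine_replicates(fbf1, fbf2, OOGENIC_PAIRING, prefix="FBF_oo")
        # rep1 = FBF-1 rep1 + FBF-2 rep3, per the 1/3, 2/2, 3/1 order
        assert c.counts.loc["g1", "FBF_oo_rep1"] == 1 + 32
        assert c.counts.loc["g1", "FBF_oo_rep2"] == 2 + 16
        assert c.counts.loc["g1", "FBF_oo_rep3"] == 4 + 8
        c2 = combine_replicates(fbf1, fbf2, SPERMATOGENIC_PAIRING)
        assert c2.counts.loc["g1", "FBF_rep1"] == 2 + 8  # 2/1, 1/2, 3/3

    def test_combined_rpm_is_count_weighted_average(self):
        rng = np.random.default_rng(5)
        a = self._matrix({"r1": rng.integers(0, 50, 3).tolist()})
        b = self._matrix({"r1": rng.integers(0, 50, 3).tolist()})
        c = combine_replicates(a, b, [(1, 1)])
        rpm_a, rpm_b = normalize_rpm(a), normalize_rpm(b)
        la, lb = a.library_sizes.iloc[0], b.library_sizes.iloc[0]
        expected = (rpm_a.iloc[:, 0] * la + rpm_b.iloc[:, 0] * lb) / (la + lb)
        got = normalize_rpm(c).iloc[:, 0]
        assert got.tolist() == pytest.approx(expected.tolist())

    def test_mismatched_genes_rejected(self):
        a = self._matrix({"r1": [1, 2, 3]})
        b = CountsMatrix(pd.DataFrame({"r1": [1]}, index=["other"]),
                         pd.Series({"r1": 1}))
        with pytest.raises(ValueError):
            combine_replicates(a, b, [(1, 1)])


class TestCorrelationReport:
    def _matrix(self, data):
        df = pd.DataFrame(data)
        df.index = [f"g{i}" for i in range(len(df))]
        return CountsMatrix(df, df.sum() + 10)

    def test_self_correlation_and_reversal(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 100, 30)
        rev = x.max() - x  # rank reversal of x
        m = self._matrix({"a1": x, "a2": x, "b1": rev, "b2": rev})
        rep = correlation_report(m, {"a1": "sperm", "a2": "sperm",
                                     "b1": "oocyte", "b2": "oocyte"})
        assert rep.rho.loc["a1", "a1"] == 1.0
        assert rep.rho.loc["a1", "a2"] == pytest.approx(1.0)
        assert rep.rho.loc["a1", "b1"] == pytest.approx(-1.0)
        assert np.allclose(rep.rho.values, rep.rho.values.T)

    def test_t_statistic_matches_closed_form(self):
        """The gender t-test equals the hand-computed two-sample t."""
        within = [0.99, 0.98, 0.99]
        between = [0.90, 0.89, 0.88, 0.91]
        t, p = stats.ttest_ind(within, between)
        # independent closed-form computation of the pooled-variance t
        n1, n2 = len(within), len(between)
        m1, m2 = np.mean(within), np.mean(between)
        sp2 = ((n1 - 1) * np.var(within, ddof=1)
               + (n2 - 1) * np.var(between, ddof=1)) / (n1 + n2 - 2)
        t_hand = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p_hand = 2 * stats.t.sf(abs(t_hand), n1 + n2 - 2)
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(p_hand)

    def test_within_gender_exceeds_between_on_synthetic_data(self, small_dataset):
        """Replicates correlate better within gender when a fold is planted."""
        from fbfsubnet.preprocess import collapse_duplicates

        index = small_dataset["index"]
        reads = {
            name: collapse_duplicates(s.reads)
            for name, s in small_dataset["samples"].items()
            if s.antibody == "FBF"
        }
        m = build_counts_matrix(reads, index)
        labels = {name: small_dataset["samples"][name].gender
                  for name in m.samples}
        rep = correlation_report(m, labels)
        assert np.mean(rep.within) > np.mean(rep.between)
        assert rep.p_value < 0.05
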