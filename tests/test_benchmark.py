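"""Labeling rules, metrics against brute-force oracles, region construction."""

import numpy as np
import pandas as pd
import pytest

from squigmeth import benchmark as bm


class TestLabelSites:
    def test_per_read_positive(self):
        cov = [[12, 15, 30]]
        assert bm.label_sites(cov, [[0.95, 0.92, 0.99]], "per_read")[0] == 1

    def test_unanimity_required(self):
        cov = [[12, 15, 30]]
        assert bm.label_sites(cov, [[0.95, 0.85, 0.99]], "per_read")[0] == bm.EXCLUDED

    def test_coverage_floor(self):
        cov = [[9, 15, 30]]
        assert bm.label_sites(cov, [[0.95, 0.92, 0.99]], "per_read")[0] == bm.EXCLUDED

    def test_per_site_mode_is_looser(self):
        cov = [[12, 15, 30]]
        freq = [[0.85, 0.82, 0.99]]
        assert bm.label_sites(cov, freq, "per_read")[0] == bm.EXCLUDED
        assert bm.label_sites(cov, freq, "per_site")[0] == 1

    def test_relaxing_threshold_never_removes_positives(self, rng):
        cov = rng.integers(5, 40, size=(300, 3))
        freq = rng.random((300, 3))
        strict = bm.label_sites(cov, freq, "per_read")
        loose = bm.label_sites(cov, freq, "per_site")
        assert not ((strict == 1) & (loose != 1)).any()


def brute_force_auroc(probs, labels):
    """Exhaustive positive-negative pair counting with midrank ties."""
    pos = [p for p, y in zip(probs, labels) if y == 1]
    neg = [p for p, y in zip(probs, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestPerReadMetrics:
    def test_perfect_separation(self):
        m = bm.per_read_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m["auroc"] == 1.0 and m["f1"] == 1.0

    def test_hand_dataset_pair_counting(self):
        probs = [0.9, 0.8, 0.7, 0.4, 0.3, 0.2]
        labels = [1, 1, 0, 1, 0, 0]
        m = bm.per_read_metrics(probs, labels)
        assert m["auroc"] == pytest.approx(8 / 9)
        assert m["auroc"] == pytest.approx(brute_force_auroc(probs, labels))

    def test_matches_pair_counting_with_ties(self, rng):
        probs = rng.integers(0, 10, size=200) / 10.0  # deliberate ties
        labels = rng.integers(0, 2, size=200)
        m = bm.per_read_metrics(probs, labels)
        assert m["auroc"] == pytest.approx(brute_force_auroc(probs, labels))

    def test_shuffled_labels_near_half(self, rng):
        probs = rng.random(4_000)
        labels = rng.integers(0, 2, size=4_000)
        assert bm.per_read_metrics(probs, labels)["auroc"] == pytest.approx(0.5,
                                                                            abs=0.05)

    def test_single_class_undefined(self):
        m = bm.per_read_metrics([0.9, 0.8], [1, 1])
        assert m["auroc"] is None and m["average_precision"] is None

    def test_confidence_interval_brackets_auc(self, rng):
        probs = rng.random(500)
        labels = (probs + rng.normal(0, 0.3, 500) > 0.5).astype(int)
        auc, lo, hi = bm.auroc_confidence_interval(probs, labels)
        assert lo <= auc <= hi and hi - lo < 0.2


def _site_df(rows):
    return pd.DataFrame(rows, columns=["ref_name", "pos", "strand", "total",
                                       "frequency"])


class TestPerSiteMetrics:
    def test_exact_half_is_methylated(self):
        pred = _site_df([("c", 1, "+", 20, 0.5)])
        truth = pd.DataFrame([("c", 1, "+", 1)],
                             columns=["ref_name", "pos", "strand", "label"])
        m = bm.per_site_metrics(pred, truth)
        assert m["recall"] == 1.0

    def test_low_coverage_excluded(self):
        pred = _site_df([("c", 1, "+", 9, 1.0), ("c", 2, "+", 10, 1.0)])
        truth = pd.DataFrame([("c", 1, "+", 1), ("c", 2, "+", 1)],
                             columns=["ref_name", "pos", "strand", "label"])
        assert bm.per_site_metrics(pred, truth, min_coverage=10)["n"] == 1

    def test_all_correct(self):
        pred = _site_df([("c", i, "+", 30, f) for i, f in
                         enumerate([0.9, 0.95, 0.1, 0.0])])
        truth = pd.DataFrame([("c", i, "+", l) for i, l in
                              enumerate([1, 1, 0, 0])],
                             columns=["ref_name", "pos", "strand", "label"])
        m = bm.per_site_metrics(pred, truth)
        assert m["f1"] == 1.0 and m["n"] == 4

    def test_empty_intersection(self):
        pred = _site_df([("c", 1, "+", 30, 0.9)])
        truth = pd.DataFrame([("c", 99, "+", 1)],
                             columns=["ref_name", "pos", "strand", "label"])
        assert bm.per_site_metrics(pred, truth)["n"] == 0


def brute_force_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
    return num / den


class TestCorrelation:
    def _frames(self, freqs_pred, freqs_truth, total=30):
        pred = pd.DataFrame([("c", i, "+", total, f)
                             for i, f in enumerate(freqs_pred)],
                            columns=["ref_name", "pos", "strand", "total",
                                     "frequency"])
        truth = pd.DataFrame([("c", i, "+", f) for i, f in enumerate(freqs_truth)],
                             columns=["ref_name", "pos", "strand", "frequency"])
        return pred, truth

    def test_exact_agreement(self):
        f = [0.1, 0.4, 0.8, 0.9, 0.3]
        assert bm.correlation(*self._frames(f, f))["pearson_r"] == pytest.approx(1.0)

    def test_anticorrelation(self):
        f = [0.1, 0.4, 0.8, 0.9, 0.3]
        r = bm.correlation(*self._frames(f, [1 - v for v in f]))["pearson_r"]
        assert r == pytest.approx(-1.0)

    def test_hand_table(self):
        a = [0.05, 0.5, 0.93, 0.21, 0.7]
        b = [0.1, 0.45, 0.88, 0.35, 0.64]
        r = bm.correlation(*self._frames(a, b))["pearson_r"]
        assert r == pytest.approx(brute_force_pearson(a, b))

    def test_zero_variance_undefined(self):
        r = bm.correlation(*self._frames([0.5] * 5, [0.1, 0.2, 0.3, 0.4, 0.5]))
        assert np.isnan(r["pearson_r"])


class TestIntervalOps:
    def test_subtract_against_brute_force(self, rng):
        for _ in range(50):
            a = rng.integers(0, 200, size=(4, 2))
            b = rng.integers(0, 200, size=(4, 2))
            a = np.sort(a, axis=1)
            b = np.sort(b, axis=1)
            a = a[a[:, 0] < a[:, 1]]
            b = b[b[:, 0] < b[:, 1]]
            got = bm.subtract_intervals(a, b)
            covered = set()
            for s, e in a:
                covered |= set(range(s, e))
            for s, e in b:
                covered -= set(range(s, e))
            got_set = set()
            for s, e in got:
                got_set |= set(range(s, e))
            assert got_set == covered

    def test_merge_is_disjoint_sorted(self, rng):
        iv = rng.integers(0, 100, size=(10, 2))
        iv = np.sort(iv, axis=1)
        iv = iv[iv[:, 0] < iv[:, 1]]
        m = bm.merge_intervals(iv)
        assert (m[1:, 0] > m[:-1, 1]).all() if len(m) > 1 else True


class TestRegions:
    CONTIGS = {"chr1": 50_000}

    def _regions(self, islands=None, genes=None, exons=None, tss=None):
        e = np.empty((0, 2), dtype=np.int64)
        return bm.build_regions(
            {"chr1": np.asarray(islands if islands is not None else e)},
            {"chr1": np.asarray(genes if genes is not None else e)},
            {"chr1": np.asarray(exons if exons is not None else e)},
            {"chr1": tss or []},
            self.CONTIGS)

    def test_shores_from_island(self):
        rs = self._regions(islands=[[10_000, 10_500]])
        np.testing.assert_array_equal(rs.regions["shores"]["chr1"],
                                      [[8_000, 10_000], [10_500, 12_500]])

    def test_shelves_beyond_shores(self):
        rs = self._regions(islands=[[10_000, 10_500]])
        np.testing.assert_array_equal(rs.regions["shelves"]["chr1"],
                                      [[6_000, 8_000], [12_500, 14_500]])

    def test_promoter_strand_aware(self):
        rs = self._regions(tss=[(5_000, "+"), (20_000, "-")])
        np.testing.assert_array_equal(rs.regions["promoters"]["chr1"],
                                      [[4_000, 5_000], [20_001, 21_001]])

    def test_introns_and_intergenic(self):
        rs = self._regions(genes=[[1_000, 9_000]], exons=[[1_000, 2_000],
                                                          [8_000, 9_000]],
                           tss=[(1_000, "+")])
        np.testing.assert_array_equal(rs.regions["introns"]["chr1"],
                                      [[2_000, 8_000]])
        # intergenic = genome - (gene U promoter [0,1000))
        np.testing.assert_array_equal(rs.regions["intergenic"]["chr1"],
                                      [[9_000, 50_000]])

    def test_island_shore_shelf_disjoint(self):
        rs = self._regions(islands=[[10_000, 10_500], [11_000, 11_200],
                                    [30_000, 31_000]])
        pos = np.arange(0, 50_000)
        isl = rs.membership("islands", "chr1", pos)
        sho = rs.membership("shores", "chr1", pos)
        she = rs.membership("shelves", "chr1", pos)
        assert not (isl & sho).any()
        assert not (isl & she).any()
        assert not (sho & she).any()

    def test_clipping_at_contig_bounds(self):
        rs = self._regions(islands=[[500, 900]])
        assert rs.regions["shores"]["chr1"][0][0] == 0


class TestAnnotationLoaders:
    def test_bed_loader(self, tmp_path):
        bed = tmp_path / "islands.bed"
        bed.write_text("chr1\t100\t200\nchr1\t150\t300\nchr2\t0\t50\n")
        iv = bm.read_bed_intervals(bed)
        np.testing.assert_array_equal(iv["chr1"], [[100, 300]])
        np.testing.assert_array_equal(iv["chr2"], [[0, 50]])

    def test_gtf_loader(self, tmp_path):
        gtf = tmp_path / "ann.gtf"
        gtf.write_text(
            'chr1\tsrc\tgene\t1001\t5000\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tsrc\texon\t1001\t2000\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tsrc\tgene\t8001\t9000\t.\t-\t.\tgene_id "g2";\n')
        genes, exons, tss = bm.read_gene_annotation(gtf)
        np.testing.assert_array_equal(genes["chr1"], [[1_000, 5_000],
                                                      [8_000, 9_000]])
        np.testing.assert_array_equal(exons["chr1"], [[1_000, 2_000]])
        assert tss["chr1"] == [(1_000, "+"), (8_999, "-")]


class TestStratify:
    def _sites(self):
        return pd.DataFrame({"ref_name": "chr1",
                             "pos": [10_100, 10_200, 40_000],
                             "frequency": [0.9, 0.8, 0.1]})

    def _metric(self, df):
        return {"mean_freq": float(df["frequency"].mean())}

    def test_island_row_matches_subset(self):
        rs = TestRegions()._regions(islands=[[10_000, 10_500]])
        out = bm.stratify(self._sites(), rs, self._metric)
        island_row = out[out.region == "islands"].iloc[0]
        assert island_row["n_sites"] == 2
        assert island_row["mean_freq"] == pytest.approx(0.85)

    def test_empty_region_reported_empty(self):
        rs = TestRegions()._regions(islands=[[10_000, 10_500]])
        out = bm.stratify(self._sites(), rs, self._metric)
        shelf_row = out[out.region == "shelves"].iloc[0]
        assert shelf_row["n_sites"] == 0
        assert "mean_freq" not in shelf_row or pd.isna(shelf_row["mean_freq"])

    def test_overlapping_labels_count_twice(self):
        rs = TestRegions()._regions(islands=[[10_000, 10_500]],
                                    tss=[(10_300, "+")])
        out = bm.stratify(self._sites(), rs, self._metric)
        n_by_region = dict(zip(out.region, out.n_sites))
        # 10_100 and 10_200 are in the island AND the promoter upstream of
        # the TSS at 10_300
        assert n_by_region["islands"] == 2
        assert n_by_region["promoters"] == 2
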