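"""Activity-score primitives: BED parsing, promoter windows, site
assignment, and overlap fractions checked against a per-basepair oracle."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import velogrn as vg
from velogrn.intervals import GenomicInterval, PeakSet

from conftest import brute_force_coverage


class TestReadBed:
    def test_parses_bed3_convention(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr2\t0\t50\n")
        peaks = vg.read_bed(p)
        assert [(i.chrom, i.start, i.end, i.strand) for i in peaks.intervals] == [
            ("chr1", 100, 200, "."),
            ("chr2", 0, 50, "."),
        ]

    def test_empty_file_gives_empty_peakset(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(vg.read_bed(p)) == 0

    @pytest.mark.parametrize(
        "line", ["chr1\t200\t100", "chr1\t100", "chr1\tx\t200"]
    )
    def test_malformed_line_names_line_number(self, line):
        with pytest.raises(ValueError, match="line 2"):
            vg.read_bed(io.StringIO("chr1\t1\t2\n" + line + "\n"))

    def test_bed6_strand_parsed(self, tmp_path):
        p = tmp_path / "b.bed"
        p.write_text("chr1\t10\t20\tsite1\t0\t-\n")
        iv = vg.read_bed(p, dialect="6-column").intervals[0]
        assert iv.strand == "-" and iv.name == "site1"


class TestPromoterWindow:
    def test_default_window_is_3kb_each_side(self):
        g = vg.GeneAnnotation("g", "chr1", "+", 10_000)
        w = vg.promoter_window(g)
        assert (w.start, w.end) == (7_000, 13_000)

    def test_clamped_at_origin(self):
        g = vg.GeneAnnotation("g", "chr1", "+", 1_000)
        w = vg.promoter_window(g)
        assert (w.start, w.end) == (0, 4_000)

    def test_minus_strand_swaps_sides(self):
        g = vg.GeneAnnotation("g", "chr1", "-", 10_000)
        w = vg.promoter_window(g, upstream=2_000, downstream=500)
        assert (w.start, w.end) == (9_500, 12_000)


class TestAssignment:
    def test_site_in_promoter_is_assigned(self):
        genes = [vg.GeneAnnotation("g1", "chr1", "+", 10_000)]
        sites = {"tfA": PeakSet([GenomicInterval("chr1", 7_100, 7_200)])}
        cat = vg.assign_sites_to_promoters(sites, genes)
        assert len(cat.sites[("tfA", "g1")]) == 1

    def test_site_outside_promoter_dropped(self):
        genes = [vg.GeneAnnotation("g1", "chr1", "+", 10_000)]
        sites = {"tfA": PeakSet([GenomicInterval("chr1", 20_000, 20_100)])}
        cat = vg.assign_sites_to_promoters(sites, genes)
        assert ("tfA", "g1") not in cat.sites

    def test_overlapping_two_promoters_goes_to_nearest_tss(self):
        # promoters [7000,13000) and [9000,15000); site midpoint 9950
        genes = [
            vg.GeneAnnotation("far", "chr1", "+", 10_000 + 5_000),
            vg.GeneAnnotation("near", "chr1", "+", 10_000),
        ]
        sites = {"tfA": PeakSet([GenomicInterval("chr1", 9_900, 10_000)])}
        cat = vg.assign_sites_to_promoters(sites, genes)
        assert ("tfA", "near") in cat.sites
        assert ("tfA", "far") not in cat.sites

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            vg.assign_sites_to_promoters({}, [])


class TestOverlapFraction:
    def test_half_overlap(self):
        site = GenomicInterval("chr1", 100, 200)
        peaks = PeakSet([GenomicInterval("chr1", 150, 250)]).merge()
        assert vg.site_overlap_fraction(site, peaks) == 0.5

    def test_no_overlap_and_full_coverage(self):
        site = GenomicInterval("chr1", 100, 200)
        assert vg.site_overlap_fraction(site, PeakSet([]).merge()) == 0.0
        full = PeakSet([GenomicInterval("chr1", 0, 1_000)]).merge()
        assert vg.site_overlap_fraction(site, full) == 1.0

    def test_unmerged_peaks_rejected(self):
        site = GenomicInterval("chr1", 100, 200)
        raw = PeakSet([GenomicInterval("chr1", 100, 160),
                       GenomicInterval("chr1", 150, 200)])
        with pytest.raises(ValueError, match="normalized"):
            vg.site_overlap_fraction(site, raw)

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_per_basepair_oracle(self, data):
        """Random small genomes: merged-interval arithmetic must agree
        exactly with counting covered basepairs one by one."""
        n = data.draw(st.integers(0, 12))
        intervals = []
        for _ in range(n):
            s = data.draw(st.integers(0, 480))
            e = data.draw(st.integers(s + 1, 500))
            intervals.append(GenomicInterval("chr1", s, e))
        s = data.draw(st.integers(0, 450))
        e = data.draw(st.integers(s + 1, min(s + 60, 500)))
        site = GenomicInterval("chr1", s, e)
        got = vg.site_overlap_fraction(site, PeakSet(intervals).merge())
        assert got == pytest.approx(brute_force_coverage(site, intervals))

    def test_strand_symmetry_under_coordinate_mirror(self):
        """Mirroring all coordinates around a point leaves S unchanged."""
        rng = np.random.default_rng(5)
        m = 100_000
        for _ in range(20):
            s = int(rng.integers(0, 9_000))
            site = GenomicInterval("chr1", s, s + int(rng.integers(1, 500)))
            ivs = []
            for _ in range(8):
                a = int(rng.integers(0, 9_500))
                ivs.append(GenomicInterval("chr1", a, a + int(rng.integers(1, 400))))
            fwd = vg.site_overlap_fraction(site, PeakSet(ivs).merge())
            mirror_site = GenomicInterval("chr1", m - site.end, m - site.start, "-")
            mirror = [GenomicInterval("chr1", m - iv.end, m - iv.start, "-")
                      for iv in ivs]
            rev = vg.site_overlap_fraction(mirror_site, PeakSet(mirror).merge())
            assert fwd == pytest.approx(rev)


class TestMerge:
    def test_merge_idempotent(self, rng):
        ivs = []
        for _ in range(30):
            s = int(rng.integers(0, 900))
            ivs.append(GenomicInterval("chr1", s, s + int(rng.integers(1, 120))))
        once = PeakSet(ivs).merge()
        twice = once.merge()
        assert [(i.start, i.end) for i in once.intervals] == [
            (i.start, i.end) for i in twice.intervals
        ]


class TestActivity:
    def _catalog_and_peaks(self):
        # two sites with S = 0.5 and 1.0
        cat = vg.BindingSiteCatalog({
            ("tfA", "g1"): [GenomicInterval("chr1", 100, 200),
                            GenomicInterval("chr1", 300, 400)],
        })
        peaks = PeakSet([GenomicInterval("chr1", 150, 250),
                         GenomicInterval("chr1", 290, 410)]).merge()
        return cat, peaks

    def test_sum_and_mean_from_known_fractions(self):
        cat, peaks = self._catalog_and_peaks()
        am = vg.compute_activity(cat, peaks)
        assert am.a_sum[0, 0] == pytest.approx(1.5)
        assert am.a_mean[0, 0] == pytest.approx(0.75)

    def test_absent_pairs_are_zero(self):
        cat = vg.BindingSiteCatalog(
            {("tfA", "g1"): [GenomicInterval("chr1", 100, 200)]},
            tf_ids=["tfA", "tfB"], gene_ids=["g1", "g2"],
        )
        am = vg.compute_activity(cat, PeakSet([]).merge())
        assert am.a_sum[1, 1] == 0.0 and am.a_mean[0, 1] == 0.0

    def test_sum_equals_m_times_mean(self, small_truth, small_dataset):
        _, _, peaks, sites, genes = small_dataset
        cat = vg.assign_sites_to_promoters(sites, genes)
        am = vg.compute_activity(cat, peaks.merge())
        for (tf, g), sl in cat.sites.items():
            i, j = cat.tf_ids.index(tf), cat.gene_ids.index(g)
            assert am.a_sum[i, j] == pytest.approx(len(sl) * am.a_mean[i, j])
        assert (am.a_mean <= 1 + 1e-12).all()

    def test_activity_unchanged_by_remerging(self, small_dataset):
        _, _, peaks, sites, genes = small_dataset
        cat = vg.assign_sites_to_promoters(sites, genes)
        once = vg.compute_activity(cat, peaks.merge())
        again = vg.compute_activity(cat, peaks.merge().merge())
        np.testing.assert_array_equal(once.a_sum, again.a_sum)


class TestPerCell:
    def test_single_owner_cell_reproduces_tissue_mode(self, small_dataset):
        _, _, peaks, sites, genes = small_dataset
        cat = vg.assign_sites_to_promoters(sites, genes)
        tissue = vg.compute_activity(cat, peaks.merge())
        owned = PeakSet(
            peaks.intervals,
            cell_assignment={"c0": list(range(len(peaks)))},
        )
        per_cell = vg.compute_activity_per_cell(cat, owned)
        s, m = per_cell.per_cell["c0"]
        np.testing.assert_array_equal(s, tissue.a_sum)
        np.testing.assert_array_equal(m, tissue.a_mean)

    def test_cell_without_peaks_scores_zero(self, small_dataset):
        _, _, peaks, sites, genes = small_dataset
        cat = vg.assign_sites_to_promoters(sites, genes)
        owned = PeakSet(peaks.intervals, cell_assignment={"c0": []})
        s, m = vg.compute_activity_per_cell(cat, owned).per_cell["c0"]
        assert not s.any() and not m.any()

    def test_unknown_peak_index_rejected(self, small_dataset):
        _, _, peaks, _, _ = small_dataset
        with pytest.raises(ValueError, match="unknown peak"):
            PeakSet(peaks.intervals, cell_assignment={"c0": [len(peaks) + 3]})

    def test_partitioned_cells_agree_with_per_bp_oracle(self):
        site = GenomicInterval("chr1", 100, 300)
        cat = vg.BindingSiteCatalog({("tfA", "g1"): [site]})
        ivs = [GenomicInterval("chr1", 80, 150),
               GenomicInterval("chr1", 200, 260),
               GenomicInterval("chr1", 280, 400)]
        owned = PeakSet(ivs, cell_assignment={"c1": [0, 1], "c2": [2]})
        res = vg.compute_activity_per_cell(cat, owned)
        for cell, idx in (("c1", [0, 1]), ("c2", [2])):
            expected = brute_force_coverage(site, [ivs[i] for i in idx])
            assert res.per_cell[cell][0][0, 0] == pytest.approx(expected)


class TestScaling:
    def test_log2_values(self):
        am = vg.ActivityMatrices(
            np.array([[0.0, 1.0, 1.5]]), np.array([[0.0, 1.0, 0.75]]),
            ["tfA"], ["g1", "g2", "g3"],
        )
        scaled = vg.scale_activity(am)
        np.testing.assert_allclose(
            scaled.a_sum[0], [0.0, 1.0, np.log2(2.5)]
        )
        assert scaled.scaled

    def test_double_scaling_rejected(self):
        am = vg.ActivityMatrices(np.zeros((1, 1)), np.zeros((1, 1)), ["t"], ["g"])
        with pytest.raises(ValueError):
            vg.scale_activity(vg.scale_activity(am))
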