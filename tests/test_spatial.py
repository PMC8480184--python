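import numpy as np
import pytest

from tomoevo import spatial
from tomoevo.io_formats import MarkerConfig, RegionSpec, SectionCounts, ValidationError
from tomoevo.spatial import SegmentationError

from conftest import make_zprofile, random_section_counts


class TestNormalizeAndZscore:
    def test_hand_computed_z(self):
        # equal section totals, one gene with normalized values (1,2,3)/6
        counts = np.array([[1, 2, 3], [5, 4, 3]])
        zp = spatial.normalize_and_zscore(SectionCounts("w", ["a", "b"], list("xyz"), counts))
        np.testing.assert_allclose(zp.z[0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_constant_gene_undefined(self):
        counts = np.array([[0, 0, 0], [1, 2, 3], [1, 1, 1]])
        zp = spatial.normalize_and_zscore(
            SectionCounts("w", ["a", "b", "c"], list("xyz"), counts))
        assert np.isnan(zp.z[0]).all()  # all-zero gene: constant normalized row
        assert not np.isnan(zp.z[1]).any()
        assert not np.isnan(zp.z[2]).any()  # constant counts but varying totals

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        zp = spatial.normalize_and_zscore(random_section_counts(rng))
        np.testing.assert_allclose(zp.normalized.sum(axis=0), 1.0, atol=1e-9)

    def test_z_rows_standardized(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            zp = spatial.normalize_and_zscore(random_section_counts(rng))
            defined = ~np.isnan(zp.z).any(axis=1)
            assert abs(np.nanmean(zp.z[defined], axis=1)).max() < 1e-9
            assert abs(np.nanstd(zp.z[defined], axis=1, ddof=1) - 1).max() < 1e-9

    def test_zero_total_sections_dropped(self):
        counts = np.array([[1, 0, 2], [3, 0, 4]])
        with pytest.warns(UserWarning, match="zero-total"):
            zp = spatial.normalize_and_zscore(SectionCounts("w", ["a", "b"], list("xyz"), counts))
        assert zp.section_ids == ["x", "z"]

    def test_all_zero_error(self):
        with pytest.raises(ValidationError):
            spatial.normalize_and_zscore(
                SectionCounts("w", ["a"], ["x", "y"], np.zeros((1, 2), dtype=int)))


class TestDetectMarkerPeaks:
    def test_two_runs(self):
        zp = make_zprofile({"m": [-1, -1, 2, 2, -1, -1, 3, -1]})
        peaks = spatial.detect_marker_peaks(zp, ["m"], smooth_window=1)
        assert peaks == [(2, 3, 2), (6, 6, 6)]

    def test_all_negative_empty(self):
        zp = make_zprofile({"m": [-1.0] * 6})
        assert spatial.detect_marker_peaks(zp, ["m"], smooth_window=1) == []

    def test_single_section_peak(self):
        zp = make_zprofile({"m": [-1, 2, -1]})
        assert spatial.detect_marker_peaks(zp, ["m"], smooth_window=1) == [(1, 1, 1)]

    def test_missing_marker_skipped_with_warning(self):
        zp = make_zprofile({"m": [-1, 2, -1]})
        with pytest.warns(UserWarning, match="absent"):
            peaks = spatial.detect_marker_peaks(zp, ["m", "ghost"], smooth_window=1)
        assert peaks == [(1, 1, 1)]

    def test_peak_tie_goes_anterior(self):
        zp = make_zprofile({"m": [-1, 2, 2, -1]})
        assert spatial.detect_marker_peaks(zp, ["m"], smooth_window=1) == [(1, 2, 1)]


def _two_region_config():
    return MarkerConfig([
        RegionSpec("A", markers=("mA",), peak=1),
        RegionSpec("B", markers=("mB",), peak=1),
    ])


class TestSegmentRegions:
    def test_midpoint_rule_tie_to_anterior(self):
        # peaks {3,4} and {7} (1-based) in 8 sections -> A = 1-5, B = 6-8
        zp = make_zprofile({
            "mA": [-1, -1, 2, 2, -1, -1, -1, -1],
            "mB": [-1, -1, -1, -1, -1, -1, 3, -1],
        })
        ra = spatial.segment_regions(zp, _two_region_config(), smooth_window=1)
        assert ra.region_of == ["A"] * 5 + ["B"] * 3

    def test_single_region_takes_everything(self):
        zp = make_zprofile({"m": [-1, 2, -1, -1]})
        cfg = MarkerConfig([RegionSpec("only", markers=("m",), peak=1)])
        ra = spatial.segment_regions(zp, cfg, smooth_window=1)
        assert ra.region_of == ["only"] * 4

    def test_out_of_order_peaks_error(self):
        zp = make_zprofile({
            "mA": [-1, -1, -1, -1, -1, -1, 3, -1],
            "mB": [-1, -1, 2, 2, -1, -1, -1, -1],
        })
        with pytest.raises(SegmentationError, match="order"):
            spatial.segment_regions(zp, _two_region_config(), smooth_window=1)

    def test_missing_peak_ordinal_error(self):
        zp = make_zprofile({"m": [-1, 2, -1, -1]})
        cfg = MarkerConfig([RegionSpec("A", markers=("m",), peak=2)])
        with pytest.raises(SegmentationError, match="peak #2"):
            spatial.segment_regions(zp, cfg, smooth_window=1)

    def test_indirect_region_between_anchors(self):
        # two-peak marker seeds A (peak 1) and C (peak 2); B takes the middle
        zp = make_zprofile({"m": [2, 2, -1, -1, -1, 2, 2, -1]})
        cfg = MarkerConfig([
            RegionSpec("A", markers=("m",), peak=1),
            RegionSpec("B", between=("A", "C")),
            RegionSpec("C", markers=("m",), peak=2),
        ])
        ra = spatial.segment_regions(zp, cfg, smooth_window=1)
        assert ra.region_of == ["A", "A", "B", "B", "B", "C", "C", "C"]


class TestPoolRegions:
    def _profiles(self, counts_list, region_of):
        zps = [spatial.normalize_and_zscore(sc) for sc in counts_list]
        ras = [spatial.RegionAssignment(zp.specimen_id, zp.section_ids, region_of,
                                        sorted(set(region_of), key=region_of.index))
               for zp in zps]
        return zps, ras

    def test_regional_requires_strictly_greater_than_one(self):
        # constructed so one gene's pooled median z is exactly 1.0
        z = np.array([[1.0, 1.0, -1.0, -1.0]])
        zp = spatial.ZProfile("w", ["g"], list("abcd"),
                              np.full((1, 4), 0.25), z, np.array([True]))
        ra = spatial.RegionAssignment("w", list("abcd"), ["r1", "r1", "r2", "r2"],
                                      ["r1", "r2"])
        rp = spatial.pool_regions([zp], [ra], min_specimens=1)
        assert rp.median_z[0, 0] == pytest.approx(1.0)
        assert not rp.regional[0, 0]

    def test_clearly_enriched_gene_is_regional(self):
        # enrichment must be narrower than half the axis: a gene elevated in
        # w of n sections has z capped at sqrt(n/w - 1), so use 2 of 6
        rng = np.random.default_rng(3)
        counts = rng.poisson(5, size=(20, 6)).astype(np.int64) + 1
        counts[0, :2] = 500  # strong anterior enrichment
        sc = SectionCounts("w", [f"g{i}" for i in range(20)],
                           [f"s{j}" for j in range(6)], counts)
        zps, ras = self._profiles([sc], ["r1"] * 2 + ["r2"] * 4)
        rp = spatial.pool_regions(zps, ras, min_specimens=1)
        assert rp.regional[0, 0] and not rp.regional[0, 1]

    def test_gene_absent_in_one_specimen_excluded(self):
        rng = np.random.default_rng(4)
        scs = []
        for w in range(4):
            counts = rng.poisson(5, size=(5, 4)).astype(np.int64) + 1
            if w == 2:
                counts[0] = 0  # gene g0 undetected in specimen 2
            scs.append(SectionCounts(f"w{w}", [f"g{i}" for i in range(5)],
                                     [f"s{j}" for j in range(4)], counts))
        zps, ras = self._profiles(scs, ["r1", "r1", "r2", "r2"])
        rp = spatial.pool_regions(zps, ras, min_specimens=4)
        assert "g0" not in rp.gene_ids
        rp3 = spatial.pool_regions(zps, ras, min_specimens=3)
        assert "g0" in rp3.gene_ids

    def test_library_size_invariance(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(8, size=(15, 6)).astype(np.int64) + 1
        scaled = counts.copy()
        scaled[:, 2] *= 7  # one section sequenced 7x deeper
        region_of = ["r1"] * 3 + ["r2"] * 3
        out = []
        for mat in (counts, scaled):
            sc = SectionCounts("w", [f"g{i}" for i in range(15)],
                               [f"s{j}" for j in range(6)], mat)
            zps, ras = self._profiles([sc], region_of)
            out.append(spatial.pool_regions(zps, ras, min_specimens=1))
        np.testing.assert_array_equal(out[0].regional, out[1].regional)
        np.testing.assert_allclose(out[0].median_z, out[1].median_z, atol=1e-9)


class TestClustering:
    def test_identical_sections_merge_at_zero(self):
        z = np.array([[1.0, 1.0, -1.0], [-1.0, -1.0, 2.0], [0.5, 0.5, -0.5]])
        zp = spatial.ZProfile("w", ["a", "b", "c"], ["s1", "s2", "s3"],
                              np.full((3, 3), 1 / 3), z, np.ones(3, bool))
        Z, labels = spatial.cluster_sections([zp])
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(labels) == {"w|s1", "w|s2", "w|s3"}

    def test_inverted_profiles_distance_two(self):
        z = np.array([[1.0, -1.0], [-2.0, 2.0], [0.5, -0.5]])
        zp = spatial.ZProfile("w", ["a", "b", "c"], ["s1", "s2"],
                              np.full((3, 2), 0.5), z, np.ones(3, bool))
        Z, _ = spatial.cluster_sections([zp])
        assert Z[0, 2] == pytest.approx(2.0, abs=1e-9)

    def test_planted_states_cluster_first(self):
        rng = np.random.default_rng(6)
        state1 = rng.normal(0, 1, 50)
        state2 = rng.normal(0, 1, 50)
        z = np.column_stack([state1 + rng.normal(0, .1, 50),
                             state1 + rng.normal(0, .1, 50),
                             state2 + rng.normal(0, .1, 50),
                             state2 + rng.normal(0, .1, 50)])
        zp = spatial.ZProfile("w", [f"g{i}" for i in range(50)],
                              ["s1", "s2", "s3", "s4"],
                              np.full_like(z, 0.25), z, np.ones(50, bool))
        Z, labels = spatial.cluster_sections([zp])
        first_merges = {frozenset({int(Z[i, 0]), int(Z[i, 1])}) for i in range(2)}
        assert first_merges == {frozenset({0, 1}), frozenset({2, 3})}

    def test_newick_export_is_parseable(self):
        from io import StringIO
        from Bio import Phylo
        z = np.array([[1.0, 1.0, -1.0], [-1.0, 0.0, 2.0], [0.5, -0.5, -0.3]])
        zp = spatial.ZProfile("w", ["a", "b", "c"], ["s1", "s2", "s3"],
                              np.full((3, 3), 1 / 3), z, np.ones(3, bool))
        Z, labels = spatial.cluster_sections([zp])
        tree = Phylo.read(StringIO(spatial.linkage_to_newick(Z, labels)), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(labels)


class TestClusterRegionsByOrthologs:
    def _profile(self, genes, regions, median_z, regional):
        n, m = len(genes), len(regions)
        return spatial.RegionProfile(genes, regions, np.asarray(median_z, float),
                                     np.full((n, m), 0.1),
                                     np.ones((n, m), bool), np.asarray(regional, bool))

    def test_conserved_regions_are_mutual_nearest(self):
        rng = np.random.default_rng(9)
        base = rng.normal(0, 1, size=(30, 3))
        orth = type("O", (), {"pairs": [(f"a{i}", f"b{i}") for i in range(30)]})()
        rp_a = self._profile([f"a{i}" for i in range(30)], ["r1", "r2", "r3"],
                             base, np.ones((30, 3)))
        rp_b = self._profile([f"b{i}" for i in range(30)], ["r1", "r2", "r3"],
                             base + rng.normal(0, .05, base.shape), np.ones((30, 3)))
        Z, labels = spatial.cluster_regions_by_orthologs(rp_a, rp_b, orth)
        # the first three merges each join a region with its cross-species twin
        for i in range(3):
            left, right = int(Z[i, 0]), int(Z[i, 1])
            assert left < 6 and right < 6
            assert labels[left].split("|")[1] == labels[right].split("|")[1]

    def test_no_qualifying_pairs_error(self):
        orth = type("O", (), {"pairs": [("a0", "b0")]})()
        rp_a = self._profile(["a0"], ["r1"], [[0.0]], [[False]])
        rp_b = self._profile(["b0"], ["r1"], [[0.0]], [[False]])
        with pytest.raises(ValidationError):
            spatial.cluster_regions_by_orthologs(rp_a, rp_b, orth)
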