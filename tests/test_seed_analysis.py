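from collections import deque

import numpy as np
import pytest

from isfc import synthetic_data as sd
from isfc.seed_analysis import (
    SeedDef,
    label_components,
    seed_correlation_map,
    summarize_clusters,
    threshold_and_extent_filter,
)
from isfc.volume import AnimalVolume


def flood_fill_labels(binary, connectivity):
    """Independent BFS flood-fill oracle for connected-component labeling."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    binary = np.asarray(binary, dtype=bool)
    labels = np.zeros(binary.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(binary)):
        if labels[start]:
            continue
        current += 1
        queue = deque([start])
        labels[start] = current
        while queue:
            i, j, k = queue.popleft()
            for di, dj, dk in offsets:
                ni, nj, nk = i + di, j + dj, k + dk
                if (
                    0 <= ni < binary.shape[0]
                    and 0 <= nj < binary.shape[1]
                    and 0 <= nk < binary.shape[2]
                    and binary[ni, nj, nk]
                    and not labels[ni, nj, nk]
                ):
                    labels[ni, nj, nk] = current
                    queue.append((ni, nj, nk))
    return labels, current


def _volumes_with_voxel_equal_to_seed(n=8, seed=0):
    rng = np.random.default_rng(seed)
    shape = (8, 8, 8)
    vols = []
    seed_mask = np.zeros(shape, dtype=bool)
    seed_mask[1:3, 1:3, 1:3] = True
    for i in range(n):
        data = 1.0 + 0.2 * rng.standard_normal(shape)
        data[seed_mask] = 1.0 + 0.3 * rng.standard_normal()
        # voxel (6,6,6) copies the seed mean exactly
        data[6, 6, 6] = data[seed_mask].mean()
        np.clip(data, 0, None, out=data)
        vols.append(AnimalVolume(animal_id=f"a{i}", group="g", data=data))
    return vols, seed_mask


class TestSeedDef:
    def test_empty_voxel_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SeedDef("s", np.zeros((3, 3, 3), dtype=bool))

    def test_box_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            SeedDef.from_box("s", (4, 4, 4), (0, 0, 0), (5, 2, 2))


class TestSeedCorrelationMap:
    def test_voxel_identical_to_seed_r_one(self):
        vols, seed_mask = _volumes_with_voxel_equal_to_seed()
        smap = seed_correlation_map(vols, SeedDef("s", seed_mask))
        assert smap.r[6, 6, 6] == pytest.approx(1.0)

    def test_constant_voxel_flagged_undefined(self):
        vols, seed_mask = _volumes_with_voxel_equal_to_seed()
        for v in vols:
            v.data[0, 0, 0] = 5.0
        smap = seed_correlation_map(vols, SeedDef("s", seed_mask))
        assert np.isnan(smap.r[0, 0, 0])

    def test_one_tailed_p_volumes_complementary(self):
        vols, seed_mask = _volumes_with_voxel_equal_to_seed()
        smap = seed_correlation_map(vols, SeedDef("s", seed_mask))
        ok = ~np.isnan(smap.r)
        assert np.allclose(smap.p_pos[ok] + smap.p_neg[ok], 1.0)

    def test_mixed_groups_rejected(self):
        vols, seed_mask = _volumes_with_voxel_equal_to_seed()
        vols[0].group = "other"
        with pytest.raises(ValueError, match="group"):
            seed_correlation_map(vols, SeedDef("s", seed_mask))

    def test_too_few_animals_rejected(self):
        vols, seed_mask = _volumes_with_voxel_equal_to_seed(n=3)
        with pytest.raises(ValueError, match="at least 4"):
            seed_correlation_map(vols, SeedDef("s", seed_mask))

    def test_planted_region_mostly_significant(self):
        # generator coupling 0.9, n=12, noise 0.1: >= 80% of coupled-region
        # voxels significant at one-tailed P < 0.05 (averaged over 5 reps)
        fractions = []
        for rep in range(5):
            cohort = sd.make_seed_cohort(n=12, seed=100 + rep)
            smap = seed_correlation_map(
                cohort["volumes"], SeedDef("s", cohort["seed_mask"])
            )
            sig = smap.p_pos < 0.05
            fractions.append(sig[cohort["region_pos"]].mean())
        assert np.mean(fractions) >= 0.80

    def test_null_voxels_exceedance_near_alpha(self):
        rng = np.random.default_rng(42)
        shape = (12, 12, 12)
        seed_mask = np.zeros(shape, dtype=bool)
        seed_mask[0:2, 0:2, 0:2] = True
        vols = []
        for i in range(12):
            data = 1.0 + 0.2 * rng.standard_normal(shape)
            vols.append(AnimalVolume(animal_id=f"a{i}", group="g", data=np.clip(data, 0, None)))
        smap = seed_correlation_map(vols, SeedDef("s", seed_mask))
        outside = ~seed_mask
        rate = (smap.p_pos[outside] < 0.05).mean()
        assert 0.02 < rate < 0.09  # ~alpha, loose Monte-Carlo bounds


class TestExtentFilter:
    @staticmethod
    def _toy_map_with_components(sizes=(99, 100, 101)):
        shape = (110, 9, 9)
        p_pos = np.ones(shape)
        for offset, size in zip((0, 3, 6), sizes):
            p_pos[:size, offset, 4] = 0.001  # straight runs, mutually non-adjacent
        r = 1.0 - p_pos
        return StatMapStub(shape, p_pos, r)

    def test_extent_threshold_99_100_101(self):
        smap = self._toy_map_with_components()
        out = threshold_and_extent_filter(smap, alpha=0.05, k=100, connectivity=18)
        assert len(out.clusters) == 2
        assert min(c["size"] for c in out.clusters) == 100

    def test_empty_suprathreshold_set(self):
        shape = (6, 6, 6)
        smap = StatMapStub(shape, np.ones(shape), np.zeros(shape))
        out = threshold_and_extent_filter(smap, alpha=0.05, k=10)
        assert out.clusters == []
        assert not out.cluster_labels.any()

    def test_k_below_one_rejected(self):
        shape = (4, 4, 4)
        smap = StatMapStub(shape, np.ones(shape), np.zeros(shape))
        with pytest.raises(ValueError):
            threshold_and_extent_filter(smap, k=0)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_labeling_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(connectivity)
        for _ in range(20):
            binary = rng.random((14, 14, 14)) < 0.2
            labels, count = label_components(binary, connectivity)
            oracle_labels, oracle_count = flood_fill_labels(binary, connectivity)
            assert count == oracle_count
            # same partition up to label permutation
            for lab in range(1, count + 1):
                component = labels == lab
                oracle_ids = np.unique(oracle_labels[component])
                assert len(oracle_ids) == 1

    def test_positive_negative_clusters_disjoint(self):
        cohort = sd.make_seed_cohort(n=12, seed=0)
        smap = seed_correlation_map(cohort["volumes"], SeedDef("s", cohort["seed_mask"]))
        out = threshold_and_extent_filter(smap, alpha=0.05, k=100)
        assert not ((out.cluster_labels > 0) & (out.cluster_labels < 0)).any()
        signs = {c["sign"] for c in out.clusters}
        assert signs <= {1, -1}

    def test_extent_is_a_true_minimum(self):
        # breaking a surviving cluster below k removes it on re-filtering
        smap = self._toy_map_with_components(sizes=(120, 0, 0))
        out = threshold_and_extent_filter(smap, alpha=0.05, k=100, connectivity=18)
        assert len(out.clusters) == 1
        broken = smap.p_pos.copy()
        broken[50:71, 0, 4] = 1.0  # split 120 into 50 + 49
        out2 = threshold_and_extent_filter(
            StatMapStub(smap.r.shape, broken, 1.0 - broken), alpha=0.05, k=100
        )
        assert len(out2.clusters) == 0

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError):
            label_components(np.zeros((2, 2, 2), dtype=bool), 10)


def StatMapStub(shape, p_pos, r, p_neg=None):
    from isfc.seed_analysis import StatMap

    r = np.asarray(r, dtype=float)
    df = 10
    t = np.clip(r, -0.999, 0.999)
    if p_neg is None:
        p_neg = np.ones(shape)  # no negative effects unless given
    return StatMap(
        r=r,
        t=t * np.sqrt(df / (1 - t**2)),
        p_pos=np.asarray(p_pos, dtype=float),
        p_neg=np.asarray(p_neg, dtype=float),
        n=12,
        group="g",
        seed_name="s",
    )


class TestSummarizeClusters:
    def _thresholded_single_cluster(self):
        shape = (20, 9, 9)
        p_pos = np.ones(shape)
        p_pos[2:12, 4, 4] = 0.001
        smap = StatMapStub(shape, p_pos, 1.0 - p_pos)
        return threshold_and_extent_filter(smap, alpha=0.05, k=5, connectivity=6)

    def test_cluster_inside_one_region(self):
        out = self._thresholded_single_cluster()
        labels = np.zeros(out.r.shape, dtype=np.int32)
        labels[:, :, :] = 3
        table = summarize_clusters(out, labels, {3: "regionA"})
        assert len(table) == 1
        assert table.loc[0, "region"] == "regionA"
        assert table.loc[0, "overlap_voxels"] == out.clusters[0]["size"]

    def test_cluster_straddling_two_regions_60_40(self):
        out = self._thresholded_single_cluster()  # 10-voxel cluster along axis 0
        labels = np.zeros(out.r.shape, dtype=np.int32)
        labels[:8, :, :] = 1  # first 6 cluster voxels (2..7)
        labels[8:, :, :] = 2  # remaining 4 (8..11)
        table = summarize_clusters(out, labels, {1: "sixty", 2: "forty"})
        assert list(table["overlap_voxels"]) == [6, 4]
        assert list(table["region"]) == ["sixty", "forty"]

    def test_no_clusters_empty_table_with_header(self):
        shape = (6, 6, 6)
        smap = StatMapStub(shape, np.ones(shape), np.zeros(shape))
        out = threshold_and_extent_filter(smap, alpha=0.05, k=10)
        table = summarize_clusters(out, np.zeros(shape, dtype=np.int32))
        assert table.empty
        assert "region" in table.columns and "overlap_voxels" in table.columns

    def test_misaligned_shapes_error(self):
        out = self._thresholded_single_cluster()
        with pytest.raises(ValueError, match="shape"):
            summarize_clusters(out, np.zeros((3, 3, 3), dtype=np.int32))

    def test_unthresholded_map_rejected(self):
        shape = (4, 4, 4)
        smap = StatMapStub(shape, np.ones(shape), np.zeros(shape))
        with pytest.raises(ValueError, match="threshold"):
            summarize_clusters(smap, np.zeros(shape, dtype=np.int32))


class TestEndToEndRecovery:
    def test_planted_regions_recovered_with_correct_signs(self):
        hits = 0
        for rep in range(20):
            cohort = sd.make_seed_cohort(n=12, seed=rep)
            smap = seed_correlation_map(
                cohort["volumes"],
                SeedDef("s", cohort["seed_mask"]),
                brain_mask=cohort["brain_mask"],
            )
            out = threshold_and_extent_filter(smap, alpha=0.05, k=100, connectivity=18)
            pos = out.cluster_labels > 0
            neg = out.cluster_labels < 0
            overlap_pos = (pos & cohort["region_pos"]).sum() / cohort["region_pos"].sum()
            overlap_neg = (neg & cohort["region_neg"]).sum() / cohort["region_neg"].sum()
            if len(out.clusters) == 2 and overlap_pos >= 0.8 and overlap_neg >= 0.8:
                hits += 1
        assert hits >= 16
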