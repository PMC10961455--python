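"""MEMRI voxel inference: median filtering, t-maps vs a closed form,
TFCE against its analytic integral, permutation calibration, cluster
filtering and volumetry."""

import numpy as np
import pytest
from scipy import stats as st

from rodentfc import synthetic as syn
from rodentfc import voxel_stats as vs
from rodentfc.io import Volume


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return Volume(data=np.asarray(data, float), spacing=spacing)


class TestMedianSmooth:
    def test_constant_unchanged(self):
        out = vs.median_smooth(_vol(np.full((8, 8, 8), 3.0)), 3)
        np.testing.assert_array_equal(out.data, 3.0)

    def test_spike_removed(self):
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 100.0
        out = vs.median_smooth(_vol(data), 3)
        assert out.data.max() == 0.0

    def test_checkerboard_majority(self):
        idx = np.indices((6, 6, 6)).sum(axis=0)
        data = (idx % 2).astype(float)
        out = vs.median_smooth(_vol(data), 3)
        # brute force: median over each edge-replicated 3^3 neighbourhood
        padded = np.pad(data, 1, mode="edge")
        for x in range(6):
            for y in range(3):
                for z in range(3):
                    nb = padded[x : x + 3, y : y + 3, z : z + 3]
                    assert out.data[x, y, z] == np.median(nb)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            vs.median_smooth(_vol(np.zeros((4, 4, 4))), 4)


class TestVoxelwiseT:
    def _groups(self, delta=0.0, n=12, seed=0, shape=(6, 6, 4)):
        rng = np.random.default_rng(seed)
        a = [_vol(delta + rng.standard_normal(shape)) for _ in range(n)]
        b = [_vol(rng.standard_normal(shape)) for _ in range(n)]
        return a, b

    def test_df_from_group_sizes(self):
        a, b = self._groups()
        assert vs.voxelwise_t(a, b).df == 22  # 12 + 12 - 2

    def test_matches_scipy_per_voxel(self):
        a, b = self._groups(delta=0.5, seed=1)
        tmap = vs.voxelwise_t(a, b)
        sa = np.stack([v.data for v in a])
        sb = np.stack([v.data for v in b])
        expected = st.ttest_ind(sa, sb, axis=0, equal_var=True).statistic
        np.testing.assert_allclose(tmap.values, expected, atol=1e-10)

    def test_planted_offset_closed_form(self):
        # t ~ delta / (s_p sqrt(2/12)); with unit variance the expected
        # mean t over voxels is about delta * sqrt(6)
        a, b = self._groups(delta=2.0, seed=2, shape=(12, 12, 6))
        tmap = vs.voxelwise_t(a, b)
        assert tmap.values.mean() == pytest.approx(2.0 * np.sqrt(6), rel=0.1)

    def test_equal_groups_near_zero(self):
        rng = np.random.default_rng(3)
        shared = [rng.standard_normal((5, 5, 3)) for _ in range(6)]
        a = [_vol(s) for s in shared]
        b = [_vol(s) for s in shared]
        assert np.abs(vs.voxelwise_t(a, b).values).max() == 0.0


class TestTfce:
    def test_zero_map(self):
        np.testing.assert_array_equal(vs.tfce(np.zeros((5, 5, 5))), 0.0)

    def test_cuboid_closed_form(self):
        # uniform cuboid of c voxels at height h0: every voxel gets
        # c^E * sum_{h<=h0} h^H dh -> c^0.5 h0^3/3 as dh -> 0
        vol = np.zeros((20, 20, 20))
        vol[5:10, 5:10, 5:10] = 2.0  # c = 125, h0 = 2
        enh = vs.tfce(vol, dh=2.0 / 100)
        analytic = 125**0.5 * 2.0**3 / 3
        assert enh[7, 7, 7] == pytest.approx(analytic, rel=0.02)

    def test_scaling_strictly_increases_enhancement(self):
        rng = np.random.default_rng(0)
        vol = np.clip(rng.standard_normal((10, 10, 10)), 0, None)
        e1 = vs.tfce(vol)
        e2 = vs.tfce(2.0 * vol)
        nz = e1 > 0  # voxels below the first threshold step stay 0
        assert nz.any()
        assert np.all(e2[nz] > e1[nz])

    def test_negative_values_antisymmetric(self):
        rng = np.random.default_rng(1)
        vol = rng.standard_normal((8, 8, 8))
        np.testing.assert_allclose(vs.tfce(-vol), -vs.tfce(vol), atol=1e-12)

    def test_axis_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        vol = rng.standard_normal((6, 7, 8))
        perm = (2, 0, 1)
        np.testing.assert_allclose(
            vs.tfce(np.transpose(vol, perm), dh=0.05),
            np.transpose(vs.tfce(vol, dh=0.05), perm), atol=1e-12)

    def test_riemann_convergence(self):
        rng = np.random.default_rng(3)
        from scipy import ndimage

        vol = ndimage.gaussian_filter(rng.standard_normal((12, 12, 12)), 2.0)
        vol = np.clip(vol, 0, None) * 10
        a = vs.tfce(vol, dh=vol.max() / 100)
        b = vs.tfce(vol, dh=vol.max() / 200)
        nz = a > 0.01 * a.max()
        assert np.abs(a[nz] - b[nz]).max() / a[nz].max() < 0.02

    def test_nonfinite_rejected(self):
        vol = np.zeros((4, 4, 4))
        vol[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            vs.tfce(vol)


class TestPermutationThreshold:
    def _null_groups(self, n=8, shape=(10, 10, 6), seed=0):
        rng = np.random.default_rng(seed)
        return ([_vol(rng.standard_normal(shape)) for _ in range(n)],
                [_vol(rng.standard_normal(shape)) for _ in range(n)])

    def test_determinism(self):
        a, b = self._null_groups()
        r1 = vs.permutation_threshold(a, b, n_perm=20, seed=4, pipeline="t")
        r2 = vs.permutation_threshold(a, b, n_perm=20, seed=4, pipeline="t")
        assert r1[0] == r2[0]
        np.testing.assert_array_equal(r1[1], r2[1])

    def test_threshold_monotone_in_percentile(self):
        a, b = self._null_groups(seed=1)
        ts = [vs.permutation_threshold(a, b, n_perm=20, percentile=p,
                                       seed=0, pipeline="t")[0]
              for p in (90.0, 99.0, 99.9)]
        assert ts == sorted(ts)

    def test_planted_effect_localized(self):
        rng = np.random.default_rng(5)
        shape = (12, 12, 8)
        region = np.zeros(shape, bool)
        region[3:9, 3:9, 2:6] = True
        a = [_vol(rng.standard_normal(shape) + 2.0 * region) for _ in range(10)]
        b = [_vol(rng.standard_normal(shape)) for _ in range(10)]
        thr, sig, _ = vs.permutation_threshold(a, b, n_perm=40, seed=0)
        dice = 2 * (sig & region).sum() / (sig.sum() + region.sum())
        assert dice >= 0.5

    def test_too_few_permutations_rejected(self):
        a, b = self._null_groups()
        with pytest.raises(ValueError):
            vs.permutation_threshold(a, b, n_perm=5)


class TestClusterFilter:
    def test_size_threshold(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[:8, :10, :5] = True  # 400 voxels
        assert len(vs.cluster_filter(mask, 500).table) == 0
        mask[:8, :15, :5] = True  # 600 voxels
        table = vs.cluster_filter(mask, 500).table
        assert len(table) == 1 and table["size"].iloc[0] == 600

    def test_diagonal_connectivity(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[1:3, 1:3, 1:3] = True
        mask[3:5, 3:5, 3:5] = True  # touches the first blob corner-to-corner
        assert len(vs.cluster_filter(mask, 0, connectivity=26).table) == 1
        assert len(vs.cluster_filter(mask, 0, connectivity=6).table) == 2

    def test_peak_from_value_map(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 1:5, 1:5] = True
        values = np.zeros((6, 6, 6))
        values[2, 3, 4] = 9.0
        table = vs.cluster_filter(mask, 0, value_map=values).table
        assert (table.peak_x.iloc[0], table.peak_y.iloc[0], table.peak_z.iloc[0]) == (2, 3, 4)
        assert table.peak_value.iloc[0] == 9.0


class TestRegionIntensityStats:
    def test_null_gives_no_rejections(self, small_atlas):
        atlas, _ = small_atlas
        rng = np.random.default_rng(0)
        a = [syn.simulate_memri(atlas, {}, 1.0, seed=rng) for _ in range(12)]
        b = [syn.simulate_memri(atlas, {}, 1.0, seed=rng) for _ in range(12)]
        table = vs.region_intensity_stats(a, b, atlas, alpha=0.01)
        assert table["significant"].sum() <= 1

    def test_single_region_reduces_to_mean_ttest(self):
        labels = np.ones((4, 4, 4), dtype=np.int32)
        atlas = Volume(labels, (1, 1, 1))
        rng = np.random.default_rng(1)
        a = [_vol(rng.standard_normal((4, 4, 4)) + 0.5) for _ in range(6)]
        b = [_vol(rng.standard_normal((4, 4, 4))) for _ in range(6)]
        table = vs.region_intensity_stats(a, b, atlas, alpha=0.05)
        ma = [v.data.mean() for v in a]
        mb = [v.data.mean() for v in b]
        expected = st.ttest_ind(ma, mb, equal_var=True)
        assert table["t"].iloc[0] == pytest.approx(expected.statistic)
        assert table["p"].iloc[0] == pytest.approx(expected.pvalue)


class TestVolumetry:
    def test_voxel_volume_arithmetic(self):
        labels = np.zeros((20, 10, 10), dtype=np.int32)
        labels[:10, :10, :10] = 1  # 1000 voxels
        vol = Volume(labels, (0.094, 0.094, 0.25))
        table = vs.region_volumes(vol)
        assert table.volume_mm3.iloc[0] == pytest.approx(1000 * 0.094 * 0.094 * 0.25)
        assert table.volume_mm3.iloc[0] == pytest.approx(2.2090, abs=1e-3)

    def test_partition_additivity(self, small_atlas):
        atlas, _ = small_atlas
        table = vs.region_volumes(atlas)
        voxel_mm3 = float(np.prod(atlas.spacing))
        assert table.volume_mm3.sum() == pytest.approx(
            (atlas.data > 0).sum() * voxel_mm3)

    def test_empty_label_absent(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[0, 0, 0] = 3
        table = vs.region_volumes(Volume(labels, (1, 1, 1)))
        assert set(table.region_id) == {3}

    def test_identical_tables_null(self):
        labels = np.zeros((6, 6, 6), dtype=np.int32)
        labels[:3] = 1
        labels[3:] = 2
        t = vs.region_volumes(Volume(labels, (1, 1, 1)))
        out = vs.compare_volumes([t, t], [t, t])
        assert np.allclose(out["t"], 0.0)
        assert np.allclose(out["p"], 1.0)

    def test_dilated_parcel_effect_recovered(self, tiny_cohort):
        data, _ = tiny_cohort
        from rodentfc import io as rio

        manifest = rio.load_manifest(data / "manifest.tsv")
        subjects = manifest.drop_duplicates("subject_id")
        tables = {
            r.subject_id: vs.region_volumes(rio.read_volume(data / f"labels_{r.subject_id}.nii.gz"))
            for r in subjects.itertuples()
        }
        ga = [tables[r.subject_id] for r in subjects.itertuples() if r.strain == "epileptic"]
        gb = [tables[r.subject_id] for r in subjects.itertuples() if r.strain == "control"]
        out = vs.compare_volumes(ga, gb).set_index("region_id")
        affected = {5, 6}  # parcels dilated in the epileptic group
        assert (out.loc[sorted(affected), "p"] < 0.05).all()

    def test_paired_null_p_uniform(self):
        rng = np.random.default_rng(2)
        labels = np.zeros((6, 6, 6), dtype=np.int32)
        labels[:3] = 1
        labels[3:] = 2
        base = vs.region_volumes(Volume(labels, (1, 1, 1)))
        ps = []
        for _ in range(200):
            jitter = lambda: base.assign(volume_mm3=base.volume_mm3 + rng.standard_normal(2))
            a = [jitter() for _ in range(6)]
            b = [jitter() for _ in range(6)]
            ps.append(vs.compare_volumes(a, b, paired=True)["p"].iloc[0])
        ks = st.kstest(ps, "uniform")
        assert ks.pvalue > 0.01
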