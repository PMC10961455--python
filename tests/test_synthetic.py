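"""Generator correctness: atlas geometry, covariance planting, recovery
of ground truth as the series grows, and determinism."""

import numpy as np
import pytest

from rodentfc import synthetic as syn
from rodentfc.synthetic import CommunitySpec, NoiseSpec


def _empirical_region_corr(series, atlas, table):
    labels = np.asarray(atlas.data)
    means = np.stack([
        series.data[labels == rid].mean(axis=0) for rid in table.region_id
    ])
    return np.corrcoef(means)


class TestAtlasPhantom:
    def test_mirror_symmetry_80(self):
        atlas, table = syn.make_atlas_phantom(80, (32, 32, 12))
        labels = np.asarray(atlas.data)
        flipped = labels[::-1]
        # mirroring the volume swaps each left label 2p+1 with its right
        # partner 2p+2
        swap = np.zeros(81, dtype=int)
        for p in range(40):
            swap[2 * p + 1], swap[2 * p + 2] = 2 * p + 2, 2 * p + 1
        np.testing.assert_array_equal(swap[labels], flipped)
        assert len(table) == 80
        assert (table.groupby(table.name.str[:-2]).size() == 2).all()

    def test_114_regions_all_present(self):
        atlas, table = syn.make_atlas_phantom(114, (32, 32, 12))
        present = set(np.unique(atlas.data)) - {0}
        assert present == set(range(1, 115))
        sizes = [int((atlas.data == r).sum()) for r in range(1, 115)]
        assert min(sizes) >= 27

    def test_grid_too_small(self):
        with pytest.raises(ValueError, match="slots"):
            syn.make_atlas_phantom(4, (4, 4, 4))

    def test_odd_region_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            syn.make_atlas_phantom(3, (12, 12, 6))


class TestTargetMatrix:
    def test_psd_and_strain_effect(self, atlas30, three_block_spec):
        _, table = atlas30
        spec = CommunitySpec(
            blocks=three_block_spec.blocks,
            within_block_r=0.5, between_block_r=0.1, homotopic_r=0.4,
            strain_effect=0.2,
            strain_effect_edges=[(1, 3), (1, 5), (3, 5)],
        )
        for strain in ("control", "epileptic"):
            t = syn.build_target_matrix(spec, table, strain=strain)
            assert np.linalg.eigvalsh(t).min() > -1e-8
        base = syn.build_target_matrix(spec, table, "control")
        bumped = syn.build_target_matrix(spec, table, "epileptic")
        assert bumped[0, 2] == pytest.approx(base[0, 2] + 0.2)

    def test_indefinite_spec_projected_with_warning(self, atlas30):
        _, table = atlas30
        ids = list(table.region_id)
        # wildly incompatible targets: near-unity within, high cross-block
        spec = CommunitySpec(blocks=[ids[:15], ids[15:]], within_block_r=0.99,
                             between_block_r=0.0, homotopic_r=0.99,
                             strain_effect=0.9,
                             strain_effect_edges=[(ids[0], ids[16]), (ids[1], ids[17])])
        with pytest.warns(UserWarning, match="PSD"):
            t = syn.build_target_matrix(spec, table, "epileptic")
        assert np.linalg.eigvalsh(t).min() > -1e-8


class TestSimulateBold:
    def test_noiseless_high_coupling_limit(self, small_atlas):
        atlas, table = small_atlas
        ids = list(table.region_id)
        spec = CommunitySpec(blocks=[ids[:10], ids[10:]], within_block_r=0.995,
                             between_block_r=0.0, homotopic_r=0.0)
        series, _ = syn.simulate_bold(atlas, table, spec, NoiseSpec(noise_sd=0.0),
                                      n_volumes=200, seed=0)
        emp = _empirical_region_corr(series, atlas, table)
        blocks = spec.block_labels(ids)
        same = (blocks[:, None] == blocks[None, :]) & ~np.eye(20, dtype=bool)
        assert emp[same].min() > 0.97

    def test_independent_regions_null(self, small_atlas):
        atlas, table = small_atlas
        ids = list(table.region_id)
        spec = CommunitySpec(blocks=[[r] for r in ids], within_block_r=0.5,
                             between_block_r=0.0, homotopic_r=0.0)
        series, _ = syn.simulate_bold(atlas, table, spec, NoiseSpec(noise_sd=0.0),
                                      n_volumes=900, seed=1)
        emp = _empirical_region_corr(series, atlas, table)
        off = ~np.eye(20, dtype=bool)
        # band-limited signals (0.01-0.08 Hz) carry ~2*BW*T ~ 126
        # effective samples at n=900, so the null |r| noise floor is
        # ~0.07 (Monte-Carlo: 0.0697 +- 0.0033); assert against that
        assert np.abs(emp[off]).mean() < 0.08

    def test_within_block_recovery_at_900(self, small_atlas):
        # sampling noise of r at n=900 band-limited samples keeps the
        # empirical within-block mean within +-0.08 of the 0.6 target
        atlas, table = small_atlas
        ids = list(table.region_id)
        spec = CommunitySpec(blocks=[ids[:10], ids[10:]], within_block_r=0.6,
                             between_block_r=0.0, homotopic_r=0.0)
        series, truth = syn.simulate_bold(atlas, table, spec, NoiseSpec(noise_sd=0.0),
                                          n_volumes=900, seed=2)
        emp = _empirical_region_corr(series, atlas, table)
        blocks = spec.block_labels(ids)
        same = (blocks[:, None] == blocks[None, :]) & ~np.eye(20, dtype=bool)
        assert emp[same].mean() == pytest.approx(0.6, abs=0.08)
        assert truth[same].max() == pytest.approx(0.6)

    def test_convergence_to_ground_truth(self, small_atlas):
        atlas, table = small_atlas
        ids = list(table.region_id)
        spec = CommunitySpec(blocks=[ids[:10], ids[10:]], within_block_r=0.5,
                             between_block_r=0.2, homotopic_r=0.3)
        series, truth = syn.simulate_bold(atlas, table, spec, NoiseSpec(noise_sd=0.0),
                                          n_volumes=5000, seed=3)
        emp = _empirical_region_corr(series, atlas, table)
        # effective samples ~700 at n=5000 under the 0.01-0.08 Hz band;
        # Monte-Carlo noise floor for the mean deviation is 0.030+-0.002
        assert np.abs(emp - truth).mean() < 0.04
        assert np.abs(emp - truth).max() < 0.15

    def test_band_exceeding_nyquist(self, small_atlas):
        atlas, table = small_atlas
        spec = CommunitySpec(blocks=[list(table.region_id)])
        with pytest.raises(ValueError, match="Nyquist"):
            syn.simulate_bold(atlas, table, spec, NoiseSpec(band=(0.01, 0.6)),
                              n_volumes=200, tr=1.0, seed=0)

    def test_determinism(self, small_atlas):
        atlas, table = small_atlas
        spec = CommunitySpec(blocks=[list(table.region_id)])
        a, _ = syn.simulate_bold(atlas, table, spec, NoiseSpec(), n_volumes=120, seed=9)
        b, _ = syn.simulate_bold(atlas, table, spec, NoiseSpec(), n_volumes=120, seed=9)
        np.testing.assert_array_equal(a.data, b.data)


class TestMotion:
    def test_zero_jitter_zero_trace(self):
        trace = syn.simulate_motion(100, jitter_mm=0.0, jitter_deg=0.0)
        np.testing.assert_array_equal(trace, 0.0)

    def test_jump_construction(self):
        trace = syn.simulate_motion(1800, jump_at=1000, jump_mm=0.5, seed=0)
        before = trace[:1000, 0]
        assert before.max() - before.min() < 0.2
        assert trace[1000:, 0].mean() - before.mean() == pytest.approx(0.5, abs=0.05)

    def test_determinism_and_validation(self):
        a = syn.simulate_motion(200, seed=5)
        b = syn.simulate_motion(200, seed=5)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            syn.simulate_motion(100, jump_at=100, jump_mm=0.5)
        with pytest.raises(ValueError):
            syn.simulate_motion(100, jump_mm=-1.0)


class TestMemri:
    def test_constant_when_no_offset_no_noise(self, small_atlas):
        atlas, _ = small_atlas
        vol = syn.simulate_memri(atlas, {}, noise_sd=0.0)
        assert np.unique(vol.data).size == 1

    def test_offset_raises_region_mean(self, small_atlas):
        atlas, _ = small_atlas
        vol = syn.simulate_memri(atlas, {7: 10.0}, noise_sd=0.5, seed=1)
        in7 = vol.data[atlas.data == 7].mean()
        bg = vol.data[atlas.data == 0].mean()
        assert in7 - bg == pytest.approx(10.0, abs=0.5)

    def test_unknown_region_rejected(self, small_atlas):
        atlas, _ = small_atlas
        with pytest.raises(ValueError, match="99"):
            syn.simulate_memri(atlas, {99: 1.0})


class TestCohort:
    def test_design_counts_and_determinism(self, tiny_cohort):
        data, cfg = tiny_cohort
        bolds = sorted(data.glob("bold_*.nii.gz"))
        memris = sorted(data.glob("memri_*.nii.gz"))
        # scaled design: 3/strain x 2 sessions = 12 series, 6 MEMRI volumes
        assert len(bolds) == 12
        assert len(memris) == 6
        assert (data / "manifest.tsv").exists()

    def test_full_design_yields_144_series(self, tmp_path):
        config = syn.CohortConfig(
            n_per_strain=12, sessions=(3, 4, 5, 6, 7, 8), n_regions=12,
            grid_shape=(12, 12, 6), n_volumes=100,
        )
        manifest = syn.simulate_cohort(config, seed=1, out_dir=tmp_path)
        assert len(manifest) == 144
        assert len(list(tmp_path.glob("bold_*.nii.gz"))) == 144
        assert len(list(tmp_path.glob("memri_*.nii.gz"))) == 24
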