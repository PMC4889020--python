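"""Phantom generator: shape volumes, placement, topology truth, determinism."""

import numpy as np
import pytest

from foci3d.phantom import (PhantomConfig, build_reticulum, generate_phantom,
                            make_focus_shape)
from foci3d.grids import LabelVolume
from foci3d.topology import euler_number, label_components, topology_report


class TestMakeFocusShape:
    def test_one_voxel_target_gives_one_voxel(self):
        m = make_focus_shape(512.0, complexity=1, spacing=8.0, rng_seed=0)
        assert m.sum() == 1

    def test_thousand_voxel_target_within_tolerance_and_simply_connected(self):
        m = make_focus_shape(5.12e5, complexity=1, spacing=8.0, rng_seed=1)
        assert abs(int(m.sum()) - 1000) <= 100
        assert euler_number(m) == 1
        assert label_components(m).n_components == 1

    def test_two_seeds_give_different_shapes_both_on_target(self):
        a = make_focus_shape(5.12e5, complexity=5, spacing=8.0, rng_seed=1)
        b = make_focus_shape(5.12e5, complexity=5, spacing=8.0, rng_seed=2)
        assert abs(int(a.sum()) - 1000) <= 100
        assert abs(int(b.sum()) - 1000) <= 100
        assert a.shape != b.shape or not np.array_equal(a, b)

    def test_unreachable_complexity_reduced_with_warning(self):
        with pytest.warns(UserWarning, match="complexity"):
            m = make_focus_shape(4 * 512.0, complexity=6, spacing=8.0, rng_seed=0)
        assert m.sum() >= 1

    def test_below_voxel_volume_rejected(self):
        with pytest.raises(ValueError, match="below one voxel"):
            make_focus_shape(100.0, complexity=1, spacing=8.0, rng_seed=0)

    @pytest.mark.parametrize("target_vox", [150, 500, 2000, 10000])
    def test_volume_within_ten_percent_for_large_targets(self, target_vox):
        m = make_focus_shape(target_vox * 512.0, complexity=3, spacing=8.0, rng_seed=42)
        assert abs(int(m.sum()) - target_vox) <= 0.10 * target_vox
        assert euler_number(m) == 1


class TestGeneratePhantom:
    def test_identical_config_bit_identical(self):
        cfg = PhantomConfig(shape=(40, 60, 60), focus_density=8.0,
                            focus_volume_range=(1.6e4, 2e5), seed=3)
        g1, l1, t1 = generate_phantom(cfg)
        g2, l2, t2 = generate_phantom(cfg)
        assert np.array_equal(g1.data, g2.data)
        assert np.array_equal(l1.data, l2.data)
        assert t1.n_foci == t2.n_foci

    def test_no_noise_means_exact_class_values(self):
        cfg = PhantomConfig(shape=(32, 48, 48), noise_sigma=0.0, focus_density=5.0,
                            focus_volume_range=(1.6e4, 1e5), airspace_fraction=0.1,
                            seed=2)
        gray, labels, truth = generate_phantom(cfg)
        vals = np.unique(gray.data)
        assert set(vals) <= {cfg.intensity_paraffin, cfg.intensity_tissue,
                             cfg.intensity_airspace, cfg.intensity_focus}
        # every focus voxel carries the focus intensity exactly
        assert (gray.data[labels.data > 0] == cfg.intensity_focus).all()

    def test_zero_density_means_zero_foci(self):
        cfg = PhantomConfig(shape=(24, 32, 32), focus_density=0.0, seed=1)
        _, labels, truth = generate_phantom(cfg)
        assert truth.n_foci == 0
        assert labels.data.max() == 0

    def test_discrete_truth_component_count(self, small_discrete_phantom):
        _, _, labels, truth = small_discrete_phantom
        labeling = label_components(labels.data > 0)
        assert labeling.n_components == truth.n_foci == truth.n_components_true
        assert topology_report(labeling).loops_estimate == 0

    def test_truth_volumes_match_labels_exactly(self, small_discrete_phantom):
        cfg, _, labels, truth = small_discrete_phantom
        voxvol = cfg.spacing_um ** 3
        for f in truth.foci:
            assert f.true_volume_um3 == (labels.data == f.id).sum() * voxvol
            # and the voxelization tracked the requested target within 10%
            assert abs(f.true_volume_um3 - f.target_volume_um3) \
                <= 0.10 * f.target_volume_um3 + voxvol

    def test_focus_intensity_ordering_enforced(self):
        with pytest.raises(ValueError, match="intensity_focus"):
            PhantomConfig(intensity_focus=200.0)

    def test_density_recovered_over_seeds(self):
        # mean realized foci per mm^3 within 3 SE of the configured density;
        # the expected count per phantom is kept well above 1 so the
        # at-least-one-focus floor does not bias the rate
        density = 30.0
        counts, vols = [], []
        for seed in range(20):
            cfg = PhantomConfig(shape=(64, 96, 96), focus_density=density,
                                focus_volume_range=(1.6e4, 1e5), seed=seed)
            _, _, truth = generate_phantom(cfg)
            counts.append(truth.n_foci)
            vols.append(truth.tissue_volume_mm3)
        total, tissue = np.sum(counts), np.sum(vols)
        se = np.sqrt(density * tissue)  # Poisson SE of the total count
        assert abs(total - density * tissue) <= 3 * se


class TestBuildReticulum:
    def _blob_labels(self, centers, r=3, shape=(40, 40, 40)):
        lab = np.zeros(shape, np.int32)
        zz, yy, xx = np.mgrid[:shape[0], :shape[1], :shape[2]]
        for i, c in enumerate(centers, start=1):
            lab[(zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r * r] = i
        return LabelVolume(lab, spacing_um=8.0)

    @pytest.mark.parametrize("centers, extra, chi", [
        ([(10, 10, 10), (28, 28, 28)], 0, 1),          # tree of 2: contractible
        ([(10, 10, 10), (20, 28, 15), (30, 10, 28)], 1, 0),   # one loop
        ([(8, 8, 8), (8, 30, 30), (20, 20, 20), (32, 8, 30), (32, 30, 8)], 3, -2),
    ])
    def test_component_and_euler_truth(self, centers, extra, chi):
        lv = self._blob_labels(centers)
        merged, bridges = build_reticulum(lv, n_extra_edges=extra, rng_seed=9)
        mask = merged.data > 0
        assert label_components(mask).n_components == 1
        assert euler_number(mask) == chi
        assert len(bridges) == len(centers) - 1 + extra

    def test_requires_two_foci(self):
        lv = self._blob_labels([(20, 20, 20)])
        with pytest.raises(ValueError, match="at least 2"):
            build_reticulum(lv, n_extra_edges=0, rng_seed=0)

    def test_reticulum_phantom_truth(self, small_reticulum_phantom):
        _, _, labels, truth = small_reticulum_phantom
        rep = topology_report(label_components(labels.data > 0))
        assert rep.n_components == 1 == truth.n_components_true
        assert rep.loops_estimate == truth.n_extra_edges == 1
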