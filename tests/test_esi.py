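import numpy as np
import pytest
from scipy.sparse.csgraph import shortest_path

from ezloc.errors import ParameterError
from ezloc.esi import (
    EEGEpoch,
    MSPOptions,
    PriorLibrary,
    average_reference,
    build_patch_library,
    diffusion_kernel,
    invert_msp,
    invert_with_siscom_prior,
    siscom_prior_components,
    source_to_ez_map,
)
from ezloc.imaging import Volume3D
from ezloc.siscom import Cluster, ClusterSet
from ezloc.synthetic import default_waveform, simulate_eeg


def _epoch(data, labels=None):
    labels = labels or [f"ch{i}" for i in range(data.shape[0])]
    return EEGEpoch(data, 250.0, labels)


def rings_from(src, center):
    return shortest_path(src.adjacency, method="D", unweighted=True,
                         indices=center)


class TestAverageReference:
    def test_idempotent(self, rng):
        e = average_reference(_epoch(rng.standard_normal((5, 20))))
        e2 = average_reference(e)
        np.testing.assert_allclose(e2.data, e.data, atol=1e-12)

    def test_constant_offset_removed(self, rng):
        base = rng.standard_normal((4, 10))
        base -= base.mean(axis=0, keepdims=True)
        shifted = base + 7.5
        out = average_reference(_epoch(shifted))
        np.testing.assert_allclose(out.data, base, atol=1e-12)

    def test_column_means_zero_oracle(self, rng):
        out = average_reference(_epoch(rng.standard_normal((7, 31))))
        for t in range(31):
            assert sum(out.data[:, t]) / 7 == pytest.approx(0.0, abs=1e-9)


class TestPatchLibrary:
    def test_smoothness_zero_is_delta(self, sphere_setup):
        src, _, _ = sphere_setup
        lib = build_patch_library(src, n_patches=10, smoothness=0)
        for c in lib.components:
            assert c.profile[c.center] == 1.0
            assert np.count_nonzero(c.profile) == 1

    def test_peak_at_center(self, sphere_setup):
        src, _, _ = sphere_setup
        lib = build_patch_library(src, n_patches=20, smoothness=4)
        for c in lib.components:
            assert np.argmax(c.profile) == c.center
            assert c.profile.max() == 1.0
            assert c.profile.min() >= 0.0

    def test_ring_monotone_decay(self, sphere_setup):
        src, _, _ = sphere_setup
        prof = diffusion_kernel(src, 0, smoothness=6)
        rings = rings_from(src, 0)
        maxima = [prof[rings == r].max() for r in range(6)]
        assert all(a >= b for a, b in zip(maxima, maxima[1:]))

    def test_too_many_patches(self, sphere_setup):
        src, _, _ = sphere_setup
        with pytest.raises(ParameterError):
            build_patch_library(src, n_patches=src.n_vertices + 1)

    def test_deterministic(self, sphere_setup):
        src, _, _ = sphere_setup
        a = build_patch_library(src, 32, 4, seed=3)
        b = build_patch_library(src, 32, 4, seed=3)
        assert [c.center for c in a.components] == [c.center for c in b.components]


def _cluster_at(points_mm):
    pts = np.atleast_2d(points_mm)
    return Cluster(
        voxels=np.zeros((len(pts), 3), int),
        size=len(pts),
        peak_z=3.0,
        peak_mm=pts[0],
        centroid_mm=pts.mean(axis=0),
        world_mm=pts,
    )


class TestSiscomPriors:
    def test_voxel_at_vertex_is_seeded(self, sphere_setup):
        src, _, _ = sphere_setup
        cs = ClusterSet([_cluster_at(src.vertices[17])], 2.0)
        lib = siscom_prior_components(cs, src, max_dist_mm=5.0, smoothness=0)
        assert len(lib) == 1
        assert lib.components[0].tag == "siscom"
        assert lib.components[0].profile[17] == 1.0

    def test_far_cluster_skipped_with_warning(self, sphere_setup):
        src, _, _ = sphere_setup
        cs = ClusterSet([_cluster_at([0.0, 0.0, 0.0])], 2.0)  # deep center
        with pytest.warns(UserWarning, match="no source vertex"):
            lib = siscom_prior_components(cs, src, max_dist_mm=10.0)
        assert len(lib) == 0

    def test_two_clusters_two_components(self, sphere_setup):
        src, _, _ = sphere_setup
        cs = ClusterSet(
            [_cluster_at(src.vertices[3]), _cluster_at(src.vertices[300])], 2.0
        )
        lib = siscom_prior_components(cs, src, max_dist_mm=5.0)
        assert len(lib) == 2
        assert lib.tags == ["siscom", "siscom"]


class TestInvertMSP:
    def test_noise_only_power_much_smaller(self, sphere_setup):
        src, _, lf = sphere_setup
        lib = build_patch_library(src, 128, 4, seed=0)
        wf = default_waveform(100, 250.0)
        eeg_sig, _ = simulate_eeg(src, lf, [50], wf, 10.0, seed=3)
        rng = np.random.default_rng(3)
        noise = rng.standard_normal(eeg_sig.data.shape) * eeg_sig.data.std()
        eeg_noise = EEGEpoch(noise, 250.0, list(eeg_sig.labels))
        res_sig = invert_msp(average_reference(eeg_sig), lf, lib)
        res_noise = invert_msp(average_reference(eeg_noise), lf, lib)
        assert res_noise.vertex_power().sum() < 0.1 * res_sig.vertex_power().sum()

    def test_single_patch_recovery(self, sphere_setup):
        src, _, lf = sphere_setup
        lib = build_patch_library(src, src.n_vertices, 4, seed=0)
        wf = default_waveform(200, 250.0)
        true_v = 123
        eeg, _ = simulate_eeg(src, lf, [true_v], wf, 20.0, seed=7)
        res = invert_msp(average_reference(eeg), lf, lib)
        peak = int(np.argmax(res.vertex_power()))
        assert rings_from(src, true_v)[peak] <= 2

    def test_free_energy_monotone(self, sphere_setup):
        src, _, lf = sphere_setup
        lib = build_patch_library(src, 64, 4, seed=1)
        wf = default_waveform(120, 250.0)
        eeg, _ = simulate_eeg(src, lf, [10], wf, 12.0, seed=5)
        res = invert_msp(average_reference(eeg), lf, lib)
        f = res.free_energy_trace
        assert np.all(np.diff(f) >= -1e-6 * np.maximum(1.0, np.abs(f[:-1])))

    def test_ard_prunes_most_components(self, sphere_setup):
        src, _, lf = sphere_setup
        lib = build_patch_library(src, 256, 4, seed=0)
        wf = default_waveform(200, 250.0)
        eeg, _ = simulate_eeg(src, lf, [321], wf, 20.0, seed=9)
        res = invert_msp(average_reference(eeg), lf, lib)
        assert len(res.active_components) < 0.1 * len(lib)

    def test_time_replication_linearity(self, sphere_setup):
        # identical covariance -> identical hyperparameters -> per-sample
        # linear posterior, so duplicating the epoch duplicates J
        src, _, lf = sphere_setup
        lib = build_patch_library(src, 64, 4, seed=2)
        wf = default_waveform(80, 250.0)
        eeg, _ = simulate_eeg(src, lf, [200], wf, 15.0, seed=11)
        eeg = average_reference(eeg)
        doubled = EEGEpoch(np.hstack([eeg.data, eeg.data]), eeg.srate,
                           list(eeg.labels))
        res1 = invert_msp(eeg, lf, lib)
        res2 = invert_msp(doubled, lf, lib)
        T = eeg.n_samples
        np.testing.assert_allclose(res2.J[:, :T], res2.J[:, T:], atol=1e-12)
        np.testing.assert_allclose(res2.J[:, :T], res1.J, rtol=1e-3, atol=1e-9)

    def test_empty_library_rejected(self, sphere_setup):
        src, _, lf = sphere_setup
        eeg = _epoch(np.random.default_rng(0).standard_normal((19, 10)),
                     list(lf.electrodes.labels))
        with pytest.raises(ParameterError):
            invert_msp(eeg, lf, PriorLibrary([]))


class TestInvertWithSiscomPrior:
    def test_empty_augmentation_identical(self, sphere_setup):
        src, _, lf = sphere_setup
        lib = build_patch_library(src, 64, 4, seed=0)
        wf = default_waveform(100, 250.0)
        eeg, _ = simulate_eeg(src, lf, [42], wf, 15.0, seed=1)
        eeg = average_reference(eeg)
        r1 = invert_msp(eeg, lf, lib)
        r2 = invert_with_siscom_prior(eeg, lf, lib, PriorLibrary([]))
        np.testing.assert_array_equal(r1.J, r2.J)
        np.testing.assert_array_equal(r1.hyperparameters, r2.hyperparameters)

    def test_colocated_prior_does_not_hurt(self, sphere_setup):
        src, _, lf = sphere_setup
        lib = build_patch_library(src, 256, 4, seed=0)
        wf = default_waveform(150, 250.0)
        errs_plain, errs_prior = [], []
        for seed in range(8):
            true_v = int(np.random.default_rng(1000 + seed).integers(0, 642))
            eeg, _ = simulate_eeg(src, lf, [true_v], wf, 10.0, seed=seed)
            eeg = average_reference(eeg)
            rings = rings_from(src, true_v)
            cs = ClusterSet([_cluster_at(src.vertices[true_v])], 2.0)
            prior = siscom_prior_components(cs, src, max_dist_mm=5.0)
            r0 = invert_msp(eeg, lf, lib)
            r1 = invert_with_siscom_prior(eeg, lf, lib, prior)
            errs_plain.append(rings[int(np.argmax(r0.vertex_power()))])
            errs_prior.append(rings[int(np.argmax(r1.vertex_power()))])
        assert np.median(errs_prior) <= np.median(errs_plain)

    def test_wrong_prior_overridden_at_high_snr(self, sphere_setup):
        src, _, lf = sphere_setup
        lib = build_patch_library(src, 256, 4, seed=0)
        wf = default_waveform(200, 250.0)
        true_v = 100
        contra = int(np.argmax(
            np.linalg.norm(src.vertices - src.vertices[true_v], axis=1)
        ))
        eeg, _ = simulate_eeg(src, lf, [true_v], wf, 20.0, seed=13)
        eeg = average_reference(eeg)
        cs = ClusterSet([_cluster_at(src.vertices[contra])], 2.0)
        prior = siscom_prior_components(cs, src, max_dist_mm=5.0)
        res = invert_with_siscom_prior(eeg, lf, lib, prior)
        rings = rings_from(src, true_v)
        ipsi = sum(
            res.hyperparameters[i]
            for i, c in enumerate(lib.components)
            if rings[c.center] <= 4
        )
        contra_w = sum(
            res.hyperparameters[len(lib) + j]
            for j in range(len(prior))
        )
        assert ipsi > contra_w


class TestSourceToEZMap:
    def _mri(self):
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        aff[:3, 3] = -63.0
        return Volume3D(np.zeros((64, 64, 64)), aff)

    def _result(self, src, power):
        from ezloc.esi import MSPResult

        J = np.sqrt(power)[:, None] * np.ones((1, 4))
        return MSPResult(np.ones(2), J, np.zeros(1), np.arange(1), True, ["patch"])

    def test_frac_one_selects_argmax_only(self, sphere_setup):
        src, _, _ = sphere_setup
        power = np.zeros(src.n_vertices)
        power[37] = 4.0
        power[40] = 1.0
        ez = source_to_ez_map(self._result(src, power), src, self._mri(), frac=1.0)
        assert list(ez.vertex_set) == [37]

    def test_small_frac_selects_all_nonzero(self, sphere_setup):
        src, _, _ = sphere_setup
        power = np.zeros(src.n_vertices)
        power[[5, 10, 15]] = [1.0, 2.0, 3.0]
        ez = source_to_ez_map(self._result(src, power), src, self._mri(),
                              frac=1e-9)
        assert sorted(ez.vertex_set) == [5, 10, 15]

    def test_rendered_count_matches_distance_loop(self, sphere_setup):
        src, _, _ = sphere_setup
        power = np.zeros(src.n_vertices)
        power[0] = 1.0
        mri = self._mri()
        ez = source_to_ez_map(self._result(src, power), src, mri, frac=0.5,
                              render_radius_mm=4.0)
        center = src.vertices[0]
        count = 0
        for idx in np.ndindex(mri.shape):
            if np.linalg.norm(mri.voxel_to_world(list(idx)) - center) <= 4.0:
                count += 1
        assert ez.volume.n_voxels == count

    def test_all_zero_currents_empty_map(self, sphere_setup):
        src, _, _ = sphere_setup
        power = np.zeros(src.n_vertices)
        with pytest.warns(UserWarning, match="all-zero"):
            ez = source_to_ez_map(self._result(src, power), src, self._mri())
        assert ez.volume.n_voxels == 0
        assert len(ez.vertex_set) == 0
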