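"""Monte Carlo engine: conservation laws, bookkeeping and physics checks."""

import numpy as np
import pytest

from skindrs import engine

from ._oracles import diffusion_reflectance


def _matched_stack(mus=10.0, g=0.8, max_depth=200.0):
    """Semi-infinite medium with index matched to the probe side."""
    return engine.LayerStack(
        thickness=(float("inf"),), mus=(mus,), g=(g,), n=(1.4,),
        n_external=1.4, max_depth=max_depth,
    )


class TestTransportBookkeeping:
    def test_energy_conservation_without_absorption(self, probe):
        """Matched-index, absorption-free: all launched weight re-emerges."""
        stack = _matched_stack(mus=10.0, max_depth=400.0)
        rec = engine.simulate(
            stack, probe, 30_000, seed=5, store_paths=False, max_path=1e7,
            max_steps=50_000_000,
        )
        assert rec.launched_weight == pytest.approx(30_000)  # no specular loss
        leak = 1.0 - rec.exited_weight / rec.launched_weight
        assert abs(leak) <= 0.005

    def test_pathlength_sum_equals_arc_length(self, probe):
        """Per-layer pathlengths must add up to the stored total arc length."""
        stack = engine.three_layer_stack(t_epi=0.05, mus=12.0)
        rec = engine.simulate(stack, probe, 40_000, seed=6)
        assert len(rec) > 10
        totals = rec.pathlengths.sum(axis=1)
        ends = rec.path_s[rec.path_offsets[1:] - 1]
        np.testing.assert_allclose(totals, ends, rtol=1e-9)
        assert np.all(rec.pathlengths >= 0)
        assert np.all(rec.weight > 0)
        assert np.all(rec.weight <= 1)

    def test_seed_reproducibility_bitwise(self, probe):
        stack = engine.three_layer_stack(t_epi=0.08, mus=8.0)
        a = engine.simulate(stack, probe, 30_000, seed=123)
        b = engine.simulate(stack, probe, 30_000, seed=123)
        assert np.array_equal(a.pathlengths, b.pathlengths)
        assert np.array_equal(a.weight, b.weight)
        assert np.array_equal(a.path_z, b.path_z)
        c = engine.simulate(stack, probe, 30_000, seed=124)
        assert not np.array_equal(a.pathlengths, c.pathlengths)

    def test_near_detector_sees_more_photons(self, probe):
        stack = engine.three_layer_stack(t_epi=0.06, mus=10.0)
        rec = engine.simulate(stack, probe, 150_000, seed=8, store_paths=False)
        n_near = int(np.sum(rec.detector == 0))
        n_far = int(np.sum(rec.detector == 1))
        assert n_near > n_far > 0

    def test_transparent_internal_boundary(self, probe):
        """Splitting a homogeneous medium into layers must not change anything:
        identical optical properties on both sides consume no randomness."""
        one = engine.LayerStack(
            thickness=(float("inf"),), mus=(9.0,), g=(0.8,), n=(1.4,),
            n_external=1.5, max_depth=20.0,
        )
        two = engine.LayerStack(
            thickness=(0.35, float("inf")), mus=(9.0, 9.0), g=(0.8, 0.8),
            n=(1.4, 1.4), n_external=1.5, max_depth=20.0,
        )
        ra = engine.simulate(one, probe, 50_000, seed=9, store_paths=False)
        rb = engine.simulate(two, probe, 50_000, seed=9, store_paths=False)
        assert len(ra) == len(rb)
        np.testing.assert_allclose(
            ra.pathlengths.sum(axis=1), rb.pathlengths.sum(axis=1), rtol=1e-9
        )
        np.testing.assert_allclose(ra.weight, rb.weight, rtol=1e-12)

    def test_degenerate_probe_rejected(self):
        with pytest.raises(ValueError):
            engine.ProbeGeometry(separations=(0.15, 1.2))


class TestPhysics:
    def test_matches_diffusion_theory_at_far_detector(self):
        """Semi-infinite medium, mus'=1, g=0.8, n=1.4 vs 1.0: the spatially
        resolved reflectance at rho=1.2 mm agrees with the diffusion closed
        form within 15 %."""
        probe = engine.ProbeGeometry(
            separations=(1.2,), source_radius=0.05, detector_radius=0.1,
            numerical_aperture=1.0,
        )
        stack = engine.LayerStack(
            thickness=(float("inf"),), mus=(5.0,), g=(0.8,), n=(1.4,),
            n_external=1.0, max_depth=60.0,
        )
        rec = engine.simulate(
            stack, probe, 250_000, seed=3, store_paths=False, max_path=5000.0
        )
        area = np.pi * probe.detector_radius**2
        mua = 0.01
        m = rec.detector == 0
        w = rec.weight[m] * np.exp(-mua * rec.pathlengths[m].sum(axis=1))
        r_mc = w.sum() / rec.launched_weight / area
        r_diff = diffusion_reflectance(1.2, mua, 1.0, 1.4)
        assert r_mc == pytest.approx(r_diff, rel=0.15)

    def test_sqrt_n_error_scaling(self, probe):
        """Doubling the photon count should shrink the standard error of the
        detected weight by ~sqrt(2) (within a +/-30 % band)."""
        stack = engine.three_layer_stack(t_epi=0.06, mus=12.0, max_depth=8.0)
        lo, hi = [], []
        for k in range(16):
            a = engine.simulate(stack, probe, 20_000, seed=300 + k, store_paths=False)
            b = engine.simulate(stack, probe, 40_000, seed=600 + k, store_paths=False)
            lo.append(a.reflectance(2)[0])
            hi.append(b.reflectance(2)[0])
        ratio = np.std(lo, ddof=1) / np.std(hi, ddof=1)
        assert 0.7 * np.sqrt(2.0) <= ratio <= 1.3 * np.sqrt(2.0)


class TestBasis:
    def test_grid_contract(self, fit_basis):
        ni, nj = fit_basis.shape
        assert (ni, nj) == (
            len(engine.DEFAULT_T_EPI_LEVELS),
            len(engine.DEFAULT_MUS_R_LEVELS),
        )
        for i in range(ni):
            for j in range(nj):
                rec = fit_basis.cell(i, j)
                assert np.sum(rec.detector == 0) >= 1
                assert rec.n_emitted == fit_basis.n_photons

    def test_roundtrip_is_lossless(self, tmp_path, path_basis):
        f = tmp_path / "basis.h5"
        path_basis.save(f)
        loaded = engine.MCBasis.load(f)
        assert np.array_equal(loaded.t_epi_levels, path_basis.t_epi_levels)
        assert np.array_equal(loaded.mus_r_levels, path_basis.mus_r_levels)
        for i in range(path_basis.shape[0]):
            for j in range(path_basis.shape[1]):
                a, b = path_basis.cell(i, j), loaded.cell(i, j)
                assert np.array_equal(a.pathlengths, b.pathlengths)
                assert np.array_equal(a.weight, b.weight)
                assert np.array_equal(a.path_z, b.path_z)
                assert a.launched_weight == b.launched_weight

    def test_invalid_levels_rejected(self, probe):
        with pytest.raises(ValueError):
            engine.build_basis([0.05], [1.0, 2.0], probe, 100, seed=0)
        with pytest.raises(ValueError):
            engine.build_basis([0.05, 0.02], [1.0, 2.0], probe, 100, seed=0)


class TestCompressPaths:
    def test_single_depth_path(self):
        """A photon whose whole path sits at depth d yields points only at d."""
        rec = engine.PhotonRecords(
            pathlengths=np.array([[0.0, 2.0, 0.0]]),
            weight=np.array([0.5]),
            exit_radius=np.array([0.4]),
            detector=np.array([0]),
            n_emitted=1,
            launched_weight=1.0,
            exited_weight=1.0,
            lost_weight=0.0,
            seed=0,
            path_offsets=np.array([0, 3]),
            path_z=np.array([0.3, 0.3, 0.3]),
            path_s=np.array([0.0, 1.0, 2.0]),
        )
        cloud = engine.compress_paths(rec, 50, seed=1)
        assert cloud.depth.shape == (50,)
        np.testing.assert_allclose(cloud.depth, 0.3)
        assert cloud.weight.sum() == pytest.approx(50 * 0.5)

    def test_zero_weight_photon_contributes_nothing(self):
        rec = engine.PhotonRecords(
            pathlengths=np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0]]),
            weight=np.array([0.25, 0.0]),
            exit_radius=np.array([0.4, 0.4]),
            detector=np.array([0, 0]),
            n_emitted=2,
            launched_weight=2.0,
            exited_weight=2.0,
            lost_weight=0.0,
            seed=0,
            path_offsets=np.array([0, 2, 4]),
            path_z=np.array([0.0, 1.0, 0.0, 1.0]),
            path_s=np.array([0.0, 1.0, 0.0, 1.0]),
        )
        cloud = engine.compress_paths(rec, 10, seed=2)
        assert cloud.weight.sum() == pytest.approx(10 * 0.25)

    def test_uniform_depth_distribution(self):
        """A straight vertical path yields a uniform depth distribution."""
        from scipy.stats import kstest

        rec = engine.PhotonRecords(
            pathlengths=np.array([[0.0, 1.0, 0.0]]),
            weight=np.array([1.0]),
            exit_radius=np.array([0.4]),
            detector=np.array([0]),
            n_emitted=1,
            launched_weight=1.0,
            exited_weight=1.0,
            lost_weight=0.0,
            seed=0,
            path_offsets=np.array([0, 2]),
            path_z=np.array([0.0, 1.0]),
            path_s=np.array([0.0, 1.0]),
        )
        cloud = engine.compress_paths(rec, 10_000, seed=3)
        assert kstest(cloud.depth, "uniform").pvalue > 0.01

    def test_empty_records(self):
        rec = engine.PhotonRecords(
            pathlengths=np.empty((0, 3)),
            weight=np.empty(0),
            exit_radius=np.empty(0),
            detector=np.empty(0, dtype=np.int8),
            n_emitted=10,
            launched_weight=10.0,
            exited_weight=10.0,
            lost_weight=0.0,
            seed=0,
            path_offsets=np.array([0]),
            path_z=np.empty(0),
            path_s=np.empty(0),
        )
        cloud = engine.compress_paths(rec, 5, seed=1)
        assert cloud.depth.size == 0
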