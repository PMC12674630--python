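import numpy as np
import pytest

from optiwrist.fem import (RegionOpticalModel, assemble, robin_A,
                           source_vector)
from optiwrist.geometry import GeometryError, LabeledTetMesh, \
    build_cylinder_mesh
from optiwrist.tdforward import (NoiseSpec, add_noise, apply_snr_noise,
                                 attach_probes, calibrate, convolve_irf,
                                 dataset_laplace, delta_irf, gaussian_irf,
                                 laplace_transform, make_probe_layout,
                                 model_laplace_data, simulate_tpsf,
                                 solve_green_functions)

MODEL = RegionOpticalModel.homogeneous(0.0122, 1.286)


class TestProbeLayout:
    def test_canonical_four_ring_geometry(self):
        layout = make_probe_layout(27.0)
        assert layout.n_positions == 32
        assert layout.n_pairs == 224
        assert layout.arc_mm.min() == pytest.approx(2 * np.pi * 27 / 8,
                                                    rel=1e-6)
        assert layout.arc_mm.max() == pytest.approx(np.pi * 27, rel=1e-6)

    def test_two_point_ring_is_antipodal(self):
        layout = make_probe_layout(10.0, ring_z=(5.0,), points_per_ring=2)
        assert layout.n_pairs == 2
        assert np.allclose(layout.arc_mm, np.pi * 10.0)

    def test_single_point_rejected(self):
        with pytest.raises(GeometryError):
            make_probe_layout(27.0, points_per_ring=1)


class TestLaplaceTransform:
    def test_p_zero_is_total_area(self):
        times = np.arange(0, 100.0, 1.0)
        curve = np.random.default_rng(0).uniform(0, 1, 100)
        assert laplace_transform(curve, 0.0, times) == pytest.approx(
            np.trapezoid(curve, times))

    def test_exponential_closed_form(self):
        times = np.arange(0, 5000.0, 1.0)
        tau = 300.0
        curve = np.exp(-times / tau)
        for p in (1e-3, 5e-3):
            assert laplace_transform(curve, p, times) == pytest.approx(
                tau / (1 + p * tau), rel=1e-3)

    def test_monotone_in_p_for_positive_data(self):
        times = np.arange(0, 1000.0, 5.0)
        curve = np.exp(-((times - 300) / 150.0) ** 2)
        vals = [laplace_transform(curve, p, times)
                for p in (0.0, 1e-3, 3e-3)]
        assert vals[0] > vals[1] > vals[2]


class TestIrf:
    def test_delta_irf_is_identity(self, homogeneous_wrist):
        layout = make_probe_layout(27.0, ring_z=(30.0,), points_per_ring=4)
        probes = attach_probes(homogeneous_wrist, layout, MODEL)
        ds = simulate_tpsf(homogeneous_wrist, MODEL, probes, t_max=1200.0)
        out = convolve_irf(ds, delta_irf(ds.times))
        np.testing.assert_allclose(out.tpsf, ds.tpsf, rtol=1e-9, atol=1e-20)

    def test_convolution_associativity(self):
        times = np.arange(0, 2000.0, 12.2)
        rng = np.random.default_rng(1)
        from optiwrist.tdforward import ProbeLayout, TimeResolvedDataset
        layout = make_probe_layout(27.0, ring_z=(30.0,), points_per_ring=2)
        tpsf = rng.uniform(0, 1, (len(times), 2))
        ds = TimeResolvedDataset(times=times, tpsf=tpsf, layout=layout)
        irf = gaussian_irf(times, 250.0)
        twice = convolve_irf(convolve_irf(ds, irf), irf)
        self_conv = np.convolve(irf, irf)[:len(times)] * (times[1] - times[0])
        once = convolve_irf(ds, self_conv)
        np.testing.assert_allclose(twice.tpsf, once.tpsf, atol=1e-10)

    def test_total_counts_scale_with_irf_area(self):
        times = np.arange(0, 3000.0, 12.2)
        irf = 2.0 * gaussian_irf(times, 200.0)
        from optiwrist.tdforward import TimeResolvedDataset
        layout = make_probe_layout(27.0, ring_z=(30.0,), points_per_ring=2)
        tpsf = np.exp(-times / 500.0)[:, None] * np.ones((1, 2))
        tpsf[-60:] = 0.0        # compactly supported so truncation is exact
        ds = TimeResolvedDataset(times=times, tpsf=tpsf, layout=layout)
        out = convolve_irf(ds, irf)
        scale = irf.sum() * ds.dt
        assert out.tpsf.sum() / ds.tpsf.sum() == pytest.approx(scale, rel=0.02)


class TestNoiseModel:
    def test_weakest_datum_sits_at_snr_min(self):
        rng = np.random.default_rng(0)
        values = np.array([1.0, 10.0, 100.0])
        draws = np.array([apply_snr_noise(values, 20.0,
                                          np.random.default_rng(s))
                          for s in range(10_000)])
        rel_sd = draws.std(axis=0) / values
        assert rel_sd[0] == pytest.approx(0.1, rel=0.05)

    def test_empirical_sd_matches_formula(self):
        values = np.array([2.0, 5.0, 20.0])
        snr = 20.0 * values / values.min()
        expect = values * 10.0 ** (-snr / 20.0)
        draws = np.array([apply_snr_noise(values, 20.0,
                                          np.random.default_rng(s))
                          for s in range(10_000)])
        np.testing.assert_allclose(draws.std(axis=0), expect, rtol=0.05)

    def test_infinite_snr_is_identity(self):
        values = np.linspace(1, 5, 10)
        out = apply_snr_noise(values, 1e6, np.random.default_rng(0))
        np.testing.assert_allclose(out, values, rtol=1e-12)

    def test_nonpositive_data_rejected(self):
        with pytest.raises(ValueError):
            apply_snr_noise(np.zeros(3), 20.0, np.random.default_rng(0))

    def test_dataset_noise_reproducible(self, homogeneous_wrist):
        layout = make_probe_layout(27.0, ring_z=(30.0,), points_per_ring=4)
        probes = attach_probes(homogeneous_wrist, layout, MODEL)
        ds = simulate_tpsf(homogeneous_wrist, MODEL, probes, t_max=1200.0)
        a = add_noise(ds, NoiseSpec(20.0, seed=5))
        b = add_noise(ds, NoiseSpec(20.0, seed=5))
        np.testing.assert_array_equal(a.tpsf, b.tpsf)


class TestCalibration:
    def test_target_equal_reference_returns_model(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(1, 2, (10, 2))
        m = rng.uniform(1, 2, (10, 2))
        np.testing.assert_allclose(calibrate(g, g, m), m)

    def test_common_per_pair_factor_cancels_exactly(self):
        rng = np.random.default_rng(1)
        tar = rng.uniform(1, 2, (12, 2))
        ref = rng.uniform(1, 2, (12, 2))
        model = rng.uniform(1, 2, (12, 2))
        irf_factor = rng.uniform(0.1, 10, (12, 1))
        base = calibrate(tar, ref, model)
        scaled = calibrate(tar * irf_factor, ref * irf_factor, model)
        np.testing.assert_allclose(scaled, base, rtol=1e-14)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            calibrate(np.ones((2, 2)), np.zeros((2, 2)), np.ones((2, 2)))


class TestFemForward:
    def test_infinite_medium_green_function(self):
        mesh = build_cylinder_mesh(27.0, 60.0, 16000)
        lm = LabeledTetMesh(mesh, np.ones(mesh.n_nodes, dtype=int),
                            radius=27.0, height=60.0)
        model = RegionOpticalModel.homogeneous(0.01, 1.0)
        system = assemble(lm, model)
        src = np.array([0.0, 0.0, 30.0])
        q = source_vector(mesh, src)
        r = np.linalg.norm(mesh.nodes - src, axis=1)
        for p in (0.0, 2e-3):
            phi = system.solve(p, q)
            kap = model.kappa(1)
            mueff = np.sqrt((0.01 + p / model.c) / kap)
            for lo in range(5, 11):
                band = (r > lo) & (r < lo + 1)
                exact = np.exp(-mueff * r[band]) / (4 * np.pi * kap * r[band])
                assert abs(phi[band].mean() / exact.mean() - 1) < 0.05

    def test_reciprocity_to_solver_precision(self, homogeneous_wrist):
        layout = make_probe_layout(27.0)
        probes = attach_probes(homogeneous_wrist, layout, MODEL)
        system = assemble(homogeneous_wrist, MODEL)
        phi, _ = solve_green_functions(system, probes, 2e-3)
        dm = probes.q.T @ phi
        assert np.abs(dm - dm.T).max() / np.abs(dm).max() < 1e-8

    def test_flux_decreases_with_p(self, homogeneous_wrist):
        layout = make_probe_layout(27.0, ring_z=(25.0, 35.0))
        probes = attach_probes(homogeneous_wrist, layout, MODEL)
        data = model_laplace_data(homogeneous_wrist, MODEL, probes,
                                  (0.0, 1e-3, 3e-3))
        assert (np.diff(data, axis=1) < 0).all()

    def test_zero_source_gives_zero_field(self, homogeneous_wrist):
        system = assemble(homogeneous_wrist, MODEL)
        phi = system.solve(0.0, np.zeros(homogeneous_wrist.mesh.n_nodes))
        assert np.abs(phi).max() == 0.0

    def test_missing_region_property_rejected(self, labeled_wrist):
        bad = RegionOpticalModel({1: 0.01}, {1: 1.0})
        with pytest.raises(Exception, match="region"):
            assemble(labeled_wrist, bad)

    def test_reflective_boundary_conserves_mass(self):
        mesh = build_cylinder_mesh(10.0, 10.0, 600)
        lm = LabeledTetMesh(mesh, np.ones(mesh.n_nodes, dtype=int),
                            radius=10.0, height=10.0)
        model = RegionOpticalModel.homogeneous(1e-12, 1.0)
        system = assemble(lm, model, robin=False)
        from scipy.sparse.linalg import splu
        dt = 12.2
        lu = splu((system.m + 0.5 * dt * system.k0).tocsc())
        rhs = (system.m - 0.5 * dt * system.k0).tocsr()
        phi = splu(system.m.tocsc()).solve(
            source_vector(mesh, np.array([0.0, 0.0, 5.0])))
        total0 = (system.m @ phi).sum()
        for _ in range(30):
            phi = lu.solve(rhs @ phi)
        assert (system.m @ phi).sum() == pytest.approx(total0, rel=1e-6)


class TestTpsf:
    @pytest.fixture(scope="class")
    def dataset(self, homogeneous_study_wrist):
        # study resolution: the transform-consistency contract is stated at
        # the default mesh scale (short pairs are under-resolved below it)
        layout = make_probe_layout(27.0)
        probes = attach_probes(homogeneous_study_wrist, layout, MODEL)
        ds = simulate_tpsf(homogeneous_study_wrist, MODEL, probes)
        return ds, probes

    def test_nonnegative_and_causal(self, dataset):
        ds, _ = dataset
        assert ds.tpsf.min() >= 0.0
        assert ds.tpsf[0].max() <= 1e-6 * ds.tpsf.max()

    def test_peak_time_grows_with_separation(self, dataset):
        from scipy.stats import spearmanr
        ds, _ = dataset
        peaks = ds.times[np.argmax(ds.tpsf, axis=0)]
        rho = spearmanr(ds.layout.arc_mm, peaks).statistic
        assert rho > 0.9

    def test_dc_consistency_with_direct_solve(self, dataset,
                                              homogeneous_study_wrist):
        ds, probes = dataset
        direct = model_laplace_data(homogeneous_study_wrist, MODEL, probes,
                                    (0.0,))
        td = dataset_laplace(ds, (0.0,))
        rel = np.abs(td / direct - 1)
        assert rel.max() < 0.01

    def test_laplace_consistency_at_p2(self, dataset,
                                       homogeneous_study_wrist):
        ds, probes = dataset
        direct = model_laplace_data(homogeneous_study_wrist, MODEL, probes,
                                    (3e-3,))
        td = dataset_laplace(ds, (3e-3,))
        rel = np.abs(td / direct - 1)
        assert rel.mean() < 0.02
        assert rel.max() < 0.05

    def test_unstable_step_rejected(self, homogeneous_wrist):
        layout = make_probe_layout(27.0, ring_z=(30.0,), points_per_ring=2)
        probes = attach_probes(homogeneous_wrist, layout, MODEL)
        with pytest.raises(ValueError):
            simulate_tpsf(homogeneous_wrist, MODEL, probes, dt=-1.0)


def test_robin_coefficient_reference_value():
    # Groenhuis fit at n = 1.4 gives A close to the widely used ~3.25
    assert robin_A(1.4) == pytest.approx(3.25, abs=0.15)
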