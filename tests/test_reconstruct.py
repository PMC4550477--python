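import numpy as np
import pytest

from neholo import (
    ArrayGeometry,
    MediumModel,
    Region,
    RegionSpec,
    ScalarFieldFrame,
    VectorFieldFrame,
    WavenumberSet,
    build_frequency_lattice,
    cycle_average,
    detect_cycle_markers,
    dissipation,
    electric_field_at_measurement,
    energy_source_density,
    estimate_H,
    infer_normal_component,
    poynting,
    reconstruct,
    reconstruct_E,
    reconstruct_movie,
    region_vectors,
    split_complex_flow,
    temporal_phasor,
)
from neholo.kspace import all_pass_filter, kspace_filter
from neholo.reconstruct import ReconstructionParams


def _vec(geometry, x, y, z=None, plane_z=0.0):
    z = np.zeros_like(np.asarray(x, dtype=complex)) if z is None else z
    return VectorFieldFrame(np.asarray(x, complex), np.asarray(y, complex), z,
                            geometry, plane_z, label="S")


class TestElectricField:
    def test_constant_potential_zero_field(self, geometry):
        E = electric_field_at_measurement(ScalarFieldFrame(np.ones(geometry.shape), geometry))
        assert np.abs(E.x).max() == 0 and np.abs(E.y).max() == 0

    def test_linear_ramp_constant_gradient(self, geometry):
        x = geometry.node_x()[None, :] * np.ones(geometry.shape)
        E = electric_field_at_measurement(ScalarFieldFrame(2.0 * x, geometry))
        assert np.allclose(E.x, 2.0)
        assert np.allclose(E.y, 0.0)
        assert np.abs(E.z).max() == 0

    def test_sinusoid_gradient_second_order_accurate(self, geometry):
        k0 = 2.0  # rad/mm, well below the 7.85 rad/mm Nyquist
        x = geometry.node_x()[None, :] * np.ones(geometry.shape)
        E = electric_field_at_measurement(ScalarFieldFrame(np.sin(k0 * x), geometry))
        h = geometry.pitch_eff
        interior = np.real(E.x[:, 1:-1])
        analytic = k0 * np.cos(k0 * x[:, 1:-1])
        assert np.abs(interior - analytic).max() < h**2 * k0**3 / 6 * 1.01

    def test_small_grid_rejected(self):
        g = ArrayGeometry(2, 2, 0.4)
        with pytest.raises(ValueError):
            electric_field_at_measurement(ScalarFieldFrame(np.zeros((2, 2)), g))


class TestReconstructE:
    def _setup(self, geometry):
        wn = WavenumberSet.for_geometry(geometry, 0.3, 1e5, 1.0, 2 * np.pi * 1.5)
        return wn

    def test_zero_distance_all_pass_identity(self, geometry, rng):
        wn = self._setup(geometry)
        E = _vec(geometry, rng.normal(size=geometry.shape), rng.normal(size=geometry.shape))
        out = reconstruct_E(E, 0.0, wn, None)
        assert np.abs(out.x - E.x).max() < 1e-10

    def test_annihilating_filter_zeroes_field(self, geometry, rng):
        wn = self._setup(geometry)
        kx, ky = build_frequency_lattice(geometry)
        dead = kspace_filter(kx, ky, kc=1.0, alpha=1.0)
        object.__setattr__(dead, "gain", np.zeros_like(dead.gain))
        E = _vec(geometry, rng.normal(size=geometry.shape), rng.normal(size=geometry.shape))
        E.x -= E.x.mean()
        E.y -= E.y.mean()
        out = reconstruct_E(E, 0.1, wn, dead)
        assert np.abs(out.x).max() < 1e-12 and np.abs(out.y).max() < 1e-12


class TestEstimateH:
    def test_zero_field_zero_estimate(self, geometry):
        wn = WavenumberSet.for_geometry(geometry, 0.3, 1e5, 1.0, 9.0)
        H = estimate_H(_vec(geometry, np.zeros(geometry.shape), np.zeros(geometry.shape)), wn)
        assert all(np.abs(c).max() == 0 for c in H.components)

    def test_single_mode_cross_product_by_hand(self, geometry):
        # spatially uniform x-polarised field lives at lattice node (0, 0)
        # where K = (0, 0, kz); K x E = kz * y_hat
        wn = WavenumberSet.for_geometry(geometry, 0.3, 1e5, 1.0, 9.0)
        E = _vec(geometry, np.ones(geometry.shape), np.zeros(geometry.shape))
        H = estimate_H(E, wn)
        kz00 = wn.kz[0, 0]
        assert np.allclose(H.y, kz00)
        assert np.abs(H.x).max() < 1e-12 and np.abs(H.z).max() < 1e-12

    def test_field_parallel_to_K_is_annihilated(self, geometry):
        # on-axis mode polarised along z: K x (0,0,Ez) has no z part and
        # the in-plane parts vanish because kx = ky = 0 at that node
        wn = WavenumberSet.for_geometry(geometry, 0.3, 1e5, 1.0, 9.0)
        E = VectorFieldFrame(
            np.zeros(geometry.shape, complex), np.zeros(geometry.shape, complex),
            np.ones(geometry.shape, complex), geometry, 0.0,
        )
        H = estimate_H(E, wn)
        assert max(np.abs(c).max() for c in H.components) < 1e-12


class TestNormalClosure:
    def test_laplace_closure_satisfies_divergence_free_condition(self, geometry, rng):
        wn = WavenumberSet.for_geometry(geometry, 0.3, 1e5, 1.0, 9.0)
        E = _vec(geometry, rng.normal(size=geometry.shape), rng.normal(size=geometry.shape))
        full = infer_normal_component(E, wn)
        KX, KY = wn.kx[None, :], wn.ky[:, None]
        resid = (KX * np.fft.fft2(full.x) + KY * np.fft.fft2(full.y)
                 + wn.kz * np.fft.fft2(full.z))
        scale = np.abs(np.fft.fft2(full.x)).max() * np.abs(wn.kx).max()
        assert np.abs(resid).max() / scale < 1e-10


class TestPoynting:
    def test_right_hand_rule(self, geometry):
        S = poynting(_vec(geometry, 1.0 * np.ones(geometry.shape), np.zeros(geometry.shape)),
                     _vec(geometry, np.zeros(geometry.shape), np.ones(geometry.shape)))
        assert np.allclose(S.z, 1.0)
        assert np.abs(S.x).max() == 0 and np.abs(S.y).max() == 0

    def test_parallel_fields_vanish(self, geometry, rng):
        e = rng.normal(size=geometry.shape) + 1j * rng.normal(size=geometry.shape)
        E = _vec(geometry, e, 2 * e, 0.5 * e)
        S = poynting(E, _vec(geometry, 3 * e, 6 * e, 1.5 * e))
        assert max(np.abs(c).max() for c in S.components) < 1e-12

    def test_bilinear_orthogonality(self, geometry, rng):
        mk = lambda: rng.normal(size=geometry.shape) + 1j * rng.normal(size=geometry.shape)
        E = _vec(geometry, mk(), mk(), mk())
        H = _vec(geometry, mk(), mk(), mk())
        S = poynting(E, H)
        dotE = S.x * E.x + S.y * E.y + S.z * E.z
        dotH = S.x * H.x + S.y * H.y + S.z * H.z
        assert np.abs(dotE).max() < 1e-10 and np.abs(dotH).max() < 1e-10

    def test_conjugated_convention_flag(self, geometry, rng):
        mk = lambda: rng.normal(size=geometry.shape) + 1j * rng.normal(size=geometry.shape)
        E = _vec(geometry, mk(), mk(), mk())
        H = _vec(geometry, mk(), mk(), mk())
        plain = poynting(E, H)
        conj = poynting(E, H, conjugate=True)
        Hc = _vec(geometry, np.conj(H.x), np.conj(H.y), np.conj(H.z))
        ref = poynting(E, Hc)
        assert np.allclose(conj.x, ref.x)
        assert not np.allclose(plain.x, conj.x)


class TestEnergySourceDensity:
    def test_uniform_flow_zero_divergence(self, geometry):
        S = _vec(geometry, np.full(geometry.shape, 2.0), np.full(geometry.shape, -1.0))
        esd = energy_source_density(S)
        assert np.abs(esd.values).max() < 1e-12

    def test_linear_radial_flow_constant_divergence(self, geometry):
        x = geometry.node_x()[None, :] * np.ones(geometry.shape)
        y = geometry.node_y()[:, None] * np.ones(geometry.shape)
        esd = energy_source_density(_vec(geometry, x, y))
        assert np.allclose(np.real(esd.values), 2.0)

    def test_discrete_divergence_theorem_on_radial_flow(self):
        """The ESD integral over a box matches the analytic outward flux
        through its rim to within 2% for a smooth radial flow."""
        from scipy.special import erf

        g = ArrayGeometry(40, 40, 0.1)
        h = g.pitch_eff
        s2 = 0.5
        x = g.node_x()[None, :] - 2.0
        y = g.node_y()[:, None] - 2.0
        r2 = x**2 + y**2
        esd = np.real(
            energy_source_density(_vec(g, x * np.exp(-r2 / s2), y * np.exp(-r2 / s2))).values
        )
        lo, hi = 10, 30  # box symmetric about the source node
        integral = esd[lo : hi + 1, lo : hi + 1].sum() * h**2
        a = (hi - lo + 1) / 2 * h  # box half-width covered by the node cells
        flux = 4 * a * np.exp(-(a**2) / s2) * np.sqrt(np.pi * s2) * erf(a / np.sqrt(s2))
        assert flux > 0  # net source inside the box -> positive ESD integral
        assert integral == pytest.approx(flux, rel=0.02)


class TestDissipation:
    def test_zero_conductivity_zero_loss(self, geometry, rng):
        E = _vec(geometry, rng.normal(size=geometry.shape), rng.normal(size=geometry.shape))
        D = dissipation(E, np.zeros(geometry.shape))
        assert np.abs(D.values).max() == 0

    def test_direct_formula(self, geometry):
        E = _vec(geometry, np.ones(geometry.shape), np.zeros(geometry.shape))
        D = dissipation(E, np.full(geometry.shape, 2.0))
        assert np.allclose(D.values, 2.0)

    def test_quadratic_homogeneity_and_nonnegativity(self, geometry, rng):
        mk = lambda: rng.normal(size=geometry.shape) + 1j * rng.normal(size=geometry.shape)
        E = _vec(geometry, mk(), mk(), mk())
        sigma = np.abs(rng.normal(size=geometry.shape))
        D1 = dissipation(E, sigma).values
        E2 = _vec(geometry, 2 * E.x, 2 * E.y, 2 * E.z)
        assert np.allclose(dissipation(E2, sigma).values, 4 * D1)
        assert np.all(np.real(D1) >= 0)


class TestComplexFlowSplit:
    def test_split_recomposes_exactly(self, geometry, rng):
        mk = lambda: rng.normal(size=geometry.shape) + 1j * rng.normal(size=geometry.shape)
        S = _vec(geometry, mk(), mk(), mk())
        prop, res = split_complex_flow(S)
        for c, p, r in zip(S.components, prop.components, res.components):
            assert np.array_equal(p + 1j * r, c)
        assert np.isrealobj(prop.x) and np.isrealobj(res.x)

    def test_pure_imaginary_flow_is_resonant(self, geometry):
        S = _vec(geometry, 1j * np.ones(geometry.shape), np.zeros(geometry.shape))
        prop, res = split_complex_flow(S)
        assert np.abs(prop.x).max() == 0
        assert np.allclose(res.x, 1.0)


class TestCycleAverage:
    def test_identical_cycles_average_to_one_cycle(self):
        cycle = np.sin(np.linspace(0, 2 * np.pi, 20, endpoint=False))
        stack = np.tile(cycle, 5)[:, None, None] * np.ones((1, 2, 2))
        markers = np.arange(0, 101, 20)[:5]
        avg = cycle_average(stack, markers, n_phasepoints=8)
        single = cycle_average(stack[:21], [0, 20], n_phasepoints=8)
        assert np.allclose(avg, single)

    def test_antiphase_cycles_cancel(self):
        v = np.ones((2, 2))
        stack = np.concatenate([np.tile(v, (10, 1, 1)), np.tile(-v, (10, 1, 1)),
                                np.tile(v, (2, 1, 1))])
        avg = cycle_average(stack, [0, 10, 20], n_phasepoints=4)
        # cycle 1 is +v throughout, cycle 2 is -v throughout
        assert np.abs(avg).max() < 1e-12

    def test_noisy_cycles_average_toward_template(self, rng):
        n_cycles, period = 60, 16
        template = np.sin(np.linspace(0, 2 * np.pi, period, endpoint=False))
        sd = 0.3
        stack = (np.tile(template, n_cycles + 1)[:, None, None]
                 + rng.normal(0, sd, (period * (n_cycles + 1), 1, 1)))
        markers = np.arange(0, period * n_cycles + 1, period)
        avg = cycle_average(stack, markers, n_phasepoints=8)
        resampled = template[::2]
        err = np.abs(avg[:, 0, 0] - resampled)
        assert np.mean(err < 3 * sd / np.sqrt(n_cycles)) >= 0.95

    def test_marker_validation(self):
        stack = np.zeros((10, 2, 2))
        with pytest.raises(ValueError):
            cycle_average(stack, [3], 4)
        with pytest.raises(ValueError):
            cycle_average(stack, [5, 3], 4)

    def test_detect_cycle_markers_on_pure_tone(self):
        fs = 200.0
        t = np.arange(int(10 * fs)) / fs
        series = np.sin(2 * np.pi * 1.5 * t)
        markers = detect_cycle_markers(series, fs)
        assert len(markers) >= 10
        # negative-going crossings of a 1.5 Hz tone are ~fs/1.5 apart;
        # the outermost intervals feel the filter's edge transient
        assert np.allclose(np.diff(markers)[1:-1], fs / 1.5, atol=4)


class TestRegionVectors:
    def test_uniform_flow_reported_everywhere(self, geometry):
        S = _vec(geometry, np.ones(geometry.shape), np.zeros(geometry.shape))
        spec = RegionSpec([Region("deep", 0, 5, 0, 10), Region("sup", 5, 10, 0, 10)])
        df = region_vectors(S, spec)
        assert np.allclose(df["magnitude"], 1.0)
        assert np.allclose(df["angle_rad"], 0.0)

    def test_opposite_fields_opposite_angles(self, geometry):
        half = np.ones((10, 5))
        sx = np.hstack([half, -half])
        S = _vec(geometry, sx, np.zeros(geometry.shape))
        spec = RegionSpec([Region("left", 0, 5, 0, 10), Region("right", 5, 10, 0, 10)])
        df = region_vectors(S, spec)
        angles = df.set_index("region")["angle_rad"]
        assert abs(abs(angles["left"] - angles["right"]) - np.pi) < 1e-12

    def test_region_mean_matches_nodewise_oracle(self, geometry, rng):
        sx = rng.normal(size=geometry.shape)
        sy = rng.normal(size=geometry.shape)
        S = _vec(geometry, sx, sy)
        spec = RegionSpec([Region("r", 2, 7, 1, 6)])
        df = region_vectors(S, spec)
        mean_x = np.mean([sx[iy, ix] for iy in range(1, 6) for ix in range(2, 7)])
        mean_y = np.mean([sy[iy, ix] for iy in range(1, 6) for ix in range(2, 7)])
        assert df.loc[0, "magnitude"] == pytest.approx(np.hypot(mean_x, mean_y))
        assert df.loc[0, "angle_rad"] == pytest.approx(np.arctan2(mean_y, mean_x))

    def test_overlap_and_out_of_grid_rejected(self, geometry):
        S = _vec(geometry, np.ones(geometry.shape), np.zeros(geometry.shape))
        with pytest.raises(ValueError, match="overlap"):
            region_vectors(S, RegionSpec([Region("a", 0, 6, 0, 6), Region("b", 5, 10, 0, 6)]))
        with pytest.raises(ValueError, match="exceeds"):
            region_vectors(S, RegionSpec([Region("a", 0, 11, 0, 6)]))
        with pytest.raises(ValueError, match="empty"):
            Region("bad", 3, 3, 0, 5)


class TestPipeline:
    def test_end_to_end_linearity(self, geometry, medium, rng):
        P = rng.normal(size=geometry.shape)
        params = ReconstructionParams()
        r1 = reconstruct(ScalarFieldFrame(P, geometry), medium, params)
        r3 = reconstruct(ScalarFieldFrame(3.0 * P, geometry), medium, params)
        assert np.allclose(r3.E.x, 3.0 * r1.E.x, atol=1e-12)
        assert np.allclose(r3.H.y, 3.0 * r1.H.y, atol=1e-12)
        assert np.allclose(r3.S.x, 9.0 * r1.S.x, atol=1e-12)
        assert np.allclose(r3.esd.values, 9.0 * r1.esd.values, atol=1e-12)
        assert np.allclose(r3.dissipation.values, 9.0 * r1.dissipation.values)

    def test_movie_matches_single_frame(self, geometry, medium, rng):
        movie = rng.normal(size=(3,) + geometry.shape)
        params = ReconstructionParams(upsample_factor=1)
        mr = reconstruct_movie(movie, geometry, medium, params)
        single = reconstruct(ScalarFieldFrame(movie[1], geometry), medium, params)
        assert np.allclose(mr.esd[1], single.esd.values, atol=1e-10)
        assert np.allclose(mr.S[0][1], single.S.x, atol=1e-10)

    def test_result_frames_share_plane(self, geometry, medium, rng):
        res = reconstruct(ScalarFieldFrame(rng.normal(size=geometry.shape), geometry), medium)
        assert res.E.plane_z == res.S.plane_z == res.esd.plane_z == 0.1
        assert np.all(np.real(res.dissipation.values) >= 0)

    def test_temporal_phasor_of_pure_cosine(self):
        fs, f0 = 200.0, 1.5
        t = np.arange(4000) / fs
        movie = np.cos(2 * np.pi * f0 * t + 0.7)[:, None, None] * np.ones((1, 2, 2))
        ph = temporal_phasor(movie, fs, f0)
        assert np.abs(ph[0, 0]) == pytest.approx(1.0, abs=1e-3)
        assert np.angle(ph[0, 0]) == pytest.approx(0.7, abs=1e-3)
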