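import numpy as np
import pytest
from scipy.integrate import quad

from ops_imaging.detector import (
    DetectorGeometry,
    DetectorResponseConfig,
    crt_to_sigma_single,
    efficiency_curves,
    generate_line_events,
    propagate_photons,
    sample_compton_deposits,
    select_triples,
    simulate_triples,
    smear_hits,
)
from ops_imaging.generator import generate_events, SourceSpec
from ops_imaging.physics import compton_edge, material


GEO = DetectorGeometry()
PLASTIC = material("plastic")


class TestGeometry:
    def test_layer_structure(self):
        assert GEO.total_thickness == pytest.approx(6.0)
        assert GEO.outer_radius == pytest.approx(49.0)
        assert GEO.layer_inner_radii == (43.0, 44.5, 46.0, 47.5)

    def test_origin_outside_bore_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            propagate_photons(np.array([[44.0, 0.0, 0.0]]),
                              np.array([[1.0, 0.0, 0.0]]), 511, GEO, PLASTIC, rng)


class TestPropagation:
    def test_normal_incidence_interaction_probability(self):
        rng = np.random.default_rng(1)
        n = 200_000
        origins = np.zeros((n, 3))
        dirs = np.tile([1.0, 0.0, 0.0], (n, 1))
        res = propagate_photons(origins, dirs, 511, GEO, PLASTIC, rng)
        p = res["hit"].mean()
        expected = 1.0 - np.exp(-PLASTIC.mu_511 * 6.0)
        assert p == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected) / n))
        # interaction points lie inside the plastic shell
        rho = np.linalg.norm(res["pos"][res["hit"], :2], axis=1)
        assert rho.min() >= 43.0 and rho.max() <= 49.0
        # flight time consistent with path length
        t = res["tof_ps"][res["hit"]]
        assert t.min() >= 43.0 / 0.0299792458

    def test_axis_parallel_photon_misses(self):
        rng = np.random.default_rng(2)
        res = propagate_photons(np.zeros((10, 3)), np.tile([0, 0, 1.0], (10, 1)),
                                511, GEO, PLASTIC, rng)
        assert not res["hit"].any()

    def test_interaction_fraction_matches_semianalytic_oracle(self):
        # isotropic 511 keV photons from the centre; oracle integrates the
        # closed-form interaction probability over the geometric acceptance
        rng = np.random.default_rng(3)
        n = 300_000
        from ops_imaging.generator import sample_isotropic
        dirs = sample_isotropic(n, rng)
        res = propagate_photons(np.zeros((n, 3)), dirs, 511, GEO, PLASTIC, rng)
        p_mc = res["hit"].mean()

        def prob(theta):
            # from the centre the slant path is limited by the end caps
            sin_t, cos_t = np.sin(theta), abs(np.cos(theta))
            t_in = GEO.inner_radius / sin_t
            t_out = GEO.outer_radius / sin_t
            t_cap = GEO.half_length / cos_t if cos_t > 0 else np.inf
            path = max(min(t_out, t_cap) - t_in, 0.0)
            return (1.0 - np.exp(-PLASTIC.mu_511 * path)) * sin_t / 2.0

        p_exact = 2 * quad(prob, 1e-9, np.pi / 2, limit=200)[0]
        assert p_mc == pytest.approx(p_exact, abs=3 * np.sqrt(p_exact * (1 - p_exact) / n))


class TestComptonSampling:
    @pytest.mark.parametrize("energy", [511.0, 1160.0])
    def test_deposits_within_edge(self, energy):
        rng = np.random.default_rng(4)
        d = sample_compton_deposits(energy, 200_000, rng)
        assert d.min() > 0
        assert d.max() <= compton_edge(energy) + 1e-9

    def test_spectrum_matches_klein_nishina_quadrature(self):
        rng = np.random.default_rng(5)
        energy, n = 511.0, 500_000
        d = sample_compton_deposits(energy, n, rng)
        alpha = energy / 511.0

        def kn_cos(ct):
            r = 1.0 / (1.0 + alpha * (1.0 - ct))
            return r**2 * (r + 1.0 / r - (1.0 - ct**2))

        norm = quad(kn_cos, -1, 1)[0]
        edges = np.linspace(0.0, compton_edge(energy), 25)
        hist, _ = np.histogram(d, bins=edges)
        # expected fraction per deposit bin via change of variables T -> cos
        expected = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            ct_hi = 1.0 - (1.0 / (1.0 - lo / energy) - 1.0) / alpha
            ct_lo = 1.0 - (1.0 / (1.0 - hi / energy) - 1.0) / alpha
            expected.append(quad(kn_cos, ct_lo, ct_hi)[0] / norm)
        expected = np.array(expected) * n
        chi2 = np.sum((hist - expected) ** 2 / expected)
        # 24 bins; generous band for a goodness-of-fit statistic
        assert chi2 < 24 + 5 * np.sqrt(2 * 24)


class TestSmearing:
    def test_sigma_convention(self):
        assert crt_to_sigma_single(10.0) == pytest.approx(3.0027, abs=1e-3)

    def test_zero_noise_identity(self):
        cfg = DetectorResponseConfig(crt_ps=0.0, spatial_fwhm_cm=0.0)
        pos = np.array([[44.0, 1.0, 10.0]])
        t = np.array([123.4])
        pos2, t2 = smear_hits(pos, t, cfg, np.random.default_rng(6))
        np.testing.assert_array_equal(pos, pos2)
        np.testing.assert_array_equal(t, t2)

    def test_time_difference_variance_matches_crt(self):
        crt = 140.0
        cfg = DetectorResponseConfig(crt_ps=crt)
        rng = np.random.default_rng(7)
        n = 1_000_000
        pos = np.tile([44.0, 0.0, 0.0], (n, 1))
        _, t1 = smear_hits(pos, np.zeros(n), cfg, rng)
        _, t2 = smear_hits(pos, np.zeros(n), cfg, rng)
        var = np.var(t1 - t2)
        assert var == pytest.approx((crt / 2.3548) ** 2, rel=0.01)

    def test_position_smearing_unbiased_and_preserves_radius(self):
        cfg = DetectorResponseConfig(crt_ps=100.0)
        rng = np.random.default_rng(8)
        n = 200_000
        pos = np.tile([44.0, 0.0, 7.0], (n, 1))
        sm, _ = smear_hits(pos, np.zeros(n), cfg, rng)
        # tangential smearing at this azimuth moves y, keeps x (radius fixed)
        np.testing.assert_allclose(sm[:, 0], 44.0, atol=1e-9)
        assert abs(sm[:, 1].mean()) < 3 * cfg.sigma_pos_cm / np.sqrt(n)
        assert abs(sm[:, 2].mean() - 7.0) < 3 * cfg.sigma_pos_cm / np.sqrt(n)
        assert sm[:, 2].std() == pytest.approx(cfg.sigma_pos_cm, rel=0.01)


class TestSelection:
    def test_prompt_boundary_rejected(self):
        cfg = DetectorResponseConfig()
        interact = np.array([True])
        sel, counters = select_triples(np.array([250.0]), np.array([250.0]),
                                       np.array([399.0]), interact, cfg)
        assert not sel.any()
        assert counters.pass_annih_threshold == 1
        assert counters.selected == 0

    def test_annihilation_deposit_cannot_fake_prompt(self):
        # hardest possible 511 keV deposit still fails the 400 keV prompt cut
        assert compton_edge(511.0) < DetectorResponseConfig().threshold_prompt_kev

    def test_counters_are_nested(self):
        rng = np.random.default_rng(9)
        events = generate_line_events(100_000, rng)
        _, c = simulate_triples(events, rng=rng)
        assert c.generated >= c.all_three_interact >= c.pass_annih_threshold \
            >= c.pass_prompt_threshold


@pytest.fixture(scope="module")
def curves():
    return efficiency_curves(np.arange(0.0, 401.0, 50.0), 150_000, seed=10)


class TestEfficiencyCurves:
    def test_monotone_non_increasing(self, curves):
        for col in ("prompt", "pair", "triple"):
            assert np.all(np.diff(curves[col].to_numpy()) <= 0)

    def test_triple_below_pair(self, curves):
        assert (curves["triple"] <= curves["pair"] + 1e-12).all()

    def test_zero_threshold_is_interaction_efficiency(self, curves):
        # with no energy cut the pair curve is pure geometry x interaction
        row0 = curves.iloc[0]
        assert row0["threshold_kev"] == 0.0
        assert row0["pair"] > row0["triple"] > 0
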