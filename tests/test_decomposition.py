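import numpy as np
import pytest

from pseudodect.containers import Sinogram
from pseudodect.decomposition import (CalibrationSample, DecompModel,
                                      decompose_sinograms, evaluate_decomposition,
                                      fit_decomposition, load_reference_model,
                                      measure_wedge_LH, validate_wedge)
from pseudodect.phantoms import WedgeSpec
from pseudodect.physics import attenuation_coefficient
from pseudodect.simulate import simulate_wedge_projection
from pseudodect.tomography import make_geometry
from tests.test_simulate import _mono_spectrum


def _identity_model(a0=0.0, c0=0.0):
    return DecompModel(a=[a0, 1, 0, 0, 0, 0], b=[0, 0],
                       c=[c0, 0, 1, 0, 0, 0], d=[0, 0])


def _mono_samples(e_lo=50.0, e_hi=80.0):
    """Monochromatic L,H are exactly linear in (x_A, x_B) with a known matrix."""
    mu = {("al", e): attenuation_coefficient("aluminum", e) for e in (e_lo, e_hi)}
    mu.update({("ac", e): attenuation_coefficient("acrylic", e) for e in (e_lo, e_hi)})
    samples = []
    for xa in (0.0, 6.0, 12.0, 18.0, 24.0, 30.0):
        for xb in (5.0, 15.0, 25.0, 40.0):
            L = mu[("al", e_lo)] * xa + mu[("ac", e_lo)] * xb
            H = mu[("al", e_hi)] * xa + mu[("ac", e_hi)] * xb
            samples.append(CalibrationSample(xa, xb, L, H))
    return samples


class TestEvaluate:
    def test_reference_model_at_origin_returns_printed_constants(self):
        m = load_reference_model()
        xa, xb = evaluate_decomposition(m, 0.0, 0.0)
        assert float(xa) == pytest.approx(0.952, abs=1e-12)
        assert float(xb) == pytest.approx(-2.319, abs=1e-12)

    def test_pass_through_model_returns_l_and_h(self):
        xa, xb = evaluate_decomposition(_identity_model(), 3.7, 1.1)
        assert float(xa) == pytest.approx(3.7)
        assert float(xb) == pytest.approx(1.1)

    def test_vanishing_denominator_names_the_branch(self):
        bad = DecompModel(a=[0, 1, 0, 0, 0, 0], b=[-1.0, 0],
                          c=[0, 0, 1, 0, 0, 0], d=[0, 0])
        with pytest.raises(ZeroDivisionError, match="aluminum"):
            evaluate_decomposition(bad, 1.0, 0.0)


class TestFit:
    def test_monochromatic_limit_recovers_exact_linear_inversion(self):
        model = fit_decomposition(_mono_samples())
        for s in _mono_samples():
            xa, xb = evaluate_decomposition(model, s.L, s.H)
            assert float(xa) == pytest.approx(s.x_a, abs=1e-6)
            assert float(xb) == pytest.approx(s.x_b, abs=1e-6)

    def test_refit_of_model_predictions_is_self_consistent(self):
        truth = DecompModel(a=[0.5, 4.0, -2.0, 0.02, -0.04, 0.03], b=[0.01, -0.02],
                            c=[-1.0, -3.0, 9.0, 0.05, -0.2, 0.3], d=[-0.02, 0.05])
        rng = np.random.default_rng(0)
        samples = []
        while len(samples) < 60:
            L, H = rng.uniform(0.2, 3.0), rng.uniform(0.1, 2.0)
            xa, xb = evaluate_decomposition(truth, L, H)
            if xa >= 0 and xb >= 0:
                samples.append(CalibrationSample(float(xa), float(xb), L, H))
        refit = fit_decomposition(samples)
        for s in samples:
            xa, xb = evaluate_decomposition(refit, s.L, s.H)
            assert float(xa) == pytest.approx(s.x_a, abs=1e-3)
            assert float(xb) == pytest.approx(s.x_b, abs=1e-3)

    def test_duplicated_samples_leave_fit_unchanged(self):
        base = _mono_samples()
        m1 = fit_decomposition(base)
        m2 = fit_decomposition(base + base)
        L = np.array([s.L for s in base])
        H = np.array([s.H for s in base])
        np.testing.assert_allclose(evaluate_decomposition(m1, L, H)[0],
                                   evaluate_decomposition(m2, L, H)[0], atol=1e-6)
        np.testing.assert_allclose(evaluate_decomposition(m1, L, H)[1],
                                   evaluate_decomposition(m2, L, H)[1], atol=1e-6)

    def test_degenerate_designs_raise(self):
        with pytest.raises(ValueError):
            fit_decomposition(_mono_samples()[:10])
        flat = [CalibrationSample(5.0, s.x_b, s.L, s.H) for s in _mono_samples()]
        with pytest.raises(ValueError):
            fit_decomposition(flat)
        # collinear (L, H) cannot span the quadratic basis
        collinear = [CalibrationSample(s.x_a, s.x_b, 0.5 * k, 0.25 * k)
                     for k, s in enumerate(_mono_samples()[:20])]
        with pytest.raises(ValueError):
            fit_decomposition(collinear)


class TestWedgeMeasurements:
    def test_default_wedge_yields_48_samples(self):
        spec = WedgeSpec()
        proj = simulate_wedge_projection(spec, _mono_spectrum(), photons_per_ray=None)
        samples = measure_wedge_LH(proj, proj, spec)
        assert len(samples) == 48
        assert len({(s.x_a, s.x_b) for s in samples}) == 48

    def test_noise_free_mono_roi_is_exact_beer_lambert(self):
        spec = WedgeSpec()
        proj = simulate_wedge_projection(spec, _mono_spectrum(60.0),
                                         photons_per_ray=None)
        samples = measure_wedge_LH(proj, proj, spec)
        mu_al = attenuation_coefficient("aluminum", 60.0)
        mu_ac = attenuation_coefficient("acrylic", 60.0)
        for s in samples:
            assert s.L == pytest.approx(mu_al * s.x_a + mu_ac * s.x_b, rel=1e-10)

    def test_wrong_projection_shape_raises(self):
        spec = WedgeSpec()
        with pytest.raises(ValueError):
            measure_wedge_LH(np.zeros((10, 10)), np.zeros((10, 10)), spec)

    def test_noise_free_in_sample_errors_below_0p1mm(self):
        spec = WedgeSpec()
        lo = simulate_wedge_projection(spec, _mono_spectrum(50.0), None)
        hi = simulate_wedge_projection(spec, _mono_spectrum(80.0), None)
        model = fit_decomposition(measure_wedge_LH(lo, hi, spec))
        report = validate_wedge(model, lo, hi, spec)
        assert report["max_aluminum_error_mm"] < 0.1
        assert report["max_acrylic_error_mm"] < 0.1

    def test_estimates_monotone_along_each_wedge_axis(self):
        spec = WedgeSpec()
        lo = simulate_wedge_projection(spec, _mono_spectrum(50.0), None)
        hi = simulate_wedge_projection(spec, _mono_spectrum(80.0), None)
        model = fit_decomposition(measure_wedge_LH(lo, hi, spec))
        table = validate_wedge(model, lo, hi, spec)["table"]
        for _, grp in table.groupby("true_acr"):
            assert grp.sort_values("true_al").est_al.is_monotonic_increasing
        for _, grp in table.groupby("true_al"):
            assert grp.sort_values("true_acr").est_acr.is_monotonic_increasing


class TestDecomposeSinograms:
    def test_elementwise_evaluation_and_tags(self):
        geom = make_geometry(8, 1.0, 6)
        rng = np.random.default_rng(0)
        lo = Sinogram(rng.uniform(0, 2, (geom.n_views, geom.n_bins)), geom)
        hi = Sinogram(rng.uniform(0, 1, (geom.n_views, geom.n_bins)), geom)
        sxa, sxb = decompose_sinograms(_identity_model(), lo, hi)
        np.testing.assert_allclose(sxa.values, lo.values)
        np.testing.assert_allclose(sxb.values, hi.values)
        assert sxa.tag == "aluminum" and sxb.tag == "acrylic"

    def test_zero_sinograms_map_to_constant_offsets(self):
        geom = make_geometry(8, 1.0, 6)
        zero = Sinogram(np.zeros((geom.n_views, geom.n_bins)), geom)
        sxa, sxb = decompose_sinograms(_identity_model(0.7, -0.3), zero, zero)
        assert np.all(sxa.values == 0.7)
        assert np.all(sxb.values == -0.3)
        assert sxb.meta["negative_fraction"] == 1.0

    def test_geometry_mismatch_raises(self):
        g1 = make_geometry(8, 1.0, 6)
        g2 = make_geometry(8, 1.0, 7)
        with pytest.raises(ValueError):
            decompose_sinograms(_identity_model(),
                                Sinogram(np.zeros((6, g1.n_bins)), g1),
                                Sinogram(np.zeros((7, g2.n_bins)), g2))


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        m = load_reference_model()
        m.to_json(tmp_path / "m.json")
        back = DecompModel.from_json(tmp_path / "m.json")
        np.testing.assert_array_equal(back.a, m.a)
        np.testing.assert_array_equal(back.d, m.d)
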