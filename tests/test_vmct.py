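import numpy as np
import pytest

from pseudodect.containers import CTImage, Sinogram
from pseudodect.decomposition import fit_decomposition, measure_wedge_LH
from pseudodect.phantoms import WedgeSpec
from pseudodect.physics import attenuation_coefficient
from pseudodect.simulate import simulate_wedge_projection
from pseudodect.tomography import forward_project, make_geometry
from pseudodect.vmct import (IodineCalibration, calibrate_iodine_factor,
                             circle_roi_mean, complete_truncation, iodine_map,
                             reconstruct_vmct, synthesize_vm_projection,
                             vmct_image_based)
from tests.test_simulate import _mono_spectrum


def _geom(n=32, sp=2.0, views=24):
    return make_geometry(n, sp, views)


def _sino(values, geom, tag=None):
    return Sinogram(values, geom, tag)


def _mono_wedge_model(e_lo=50.0, e_hi=80.0):
    spec = WedgeSpec()
    lo = simulate_wedge_projection(spec, _mono_spectrum(e_lo), None)
    hi = simulate_wedge_projection(spec, _mono_spectrum(e_hi), None)
    return fit_decomposition(measure_wedge_LH(lo, hi, spec))


class TestVmProjection:
    def test_zero_aluminum_reduces_to_acrylic_term(self):
        geom = _geom()
        rng = np.random.default_rng(0)
        xb = rng.uniform(0, 40, (geom.n_views, geom.n_bins))
        vm = synthesize_vm_projection(_sino(np.zeros_like(xb), geom),
                                      _sino(xb, geom), 70.0)
        np.testing.assert_allclose(
            vm.values, attenuation_coefficient("acrylic", 70.0) * xb, rtol=1e-12)

    def test_exactly_linear_in_both_bases(self):
        geom = _geom()
        rng = np.random.default_rng(1)
        xa1, xa2 = rng.uniform(0, 30, (2, geom.n_views, geom.n_bins))
        xb1, xb2 = rng.uniform(0, 40, (2, geom.n_views, geom.n_bins))
        combo = synthesize_vm_projection(_sino(2 * xa1 - 0.5 * xa2, geom),
                                         _sino(2 * xb1 - 0.5 * xb2, geom), 60.0)
        parts = (2 * synthesize_vm_projection(_sino(xa1, geom), _sino(xb1, geom), 60.0).values
                 - 0.5 * synthesize_vm_projection(_sino(xa2, geom), _sino(xb2, geom), 60.0).values)
        np.testing.assert_allclose(combo.values, parts, atol=1e-12)

    def test_energy_range_and_geometry_checks(self):
        geom = _geom()
        z = _sino(np.zeros((geom.n_views, geom.n_bins)), geom)
        with pytest.raises(ValueError):
            synthesize_vm_projection(z, z, 30.0)
        other = _geom(views=25)
        z2 = _sino(np.zeros((other.n_views, other.n_bins)), other)
        with pytest.raises(ValueError):
            synthesize_vm_projection(z, z2, 60.0)

    def test_water_equivalent_ray_matches_water_attenuation(self):
        # solve the 2x2 monochromatic system so (x_A, x_B) mimics water at
        # two energies, then check the VM value against water in between
        e1, e2 = 50.0, 80.0
        m = np.array([[attenuation_coefficient("aluminum", e) ,
                       attenuation_coefficient("acrylic", e)] for e in (e1, e2)])
        path = 100.0
        rhs = np.array([attenuation_coefficient("water", e) * path for e in (e1, e2)])
        xa, xb = np.linalg.solve(m, rhs)
        geom = _geom(views=1)
        for e in (40.0, 60.0, 70.0, 100.0):
            vm = synthesize_vm_projection(
                _sino(np.full((1, geom.n_bins), xa), geom),
                _sino(np.full((1, geom.n_bins), xb), geom), e)
            water = attenuation_coefficient("water", e) * path
            assert vm.values[0, 0] == pytest.approx(water, rel=0.02)


class TestVmctReconstruction:
    def test_zero_sinogram_reconstructs_to_air(self):
        geom = _geom()
        vm = _sino(np.zeros((geom.n_views, geom.n_bins)), geom)
        img = reconstruct_vmct(vm, 70.0, n_pixels=32, spacing=2.0)
        np.testing.assert_allclose(img.values, -1000.0, atol=1e-9)

    def test_water_disk_vmct_within_20_hu(self, water_disk):
        img, r, mu = water_disk   # mu at 60 keV
        geom = make_geometry(img.shape[0], img.spacing, 180)
        sino = forward_project(img, geom)
        # express the water sinogram in basis thicknesses via the 2x2 solve
        e1, e2 = 50.0, 80.0
        m = np.array([[attenuation_coefficient("aluminum", e),
                       attenuation_coefficient("acrylic", e)] for e in (e1, e2)])
        scale = np.linalg.solve(m, [attenuation_coefficient("water", e1),
                                    attenuation_coefficient("water", e2)])
        base = sino.values / mu   # water path length per ray
        vm = synthesize_vm_projection(sino.copy_with(scale[0] * base),
                                      sino.copy_with(scale[1] * base), 60.0)
        recon = reconstruct_vmct(vm, 60.0, n_pixels=img.shape[0],
                                 spacing=img.spacing)
        xx, yy = img.pixel_centers()
        inner = xx ** 2 + yy ** 2 <= (0.7 * r) ** 2
        assert abs(recon.values[inner].mean()) < 20.0

    def test_provenance_and_energy_recorded(self):
        geom = _geom()
        vm = _sino(np.zeros((geom.n_views, geom.n_bins)), geom)
        img = reconstruct_vmct(vm, 55.0, provenance="pseudo-DECT",
                               n_pixels=32, spacing=2.0)
        assert img.provenance == "pseudo-DECT"
        assert img.energy == 55.0


class TestImageBased:
    def test_identical_water_images_give_flat_output(self):
        lo = CTImage(np.zeros((16, 16)), 1.0, "HU", "80")
        hi = CTImage(np.zeros((16, 16)), 1.0, "HU", "140Sn")
        out = vmct_image_based(lo, hi, 70.0)
        assert np.ptp(out.values) < 1e-6

    def test_registration_mismatch_raises(self):
        lo = CTImage(np.zeros((16, 16)), 1.0, "HU", "80")
        hi = CTImage(np.zeros((17, 17)), 1.0, "HU", "140Sn")
        with pytest.raises(ValueError):
            vmct_image_based(lo, hi, 70.0)


class TestIodine:
    def _recon(self, values, spacing=2.0):
        return CTImage(values, spacing, "mm/mm")

    def test_exact_proportional_data_recovers_inverse_slope(self):
        n = 64
        img = np.zeros((n, n))
        rois, k = [], 0.02
        for i, conc in enumerate((2.0, 5.0, 10.0)):
            cx = -40.0 + 40.0 * i
            xx, yy = np.meshgrid((np.arange(n) - (n - 1) / 2) * 2.0,
                                 (np.arange(n) - (n - 1) / 2) * 2.0)
            img[(xx - cx) ** 2 + (yy - 40) ** 2 <= 64] = k * conc
            rois.append(((cx, 40.0), 6.0, conc))
        cal = calibrate_iodine_factor(self._recon(img), rois, ((0.0, -40.0), 8.0))
        assert cal.factor == pytest.approx(1 / k, rel=1e-6)
        assert cal.stderr == pytest.approx(0.0, abs=1e-9)

    def test_noisy_linear_data_recovered_within_3_se(self):
        rng = np.random.default_rng(4)
        n = 96
        xx, yy = np.meshgrid((np.arange(n) - (n - 1) / 2) * 2.0,
                             (np.arange(n) - (n - 1) / 2) * 2.0)
        k = 0.025
        img = rng.normal(0, 0.004, (n, n))
        rois = []
        for i, conc in enumerate((2.19, 4.38, 8.75, 17.5, 35.0)):
            cx, cy = -70.0 + 35.0 * i, 50.0
            img[(xx - cx) ** 2 + (yy - cy) ** 2 <= 100] += k * conc
            rois.append(((cx, cy), 8.0, conc))
        cal = calibrate_iodine_factor(self._recon(img), rois, ((0.0, -50.0), 10.0))
        assert abs(cal.factor - 1 / k) <= 3 * cal.stderr
        # closed-form through-origin regression oracle
        bg = circle_roi_mean(self._recon(img), (0.0, -50.0), 10.0)
        v = np.array([circle_roi_mean(self._recon(img), c, r) - bg
                      for c, r, _ in rois])
        c = np.array([conc for *_, conc in rois])
        assert cal.factor == pytest.approx(float(c @ v / (v @ v)), rel=1e-12)

    def test_failure_modes(self):
        img = self._recon(np.zeros((32, 32)))
        with pytest.raises(ValueError):
            calibrate_iodine_factor(img, [((0, 0), 4.0, 5.0)], ((10, 10), 4.0))
        with pytest.raises(ValueError):
            IodineCalibration(-1.0, 0.1)

    def test_zero_sinogram_gives_zero_map_and_scaling_is_linear(self):
        geom = _geom()
        cal = IodineCalibration(40.0, 0.1)
        zero = iodine_map(_sino(np.zeros((geom.n_views, geom.n_bins)), geom), cal,
                          n_pixels=32, spacing=2.0)
        assert np.allclose(zero.values, 0.0)
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 5, (geom.n_views, geom.n_bins))
        one = iodine_map(_sino(vals, geom), cal, n_pixels=32, spacing=2.0)
        two = iodine_map(_sino(2 * vals, geom), cal, n_pixels=32, spacing=2.0)
        np.testing.assert_allclose(two.values, 2 * one.values, atol=1e-9)


class TestTruncationCompletion:
    def test_fills_only_outside_the_fov_mask(self):
        n = 32
        lo = CTImage(np.full((n, n), 7.0), 10.0, "HU", "80")
        hi = CTImage(np.full((n, n), -1000.0), 10.0, "HU", "140Sn",
                     {"fov_mask_mm": 160.0})
        xx, yy = hi.pixel_centers()
        inside = xx ** 2 + yy ** 2 <= 80.0 ** 2
        hi.values[inside] = 3.0
        out = complete_truncation(hi, lo)
        assert np.all(out.values[inside] == 3.0)
        assert np.all(out.values[~inside] == 7.0)
        assert "fov_mask_mm" not in out.meta

    def test_no_mask_is_identity_and_mismatch_raises(self):
        hi = CTImage(np.zeros((8, 8)), 1.0, "HU", "140Sn")
        lo = CTImage(np.zeros((8, 8)), 1.0, "HU", "80")
        assert complete_truncation(hi, lo) is hi
        hi2 = CTImage(np.zeros((8, 8)), 1.0, "HU", "140Sn", {"fov_mask_mm": 4.0})
        lo2 = CTImage(np.zeros((9, 9)), 1.0, "HU", "80")
        with pytest.raises(ValueError):
            complete_truncation(hi2, lo2)
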