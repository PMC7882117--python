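"""X-ray physics: attenuation tables, tube spectra, and HU <-> mm^-1 conversion.

The material table ships as a CSV fixture of mass attenuation coefficients
(cm^2/g) on a coarse NIST-style energy grid with duplicated points at K-edges;
it is resampled by log-log interpolation onto a 1-keV working grid spanning
10-150 keV.  Tissue surrogates of the electron-density phantoms are modeled as
water-like mixtures at their nominal densities, and iodine solutions as water
plus elemental iodine by mass (dilute mixture rule), so an ``c`` mg/ml syringe
attenuates as ``mu_water(E) + (c/1000) * (mu/rho)_iodine(E)`` per cm.

Tube spectra use an analytic tungsten-anode model: Kramers bremsstrahlung
shaped by inherent aluminum filtration (default 9 mm Al-equivalent, matching
the beam quality of a clinical CT bow-tie/flat-filter stack: effective energy
of the 80-kVp beam about 49 keV over a 20-cm water path), tungsten K-lines
above their excitation threshold, and an optional tin filter for the
high-energy beam.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "MaterialTable", "Spectrum", "EnergyCalibration", "default_table",
    "attenuation_coefficient", "generate_spectrum", "hu_to_mu", "mu_to_hu",
    "iodine_solution_name", "IODINE_CONCENTRATIONS_MG_ML",
]

ENERGY_GRID_KEV = np.arange(10.0, 151.0)  # 1-keV working grid

#: Syringe concentrations used throughout the calibration/evaluation phantoms.
IODINE_CONCENTRATIONS_MG_ML = (2.19, 4.38, 8.75, 17.5, 35.0)

#: Tissue surrogates: nominal density (g/cm^3), water-like composition.
TISSUE_DENSITIES = {
    "soft_tissue": 1.020,
    "adipose": 0.960,
    "breast": 0.991,
    "muscle": 1.062,
    "liver": 1.072,
    "plastic_water": 1.016,
    "lung_inhale": 0.195,
    "lung_exhale": 0.510,
    "trabecular_bone": 1.161,
    "dense_bone": 1.530,
    "bolus": 1.000,
}


def iodine_solution_name(conc_mg_ml: float) -> str:
    return f"iodine_{conc_mg_ml:g}mgml"


def _loglog_resample(e_src, v_src, e_dst):
    return np.exp(np.interp(np.log(e_dst), np.log(e_src), np.log(v_src)))


class MaterialTable:
    """Linear attenuation lookup for base materials, tissue surrogates and
    iodine solutions, on the 1-keV working grid."""

    def __init__(self) -> None:
        self.energies = ENERGY_GRID_KEV
        self._density: dict[str, float] = {}
        self._mass_atten: dict[str, np.ndarray] = {}  # cm^2/g on working grid
        self._load_csv()
        self._register_derived()

    def _load_csv(self) -> None:
        raw: dict[str, list[tuple[float, float]]] = {}
        dens: dict[str, float] = {}
        text = resources.files("pseudodect.data").joinpath("attenuation.csv").read_text()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("material,"):
                continue
            name, d, e, v = line.split(",")
            raw.setdefault(name, []).append((float(e), float(v)))
            dens[name] = float(d)
        for name, rows in raw.items():
            rows.sort()
            e = np.array([r[0] for r in rows])
            v = np.array([r[1] for r in rows])
            if np.any(np.diff(e) <= 0) and not np.all(np.diff(e) > 0):
                raise ValueError(f"non-increasing energy grid for {name}")
            self._density[name] = dens[name]
            self._mass_atten[name] = _loglog_resample(e, v, self.energies)

    def _register_derived(self) -> None:
        water = self._mass_atten["water"]
        for name, rho in TISSUE_DENSITIES.items():
            self._density[name] = rho
            self._mass_atten[name] = water.copy()
        iod = self._mass_atten["iodine"]
        for c in IODINE_CONCENTRATIONS_MG_ML:
            name = iodine_solution_name(c)
            rho = 1.0 + c / 1000.0          # additive mass, dilute solution
            w_i = (c / 1000.0) / rho
            self._density[name] = rho
            self._mass_atten[name] = (1.0 - w_i) * water + w_i * iod

    # -- queries ----------------------------------------------------------

    @property
    def materials(self) -> list[str]:
        return sorted(self._mass_atten)

    def density(self, material: str) -> float:
        self._check(material)
        return self._density[material]

    def mass_attenuation(self, material: str, energy_kev) -> np.ndarray:
        """Mass attenuation coefficient (cm^2/g), log-log interpolated on the
        1-keV working grid."""
        self._check(material)
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < self.energies[0]) or np.any(e > self.energies[-1]):
            raise ValueError(f"energy outside the tabulated 10-150 keV range: {energy_kev}")
        out = _loglog_resample(self.energies, self._mass_atten[material], e)
        return out if out.ndim else float(out)

    def mu(self, material: str, energy_kev) -> np.ndarray:
        """Linear attenuation coefficient in mm^-1."""
        return self.density(material) * self.mass_attenuation(material, energy_kev) * 0.1

    def _check(self, material: str) -> None:
        if material not in self._mass_atten:
            raise KeyError(f"unknown material {material!r}; known: {self.materials}")


@functools.lru_cache(maxsize=1)
def default_table() -> MaterialTable:
    return MaterialTable()


def attenuation_coefficient(material: str, energy_kev: float) -> float:
    """Linear attenuation coefficient (mm^-1) of a named material."""
    return float(default_table().mu(material, energy_kev))


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    kvp: int
    filtration: str
    energies: np.ndarray       # keV, 1-keV bins
    fluence: np.ndarray        # relative photon fluence, sums to 1

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.fluence = np.asarray(self.fluence, dtype=float)
        if np.any(self.fluence < 0):
            raise ValueError("negative fluence")
        if abs(self.fluence.sum() - 1.0) > 1e-12:
            raise ValueError("fluence must be normalized to 1")
        if np.any(self.fluence[self.energies > self.kvp] != 0):
            raise ValueError("fluence above the tube potential must be zero")

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.fluence))

    def filtered(self, material: str, thickness_mm: float, label: str = "") -> "Spectrum":
        mu = default_table().mu(material, self.energies)
        f = self.fluence * np.exp(-mu * thickness_mm)
        return Spectrum(self.kvp, self.filtration + (label or f"+{thickness_mm}mm {material}"),
                        self.energies, f / f.sum())


# Tungsten K-series lines (keV, relative strength within the series).
_W_K_LINES = ((58.0, 0.30), (59.3, 0.50), (67.2, 0.15), (69.1, 0.05))
_W_K_EDGE = 69.5
_K_LINE_FRACTION = 0.08   # of total filtered fluence, split across the lines


def generate_spectrum(kvp: int, tin_filter: bool = False, *,
                      tin_mm: float = 0.4, inherent_al_mm: float = 9.0) -> Spectrum:
    """Polychromatic tube spectrum at 80, 120 or 140 kVp, 1-keV bins.

    ``tin_filter`` models the Sn prefilter of the high-energy beam of a
    dual-source acquisition; it is only meaningful at 140 kVp.
    """
    if kvp not in (80, 120, 140):
        raise ValueError(f"unsupported tube potential {kvp}; expected 80, 120 or 140")
    if tin_filter and kvp != 140:
        raise ValueError("the tin prefilter applies to the 140-kVp beam only")
    table = default_table()
    e = ENERGY_GRID_KEV
    n = np.where(e <= kvp, np.maximum(kvp - e, 0.0) / e, 0.0)  # Kramers
    n *= np.exp(-table.mu("aluminum", e) * inherent_al_mm)
    if kvp > _W_K_EDGE:
        lines = np.zeros_like(n)
        for le, w in _W_K_LINES:
            idx = int(round(le)) - 10
            lines[idx] += w * np.exp(-table.mu("aluminum", e[idx]) * inherent_al_mm)
        n += _K_LINE_FRACTION * n.sum() * lines / lines.sum()
    label = f"{kvp} kVp, {inherent_al_mm} mm Al inherent"
    if tin_filter:
        n *= np.exp(-table.mu("tin", e) * tin_mm)
        label += f", {tin_mm} mm Sn"
    return Spectrum(kvp, label, e, n / n.sum())


# ---------------------------------------------------------------------------
# HU <-> mu
# ---------------------------------------------------------------------------

@dataclass
class EnergyCalibration:
    """Effective energies (keV) used to convert scanner HU to mm^-1.

    Defaults are derived from the package's own tube spectra: the energy whose
    water attenuation matches the effective attenuation of a 20-cm water path
    under each beam, so uniform water reconstructs near 0 HU.  They are
    conventions of the simulated scanner, monotone in kVp and below the
    respective tube potentials."""

    effective_kev: dict[str, float] = field(
        default_factory=lambda: {"80": 49.4, "120": 59.3, "140Sn": 85.8, "140": 64.1})

    def __post_init__(self) -> None:
        for tag, e in self.effective_kev.items():
            kvp = float(tag.rstrip("Sn"))
            if not (10.0 < e < kvp):
                raise ValueError(f"effective energy {e} keV invalid for {tag} kVp")

    def effective_energy(self, tag) -> float:
        key = str(tag)
        if key not in self.effective_kev:
            raise KeyError(f"no effective energy registered for {tag!r}")
        return self.effective_kev[key]


DEFAULT_CALIBRATION = EnergyCalibration()


def _mu_water_at(tag, calibration: EnergyCalibration) -> float:
    e = calibration.effective_energy(tag)
    return attenuation_coefficient("water", e)


def hu_to_mu(image, calibration: EnergyCalibration = DEFAULT_CALIBRATION):
    """Convert an HU-tagged CTImage to linear attenuation (mm^-1):
    mu = mu_water(E_eff) * (1 + HU/1000)."""
    if image.units != "HU":
        raise ValueError(f"expected an HU image, got units {image.units!r}")
    if image.energy is None:
        raise ValueError("image carries no energy tag")
    mu_w = _mu_water_at(image.energy, calibration)
    return image.copy_with(mu_w * (1.0 + image.values / 1000.0), units="mm^-1")


def mu_to_hu(image, calibration: EnergyCalibration = DEFAULT_CALIBRATION):
    """Exact inverse of :func:`hu_to_mu`."""
    if image.units != "mm^-1":
        raise ValueError(f"expected a mm^-1 image, got units {image.units!r}")
    if image.energy is None:
        raise ValueError("image carries no energy tag")
    mu_w = _mu_water_at(image.energy, calibration)
    return image.copy_with(image.values / mu_w * 1000.0 - 1000.0, units="HU")
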