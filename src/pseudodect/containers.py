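"""Core in-memory containers shared by all pipeline stages.

A ``CTImage`` is a single 2-D axial slice with isotropic pixel spacing; the
``units`` tag distinguishes Hounsfield units from linear attenuation (mm^-1)
and the ``energy`` tag records the acquisition (kVp string such as ``"80"``
or ``"140Sn"``) or, for virtual monochromatic images, a photon energy in keV.

Sinograms are parallel-beam line-integral stacks: ``values[view, bin]`` holds
either ``-ln(I/I0)`` (polychromatic) or an exact line integral of mm^-1 over
mm (monochromatic / basis-material thickness).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["CTImage", "Geometry", "Sinogram", "save_image", "load_image"]


@dataclass
class CTImage:
    values: np.ndarray          # (ny, nx)
    spacing: float              # mm per pixel, isotropic
    units: str                  # "HU" or "mm^-1" or derived ("mm/mm", "mg/ml")
    energy: str | float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("CTImage expects a 2-D array")
        if self.spacing <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy_with(self, values: np.ndarray, *, units: str | None = None,
                  energy=None, **meta) -> "CTImage":
        merged = dict(self.meta)
        merged.update(meta)
        return CTImage(values, self.spacing, units or self.units,
                       self.energy if energy is None else energy, merged)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates (mm) of pixel centers, image centered on origin."""
        ny, nx = self.values.shape
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.spacing
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.spacing
        return np.meshgrid(x, y)


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam acquisition geometry: views uniformly spaced on [0, pi)."""

    n_views: int
    n_bins: int
    pitch: float  # detector bin spacing, mm

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise ValueError("need at least one view")
        if self.pitch <= 0:
            raise ValueError("detector pitch must be positive")

    @property
    def angles(self) -> np.ndarray:
        return np.linspace(0.0, np.pi, self.n_views, endpoint=False)

    @property
    def bin_positions(self) -> np.ndarray:
        """Signed detector coordinates (mm) of bin centers."""
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0) * self.pitch


@dataclass
class Sinogram:
    values: np.ndarray        # (n_views, n_bins)
    geometry: Geometry
    tag: str | float | None = None   # kVp, keV, or basis-material name
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        expect = (self.geometry.n_views, self.geometry.n_bins)
        if self.values.shape != expect:
            raise ValueError(f"sinogram shape {self.values.shape} != geometry {expect}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")

    def copy_with(self, values: np.ndarray, *, tag=None, **meta) -> "Sinogram":
        merged = dict(self.meta)
        merged.update(meta)
        return Sinogram(values, self.geometry, self.tag if tag is None else tag, merged)


def save_image(img: CTImage, path: str | Path) -> None:
    """Persist as a portable array container plus a JSON sidecar."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), img.values)
    sidecar = {"spacing_mm": img.spacing, "units": img.units,
               "energy": img.energy, "meta": img.meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_image(path: str | Path) -> CTImage:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return CTImage(values, sidecar["spacing_mm"], sidecar["units"],
                   sidecar.get("energy"), sidecar.get("meta", {}))
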