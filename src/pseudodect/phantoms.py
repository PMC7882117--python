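"""Digital phantoms: calibration disks, evaluation ellipses, and step wedges.

The calibration phantom is an 18-cm soft-tissue-equivalent disk carrying four
tissue rods (adipose/breast/muscle/liver) and five 2-cm iodine syringes
(2.19-35 mg/ml); water-equivalent bolus annuli enlarge it to 23/28/33/38 cm.
The evaluation phantoms are 33 x 27 cm ellipses: Ephan1 holds 17 tissue rods
(including lung and bone surrogates), Ephan2 holds 12 tissue rods plus the
five iodine syringes.

The calibration step wedge pairs a 6-step aluminum wedge (0-30 mm) with an
8-step acrylic wedge (5-40 mm) stacked orthogonally, so a single projection
exposes all 48 thickness combinations as rectangular regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .physics import IODINE_CONCENTRATIONS_MG_ML, iodine_solution_name

__all__ = ["Insert", "PhantomSpec", "MaterialMap", "WedgeSpec",
           "build_calibration_phantom", "build_evaluation_phantom",
           "rasterize", "build_step_wedge", "wedge_roi_grid"]

ROD_RADIUS_MM = 15.0
SYRINGE_RADIUS_MM = 10.0
CORE_RADIUS_MM = 90.0
BOLUS_LAYER_MM = 25.0
CALIBRATION_SIZES_CM = (18, 23, 28, 33, 38)


@dataclass(frozen=True)
class Insert:
    cx: float       # mm, phantom-centered coordinates
    cy: float
    radius: float
    material: str


@dataclass
class PhantomSpec:
    name: str
    shape: str                       # "circle" or "ellipse"
    semi_axes: tuple[float, float]   # (a, b) mm; equal for a circle
    base_material: str
    inserts: list[Insert] = field(default_factory=list)
    annuli: list[tuple[float, str]] = field(default_factory=list)  # (outer radius, material)
    background_roi: tuple[float, float, float] = (0.0, 0.0, 8.0)   # cx, cy, radius

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        for ins in self.inserts:
            if (ins.cx / (a - ins.radius)) ** 2 + (ins.cy / (b - ins.radius)) ** 2 > 1.0:
                raise ValueError(f"insert {ins} extends outside the phantom outline")
        for i, p in enumerate(self.inserts):
            for q in self.inserts[i + 1:]:
                if np.hypot(p.cx - q.cx, p.cy - q.cy) < p.radius + q.radius:
                    raise ValueError(f"overlapping inserts {p} / {q}")

    @property
    def outer_radius(self) -> float:
        r = max(self.semi_axes)
        return max([r] + [ra for ra, _ in self.annuli])

    def iodine_inserts(self) -> list[tuple[Insert, float]]:
        out = []
        for ins in self.inserts:
            if ins.material.startswith("iodine_"):
                conc = float(ins.material.removeprefix("iodine_").removesuffix("mgml"))
                out.append((ins, conc))
        return out


@dataclass
class MaterialMap:
    """Anti-aliased rasterization: per-material area fractions on the grid."""

    fractions: dict[str, np.ndarray]
    spacing: float

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        total = sum(self.fractions.values())
        if not np.allclose(total, 1.0, atol=1e-6):
            raise ValueError("per-pixel material fractions must sum to 1")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.fractions.values())).shape

    def area_mm2(self, material: str) -> float:
        return float(self.fractions[material].sum()) * self.spacing ** 2


def _ring(n: int, radius: float, phase_deg: float = 0.0):
    ang = np.deg2rad(phase_deg + 360.0 * np.arange(n) / n)
    return radius * np.cos(ang), radius * np.sin(ang)


def build_calibration_phantom(size_cm: int) -> PhantomSpec:
    """Calibration phantom at one of the five diameters (18/23/28/33/38 cm)."""
    if size_cm not in CALIBRATION_SIZES_CM:
        raise ValueError(f"size {size_cm} cm not in {CALIBRATION_SIZES_CM}")
    xs, ys = _ring(9, 60.0)
    inserts = [Insert(xs[k], ys[k], SYRINGE_RADIUS_MM, iodine_solution_name(c))
               for k, c in enumerate(IODINE_CONCENTRATIONS_MG_ML)]
    for k, mat in enumerate(("adipose", "breast", "muscle", "liver")):
        inserts.append(Insert(xs[5 + k], ys[5 + k], ROD_RADIUS_MM, mat))
    n_layers = (size_cm - 18) // 5
    annuli = [(CORE_RADIUS_MM + BOLUS_LAYER_MM * (k + 1), "bolus")
              for k in range(n_layers)][::-1]
    return PhantomSpec(f"Cphan_{size_cm}cm", "circle",
                       (CORE_RADIUS_MM, CORE_RADIUS_MM), "soft_tissue",
                       inserts, annuli, background_roi=(0.0, 0.0, 10.0))


_EPHAN1_INNER = ("lung_inhale", "lung_exhale", "adipose", "breast",
                 "muscle", "liver", "trabecular_bone", "dense_bone")
_EPHAN1_OUTER = ("adipose", "breast", "plastic_water", "muscle",
                 "liver", "trabecular_bone", "dense_bone", "lung_exhale")
_EPHAN2_INNER_RODS = ("adipose", "muscle", "liver")
_EPHAN2_OUTER = ("breast", "plastic_water", "lung_exhale", "trabecular_bone",
                 "adipose", "muscle", "liver", "breast")


def build_evaluation_phantom(which: str) -> PhantomSpec:
    """Ephan1 (17 tissue rods) or Ephan2 (12 rods + 5 iodine syringes),
    330 x 270 mm ellipse."""
    if which not in ("Ephan1", "Ephan2"):
        raise ValueError(f"unknown evaluation phantom {which!r}")
    xi, yi = _ring(8, 60.0)
    xo = 125.0 * np.cos(np.deg2rad(360.0 * np.arange(8) / 8 + 22.5))
    yo = 95.0 * np.sin(np.deg2rad(360.0 * np.arange(8) / 8 + 22.5))
    inserts: list[Insert] = []
    if which == "Ephan1":
        inserts.append(Insert(0.0, 0.0, ROD_RADIUS_MM, "plastic_water"))
        inserts += [Insert(xi[k], yi[k], ROD_RADIUS_MM, m)
                    for k, m in enumerate(_EPHAN1_INNER)]
        inserts += [Insert(xo[k], yo[k], ROD_RADIUS_MM, m)
                    for k, m in enumerate(_EPHAN1_OUTER)]
        bg = (0.0, 30.0, 8.0)
    else:
        inserts += [Insert(xi[k], yi[k], SYRINGE_RADIUS_MM, iodine_solution_name(c))
                    for k, c in enumerate(IODINE_CONCENTRATIONS_MG_ML)]
        inserts += [Insert(xi[5 + k], yi[5 + k], ROD_RADIUS_MM, m)
                    for k, m in enumerate(_EPHAN2_INNER_RODS)]
        inserts.append(Insert(0.0, 0.0, ROD_RADIUS_MM, "plastic_water"))
        inserts += [Insert(xo[k], yo[k], ROD_RADIUS_MM, m)
                    for k, m in enumerate(_EPHAN2_OUTER)]
        bg = (0.0, 32.0, 8.0)
    return PhantomSpec(which, "ellipse", (165.0, 135.0), "soft_tissue",
                       inserts, background_roi=bg)


def rasterize(spec: PhantomSpec, n_pixels: int, spacing: float,
              supersample: int = 4) -> MaterialMap:
    """Anti-aliased material map: labels are painted on a supersampled grid
    (outermost annulus first, then the base outline, then inserts) and averaged
    into per-pixel area fractions."""
    half = n_pixels * spacing / 2.0
    if spec.outer_radius > half:
        raise ValueError(f"phantom (radius {spec.outer_radius} mm) exceeds the "
                         f"{2 * half:.0f}-mm grid")
    ss = supersample
    n_sub = n_pixels * ss
    c = (np.arange(n_sub) + 0.5) * (spacing / ss) - half
    xx, yy = np.meshgrid(c, c)

    materials = ["air"]
    label = np.zeros((n_sub, n_sub), dtype=np.int16)

    def paint(mask: np.ndarray, material: str) -> None:
        if material not in materials:
            materials.append(material)
        label[mask] = materials.index(material)

    for radius, mat in sorted(spec.annuli, reverse=True):
        paint(xx ** 2 + yy ** 2 <= radius ** 2, mat)
    a, b = spec.semi_axes
    paint((xx / a) ** 2 + (yy / b) ** 2 <= 1.0, spec.base_material)
    for ins in spec.inserts:
        paint((xx - ins.cx) ** 2 + (yy - ins.cy) ** 2 <= ins.radius ** 2, ins.material)

    fractions: dict[str, np.ndarray] = {}
    for code, mat in enumerate(materials):
        hit = (label == code).astype(np.float64)
        frac = hit.reshape(n_pixels, ss, n_pixels, ss).mean(axis=(1, 3))
        if frac.any():
            fractions[mat] = fractions.get(mat, 0.0) + frac
    return MaterialMap(fractions, spacing)


# ---------------------------------------------------------------------------
# Step wedge
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WedgeSpec:
    """Orthogonal aluminum/acrylic step-wedge stack in the projection plane."""

    aluminum_mm: tuple = (0.0, 6.0, 12.0, 18.0, 24.0, 30.0)
    acrylic_mm: tuple = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0)
    step_px: int = 24
    roi_px: int = 12

    def __post_init__(self) -> None:
        for seq in (self.aluminum_mm, self.acrylic_mm):
            if any(t < 0 for t in seq) or any(np.diff(seq) <= 0):
                raise ValueError("step thicknesses must be non-negative and increasing")
        if self.roi_px > self.step_px - 4:
            raise ValueError("ROI must keep a >=2 pixel margin inside each step")

    @property
    def n_rois(self) -> int:
        return len(self.aluminum_mm) * len(self.acrylic_mm)


def build_step_wedge(spec: WedgeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Projection-domain thickness maps (x_A, x_B) in mm.

    Aluminum steps run along axis 0 and acrylic steps along axis 1, so every
    (x_A, x_B) pair appears as a ``step_px`` x ``step_px`` rectangle."""
    al = np.repeat(np.asarray(spec.aluminum_mm, float), spec.step_px)
    ac = np.repeat(np.asarray(spec.acrylic_mm, float), spec.step_px)
    x_a = np.broadcast_to(al[:, None], (al.size, ac.size)).copy()
    x_b = np.broadcast_to(ac[None, :], (al.size, ac.size)).copy()
    return x_a, x_b


def wedge_roi_grid(spec: WedgeSpec):
    """Centered ROI slices for every thickness combination.

    Yields (i_aluminum, j_acrylic, slice_u, slice_v); ROI centers sit at step
    centers, at least 2 pixels clear of step boundaries."""
    off = (spec.step_px - spec.roi_px) // 2
    for i in range(len(spec.aluminum_mm)):
        for j in range(len(spec.acrylic_mm)):
            u0 = i * spec.step_px + off
            v0 = j * spec.step_px + off
            yield i, j, slice(u0, u0 + spec.roi_px), slice(v0, v0 + spec.roi_px)
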