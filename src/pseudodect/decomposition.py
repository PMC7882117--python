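"""Projection-domain two-material (aluminum/acrylic) decomposition.

Each dual-energy ray pair (L, H) = (-ln I/I0 at 80 kVp, at Sn-filtered
140 kVp) is mapped to equivalent basis-material thicknesses by a pair of
rational functions

    x_A = (a0 + a1 L + a2 H + a3 L^2 + a4 LH + a5 H^2) / (1 + b0 L + b1 H)
    x_B = (c0 + c1 L + c2 H + c3 L^2 + c4 LH + c5 H^2) / (1 + d0 L + d1 H)

whose 16 coefficients absorb the beam-spectrum characteristics.  They are
parameterized by minimizing the absolute thickness error over step-wedge
calibration measurements (48 ROI means covering a 6 x 8 thickness grid): a
robust soft-L1 loss (absolute error outside a 0.1-mm quadratic core, which
keeps the objective smooth) minimized by trust-region least squares, started
from the ordinary least-squares solution of the linearized residual
``num - x * den``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .containers import Sinogram
from .phantoms import WedgeSpec, wedge_roi_grid

__all__ = ["DecompModel", "CalibrationSample", "evaluate_decomposition",
           "fit_decomposition", "measure_wedge_LH", "decompose_sinograms",
           "validate_wedge", "load_reference_model"]

_DEN_EPS = 1e-6


@dataclass(frozen=True)
class CalibrationSample:
    x_a: float   # true aluminum thickness, mm
    x_b: float   # true acrylic thickness, mm
    L: float     # measured low-energy projection value
    H: float     # measured high-energy projection value

    def __post_init__(self) -> None:
        if self.x_a < 0 or self.x_b < 0:
            raise ValueError("thicknesses must be non-negative")


@dataclass
class DecompModel:
    a: np.ndarray    # aluminum numerator (6,)
    b: np.ndarray    # aluminum denominator (2,)
    c: np.ndarray    # acrylic numerator (6,)
    d: np.ndarray    # acrylic denominator (2,)
    domain: dict = field(default_factory=dict)   # calibrated (L, H) ranges
    meta: dict = field(default_factory=dict)     # spectra used, fit residuals

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, float)
        self.b = np.asarray(self.b, float)
        self.c = np.asarray(self.c, float)
        self.d = np.asarray(self.d, float)
        if self.a.shape != (6,) or self.c.shape != (6,) or \
           self.b.shape != (2,) or self.d.shape != (2,):
            raise ValueError("expected 6+2 coefficients per branch")
        if not all(np.all(np.isfinite(v)) for v in (self.a, self.b, self.c, self.d)):
            raise ValueError("non-finite coefficients")

    def to_json(self, path: str | Path) -> None:
        payload = {"a": self.a.tolist(), "b": self.b.tolist(),
                   "c": self.c.tolist(), "d": self.d.tolist(),
                   "domain": self.domain, "meta": self.meta}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DecompModel":
        p = json.loads(Path(path).read_text())
        return cls(p["a"], p["b"], p["c"], p["d"], p.get("domain", {}),
                   p.get("meta", {}))


def load_reference_model() -> DecompModel:
    """Example model parameterized on a clinical dual-source scanner's
    step-wedge projections (shipped fixture; used in docs and desk checks)."""
    p = json.loads(resources.files("pseudodect.data")
                   .joinpath("reference_decomposition_model.json").read_text())
    return DecompModel(p["a"], p["b"], p["c"], p["d"], p.get("domain", {}),
                       p.get("meta", {}))


def _basis(L: np.ndarray, H: np.ndarray) -> np.ndarray:
    one = np.ones_like(L)
    return np.stack([one, L, H, L * L, L * H, H * H], axis=-1)


def _branch_eval(num_c, den_c, L, H, branch: str) -> np.ndarray:
    num = _basis(L, H) @ num_c
    den = 1.0 + den_c[0] * L + den_c[1] * H
    if np.any(np.abs(den) < _DEN_EPS):
        raise ZeroDivisionError(
            f"{branch} branch denominator vanishes inside the evaluated (L, H) set")
    return num / den


def evaluate_decomposition(model: DecompModel, L, H) -> tuple[np.ndarray, np.ndarray]:
    """Equivalent aluminum and acrylic thicknesses (mm) for projection values
    (L, H); accepts scalars or arrays."""
    L = np.asarray(L, float)
    H = np.asarray(H, float)
    x_a = _branch_eval(model.a, model.b, L, H, "aluminum")
    x_b = _branch_eval(model.c, model.d, L, H, "acrylic")
    return x_a, x_b


def _fit_branch(x: np.ndarray, L: np.ndarray, H: np.ndarray,
                f_scale_mm: float = 0.1, max_iter: int = 2000):
    """Absolute-error fit of one rational branch.

    Soft-L1 robust loss (quadratic only inside ``f_scale_mm``) minimized by
    trust-region least squares, initialized from the linear least-squares
    solution of ``num - x * den = 0``."""
    phi = _basis(L, H)                                # (n, 6)
    rank = np.linalg.matrix_rank(phi)
    if rank < 6:
        raise ValueError(f"degenerate calibration design (basis rank {rank} < 6); "
                         "need (L, H) variation spanning both projection axes")
    # In the monochromatic limit the denominator columns x*L, x*H lie in the
    # span of the quadratic basis, so the full design is rank-deficient by
    # construction; lstsq returns the minimum-norm solution (denominator -> 1).
    design = np.hstack([phi, -(x * L)[:, None], -(x * H)[:, None]])  # (n, 8)
    theta0, *_ = np.linalg.lstsq(design, x, rcond=None)

    def residual(theta):
        den = 1.0 + theta[6] * L + theta[7] * H
        safe = np.where(np.abs(den) < 0.05, np.where(den < 0, -0.05, 0.05), den)
        return (phi @ theta[:6]) / safe - x

    fit = least_squares(residual, theta0, loss="soft_l1", f_scale=f_scale_mm,
                        max_nfev=max_iter, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not fit.success:
        raise RuntimeError(f"decomposition fit did not converge: {fit.message}")
    if not np.all(np.isfinite(fit.x)):
        raise RuntimeError("decomposition fit produced non-finite coefficients")
    return fit.x[:6], fit.x[6:], residual(fit.x)


def fit_decomposition(samples: list[CalibrationSample]) -> DecompModel:
    """Parameterize both branches from calibration samples by absolute-error
    minimization (the two branches are fit independently)."""
    if len(samples) < 16:
        raise ValueError("need at least 16 calibration samples")
    x_a = np.array([s.x_a for s in samples])
    x_b = np.array([s.x_b for s in samples])
    L = np.array([s.L for s in samples])
    H = np.array([s.H for s in samples])
    if len(np.unique(x_a)) < 2 or len(np.unique(x_b)) < 2:
        raise ValueError("calibration must span at least two distinct "
                         "thicknesses of each basis material")
    a, b, res_a = _fit_branch(x_a, L, H)
    c, d, res_b = _fit_branch(x_b, L, H)
    domain = {"L": [float(L.min()), float(L.max())],
              "H": [float(H.min()), float(H.max())]}
    meta = {"n_samples": len(samples),
            "residual_aluminum_mm": {"mean_abs": float(np.mean(np.abs(res_a))),
                                     "max_abs": float(np.max(np.abs(res_a)))},
            "residual_acrylic_mm": {"mean_abs": float(np.mean(np.abs(res_b))),
                                    "max_abs": float(np.max(np.abs(res_b)))}}
    return DecompModel(a, b, c, d, domain, meta)


def measure_wedge_LH(proj_low: np.ndarray, proj_high: np.ndarray,
                     spec: WedgeSpec) -> list[CalibrationSample]:
    """ROI means over every thickness combination of the wedge projections."""
    expect = (len(spec.aluminum_mm) * spec.step_px,
              len(spec.acrylic_mm) * spec.step_px)
    for name, proj in (("low", proj_low), ("high", proj_high)):
        if proj.shape != expect:
            raise ValueError(f"{name}-energy projection shape {proj.shape} does "
                             f"not cover the wedge layout {expect}")
    samples = []
    for i, j, su, sv in wedge_roi_grid(spec):
        samples.append(CalibrationSample(
            spec.aluminum_mm[i], spec.acrylic_mm[j],
            float(proj_low[su, sv].mean()), float(proj_high[su, sv].mean())))
    return samples


def decompose_sinograms(model: DecompModel, sino_low: Sinogram,
                        sino_high: Sinogram) -> tuple[Sinogram, Sinogram]:
    """Ray-wise decomposition of matched dual-energy sinograms into
    basis-material thickness sinograms (mm).  Negative thicknesses are kept
    (not clipped) and their fraction is reported in the metadata."""
    if sino_low.geometry != sino_high.geometry:
        raise ValueError("low/high sinogram geometries differ")
    x_a, x_b = evaluate_decomposition(model, sino_low.values, sino_high.values)
    neg_a = float(np.mean(x_a < 0))
    neg_b = float(np.mean(x_b < 0))
    return (sino_low.copy_with(x_a, tag="aluminum", negative_fraction=neg_a),
            sino_low.copy_with(x_b, tag="acrylic", negative_fraction=neg_b))


def validate_wedge(model: DecompModel, proj_low: np.ndarray,
                   proj_high: np.ndarray, spec: WedgeSpec) -> dict:
    """Compare decomposition estimates on wedge ROIs with the known (caliper)
    thicknesses.

    Returns per-thickness mean absolute errors: for each aluminum step the
    error is averaged over the acrylic steps, and vice versa (one number per
    thickness)."""
    samples = measure_wedge_LH(proj_low, proj_high, spec)
    rows = []
    for s in samples:
        ea, eb = evaluate_decomposition(model, s.L, s.H)
        rows.append((s.x_a, s.x_b, float(ea), float(eb)))
    df = pd.DataFrame(rows, columns=["true_al", "true_acr", "est_al", "est_acr"])
    df["err_al"] = (df.est_al - df.true_al).abs()
    df["err_acr"] = (df.est_acr - df.true_acr).abs()
    al = df.groupby("true_al").err_al.mean()
    acr = df.groupby("true_acr").err_acr.mean()
    return {"table": df,
            "aluminum_mae_mm": al,
            "acrylic_mae_mm": acr,
            "max_aluminum_error_mm": float(al.max()),
            "max_acrylic_error_mm": float(acr.max())}
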