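"""Parallel-beam tomography: Siddon ray tracing, forward/back projection, FBP.

Conventions: images are (ny, nx) arrays of linear attenuation in mm^-1 with
isotropic pixel spacing and the grid centered on the origin; row index i
increases with y, column j with x.  A view at angle theta integrates along the
unit direction (-sin t, cos t); detector coordinate s is the signed distance of
the ray from the origin, so a ray is p(t) = (s cos t, s sin t) + t * dir.

The exact per-pixel intersection lengths come from Siddon's incremental
traversal; the same traversal drives the batched forward projector and its
adjoint (numba-compiled), which keeps <proj(x), y> = <x, backproject(y)> to
rounding error.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .containers import CTImage, Geometry, Sinogram

__all__ = ["siddon_trace", "forward_project", "backproject", "fbp_reconstruct",
           "make_geometry"]

_EPS = 1e-12


def siddon_trace(point, direction, n_pixels, spacing):
    """Trace one ray through a centered square grid.

    Parameters
    ----------
    point, direction : (x, y) pairs in mm; direction need not be normalized.
    n_pixels : grid size N (N x N pixels).
    spacing : pixel size in mm.

    Returns
    -------
    list of ((ix, iy), length_mm) for every pixel the ray traverses, ordered
    along the ray.  A ray that misses the grid returns an empty list.
    """
    d = np.asarray(direction, dtype=float)
    norm = np.hypot(d[0], d[1])
    if norm == 0:
        raise ValueError("ray direction must be non-zero")
    d = d / norm
    p = np.asarray(point, dtype=float)
    half = n_pixels * spacing / 2.0

    t0, t1 = -np.inf, np.inf
    for k in range(2):
        if abs(d[k]) < _EPS:
            if not (-half <= p[k] <= half):
                return []
        else:
            ta = (-half - p[k]) / d[k]
            tb = (half - p[k]) / d[k]
            t0 = max(t0, min(ta, tb))
            t1 = min(t1, max(ta, tb))
    if not np.isfinite(t0):
        t0, t1 = -4.0 * half, 4.0 * half   # ray parallel to both axes cannot occur
    if t1 <= t0:
        return []

    out = []
    t = t0
    # current pixel at a point just inside
    x = p + (t0 + 1e-9) * d
    ix = min(max(int(np.floor((x[0] + half) / spacing)), 0), n_pixels - 1)
    iy = min(max(int(np.floor((x[1] + half) / spacing)), 0), n_pixels - 1)
    step = [0, 0]
    t_next = [np.inf, np.inf]
    dt = [np.inf, np.inf]
    idx = [ix, iy]
    for k in range(2):
        if d[k] > _EPS:
            step[k] = 1
            t_next[k] = ((idx[k] + 1) * spacing - half - p[k]) / d[k]
            dt[k] = spacing / d[k]
        elif d[k] < -_EPS:
            step[k] = -1
            t_next[k] = (idx[k] * spacing - half - p[k]) / d[k]
            dt[k] = -spacing / d[k]
    while t < t1 - _EPS:
        k = 0 if t_next[0] <= t_next[1] else 1
        t_stop = min(t_next[k], t1)
        seg = t_stop - t
        if seg > _EPS:
            out.append(((idx[0], idx[1]), seg))
        t = t_stop
        if t_next[k] <= t1 + _EPS:
            idx[k] += step[k]
            t_next[k] += dt[k]
            if idx[k] < 0 or idx[k] >= n_pixels:
                break
    return out


@njit(cache=True)
def _siddon_project(image, spacing, angles, s_pos, out):  # pragma: no cover
    n = image.shape[0]
    half = n * spacing / 2.0
    eps = 1e-12
    for a in range(angles.shape[0]):
        ct = np.cos(angles[a])
        st = np.sin(angles[a])
        dx, dy = -st, ct
        for b in range(s_pos.shape[0]):
            px = s_pos[b] * ct
            py = s_pos[b] * st
            t0 = -1e30
            t1 = 1e30
            miss = False
            for k in range(2):
                dk = dx if k == 0 else dy
                pk = px if k == 0 else py
                if abs(dk) < eps:
                    if pk < -half or pk > half:
                        miss = True
                else:
                    ta = (-half - pk) / dk
                    tb = (half - pk) / dk
                    lo = min(ta, tb)
                    hi = max(ta, tb)
                    if lo > t0:
                        t0 = lo
                    if hi < t1:
                        t1 = hi
            if miss or t1 <= t0:
                out[a, b] = 0.0
                continue
            x0 = px + (t0 + 1e-9) * dx
            y0 = py + (t0 + 1e-9) * dy
            ix = int(np.floor((x0 + half) / spacing))
            iy = int(np.floor((y0 + half) / spacing))
            if ix < 0:
                ix = 0
            if ix > n - 1:
                ix = n - 1
            if iy < 0:
                iy = 0
            if iy > n - 1:
                iy = n - 1
            if dx > eps:
                sx = 1
                tnx = ((ix + 1) * spacing - half - px) / dx
                dtx = spacing / dx
            elif dx < -eps:
                sx = -1
                tnx = (ix * spacing - half - px) / dx
                dtx = -spacing / dx
            else:
                sx = 0
                tnx = 1e30
                dtx = 1e30
            if dy > eps:
                sy = 1
                tny = ((iy + 1) * spacing - half - py) / dy
                dty = spacing / dy
            elif dy < -eps:
                sy = -1
                tny = (iy * spacing - half - py) / dy
                dty = -spacing / dy
            else:
                sy = 0
                tny = 1e30
                dty = 1e30
            acc = 0.0
            t = t0
            while t < t1 - eps:
                if tnx <= tny:
                    tstop = tnx if tnx < t1 else t1
                    seg = tstop - t
                    if seg > eps:
                        acc += image[iy, ix] * seg
                    t = tstop
                    if tnx <= t1 + eps:
                        ix += sx
                        tnx += dtx
                        if ix < 0 or ix >= n:
                            break
                else:
                    tstop = tny if tny < t1 else t1
                    seg = tstop - t
                    if seg > eps:
                        acc += image[iy, ix] * seg
                    t = tstop
                    if tny <= t1 + eps:
                        iy += sy
                        tny += dty
                        if iy < 0 or iy >= n:
                            break
            out[a, b] = acc


@njit(cache=True)
def _siddon_backproject(sino, spacing, angles, s_pos, image):  # pragma: no cover
    n = image.shape[0]
    half = n * spacing / 2.0
    eps = 1e-12
    for a in range(angles.shape[0]):
        ct = np.cos(angles[a])
        st = np.sin(angles[a])
        dx, dy = -st, ct
        for b in range(s_pos.shape[0]):
            val = sino[a, b]
            if val == 0.0:
                continue
            px = s_pos[b] * ct
            py = s_pos[b] * st
            t0 = -1e30
            t1 = 1e30
            miss = False
            for k in range(2):
                dk = dx if k == 0 else dy
                pk = px if k == 0 else py
                if abs(dk) < eps:
                    if pk < -half or pk > half:
                        miss = True
                else:
                    ta = (-half - pk) / dk
                    tb = (half - pk) / dk
                    lo = min(ta, tb)
                    hi = max(ta, tb)
                    if lo > t0:
                        t0 = lo
                    if hi < t1:
                        t1 = hi
            if miss or t1 <= t0:
                continue
            x0 = px + (t0 + 1e-9) * dx
            y0 = py + (t0 + 1e-9) * dy
            ix = int(np.floor((x0 + half) / spacing))
            iy = int(np.floor((y0 + half) / spacing))
            if ix < 0:
                ix = 0
            if ix > n - 1:
                ix = n - 1
            if iy < 0:
                iy = 0
            if iy > n - 1:
                iy = n - 1
            if dx > eps:
                sx = 1
                tnx = ((ix + 1) * spacing - half - px) / dx
                dtx = spacing / dx
            elif dx < -eps:
                sx = -1
                tnx = (ix * spacing - half - px) / dx
                dtx = -spacing / dx
            else:
                sx = 0
                tnx = 1e30
                dtx = 1e30
            if dy > eps:
                sy = 1
                tny = ((iy + 1) * spacing - half - py) / dy
                dty = spacing / dy
            elif dy < -eps:
                sy = -1
                tny = (iy * spacing - half - py) / dy
                dty = -spacing / dy
            else:
                sy = 0
                tny = 1e30
                dty = 1e30
            t = t0
            while t < t1 - eps:
                if tnx <= tny:
                    tstop = tnx if tnx < t1 else t1
                    seg = tstop - t
                    if seg > eps:
                        image[iy, ix] += val * seg
                    t = tstop
                    if tnx <= t1 + eps:
                        ix += sx
                        tnx += dtx
                        if ix < 0 or ix >= n:
                            break
                else:
                    tstop = tny if tny < t1 else t1
                    seg = tstop - t
                    if seg > eps:
                        image[iy, ix] += val * seg
                    t = tstop
                    if tny <= t1 + eps:
                        iy += sy
                        tny += dty
                        if iy < 0 or iy >= n:
                            break


def make_geometry(n_pixels: int, spacing: float, n_views: int = 360) -> Geometry:
    """Geometry whose detector (pitch = pixel size) covers the grid diagonal."""
    n_bins = int(np.ceil(n_pixels * np.sqrt(2.0))) + 3
    return Geometry(n_views=n_views, n_bins=n_bins, pitch=spacing)


def _project_array(values: np.ndarray, spacing: float, geometry: Geometry) -> np.ndarray:
    out = np.zeros((geometry.n_views, geometry.n_bins))
    _siddon_project(np.ascontiguousarray(values, dtype=np.float64), spacing,
                    geometry.angles, geometry.bin_positions, out)
    return out


def forward_project(image: CTImage, geometry: Geometry) -> Sinogram:
    """Siddon line integrals of a mm^-1 image: value = sum mu * length (dimensionless)."""
    if image.units != "mm^-1":
        raise ValueError(f"forward projection expects mm^-1 units, got {image.units!r}")
    ny, nx = image.shape
    if ny != nx:
        raise ValueError("square grids only")
    vals = _project_array(image.values, image.spacing, geometry)
    return Sinogram(vals, geometry, tag=image.energy,
                    meta={"spacing": image.spacing, "n_pixels": nx})


def backproject(sino: Sinogram, n_pixels: int, spacing: float) -> CTImage:
    """Unfiltered adjoint of :func:`forward_project` (same ray weights)."""
    img = np.zeros((n_pixels, n_pixels))
    _siddon_backproject(np.ascontiguousarray(sino.values, dtype=np.float64),
                        spacing, sino.geometry.angles, sino.geometry.bin_positions, img)
    return CTImage(img, spacing, "mm^-1", sino.tag)


def _ramp_filter(n_bins: int, pitch: float, name: str) -> tuple[np.ndarray, int]:
    n_pad = 1 << int(np.ceil(np.log2(max(2 * n_bins, 16))))
    freq = np.fft.rfftfreq(n_pad, d=pitch)       # cycles/mm
    f_nyq = 1.0 / (2.0 * pitch)
    ramp = np.abs(freq)
    if name == "ram-lak":
        window = np.ones_like(freq)
    elif name == "shepp-logan":
        window = np.sinc(freq / (2.0 * f_nyq))
    elif name == "hann":
        window = 0.5 * (1.0 + np.cos(np.pi * freq / f_nyq))
    else:
        raise ValueError(f"unknown filter {name!r}; use ram-lak, shepp-logan or hann")
    return ramp * window, n_pad


def fbp_reconstruct(sino: Sinogram, filter_name: str = "shepp-logan", *,
                    n_pixels: int | None = None, spacing: float | None = None,
                    circle: bool = True) -> CTImage:
    """Filtered backprojection on the sinogram's own geometry.

    Output units are mm^-1 when the sinogram holds dimensionless line
    integrals.  The reconstruction grid defaults to (n_bins rounded down to the
    inscribed square) pixels at the detector pitch; pass ``n_pixels``/``spacing``
    to override.
    """
    geom = sino.geometry
    if geom.n_views < 2:
        raise ValueError("filtered backprojection needs at least two views")
    if n_pixels is None:
        n_pixels = int(sino.meta.get("n_pixels", int(geom.n_bins / np.sqrt(2.0))))
    if spacing is None:
        spacing = float(sino.meta.get("spacing", geom.pitch))

    filt, n_pad = _ramp_filter(geom.n_bins, geom.pitch, filter_name)
    padded = np.zeros((geom.n_views, n_pad))
    padded[:, :geom.n_bins] = sino.values
    q = np.fft.irfft(np.fft.rfft(padded, axis=1) * filt[None, :], n=n_pad, axis=1)
    q = q[:, :geom.n_bins]

    x = (np.arange(n_pixels) - (n_pixels - 1) / 2.0) * spacing
    xx, yy = np.meshgrid(x, x)
    recon = np.zeros((n_pixels, n_pixels))
    s0 = geom.bin_positions[0]
    for a, theta in enumerate(geom.angles):
        s = (xx * np.cos(theta) + yy * np.sin(theta) - s0) / geom.pitch
        i0 = np.clip(np.floor(s).astype(np.int64), 0, geom.n_bins - 2)
        w = s - i0
        recon += (1.0 - w) * q[a, i0] + w * q[a, i0 + 1]
    recon *= np.pi / geom.n_views
    if circle:
        r2 = xx ** 2 + yy ** 2
        recon[r2 > (n_pixels * spacing / 2.0) ** 2] = 0.0
    return CTImage(recon, spacing, "mm^-1", sino.tag, {"filter": filter_name})
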