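"""Brown–Conrady lens distortion: the forward model and its Newton inverse.

The camera observes a planar specimen, so the model works on normalized
coordinates x' = (u_ideal - cx)/fx, y' = (v_ideal - cy)/fy (z = 1).  The
forward map distorts the normalized point with a rational radial factor and
tangential terms, then projects to pixels:

    r^2  = x'^2 + y'^2
    rad  = (1 + k1 r^2 + k2 r^4 + k3 r^6) / (1 + k4 r^2 + k5 r^4 + k6 r^6)
    x''  = x' * rad + 2 p1 x' y' + p2 (r^2 + 2 x'^2)
    y''  = y' * rad + p1 (r^2 + 2 y'^2) + 2 p2 x' y'
    u    = fx x'' + cx
    v    = fy y'' + cy

There is no closed-form inverse; :func:`invert_distortion` solves the 2-D
system per point with Newton's method and a finite-difference Jacobian.

The principal point (cx, cy) is fixed at the image center and fx = fy is a
nominal focal length (the tile's larger side); a planar mosaic cannot
identify focal length separately from scale, so those are never optimized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: distortion coefficients optimized by default during composition
DEFAULT_OPTIMIZED_COEFFS = ("k1", "k2", "p1", "p2")

COEFF_NAMES = ("k1", "k2", "k3", "k4", "k5", "k6", "p1", "p2")


@dataclass
class DistortionParams:
    """Shared (per-instrument, not per-tile) lens distortion description."""

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    k5: float = 0.0
    k6: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    @classmethod
    def identity(cls, width: int, height: int) -> "DistortionParams":
        """Distortion-free camera for a w×h sensor (principal point at center)."""
        f = float(max(width, height))
        return cls(fx=f, fy=f, cx=width / 2.0, cy=height / 2.0)

    @property
    def is_identity(self) -> bool:
        return all(getattr(self, n) == 0.0 for n in COEFF_NAMES)

    def coeffs(self, names=COEFF_NAMES) -> np.ndarray:
        return np.array([getattr(self, n) for n in names])

    def with_coeffs(self, names, values) -> "DistortionParams":
        d = self.to_dict()
        for n, v in zip(names, values):
            d[n] = float(v)
        return DistortionParams(**d)

    def to_dict(self) -> dict:
        return {
            "fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
            **{n: getattr(self, n) for n in COEFF_NAMES},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DistortionParams":
        return cls(**d)


def _distort_normalized(xy: np.ndarray, d: DistortionParams) -> np.ndarray:
    x, y = xy[..., 0], xy[..., 1]
    r2 = x * x + y * y
    num = 1.0 + r2 * (d.k1 + r2 * (d.k2 + r2 * d.k3))
    den = 1.0 + r2 * (d.k4 + r2 * (d.k5 + r2 * d.k6))
    rad = num / den
    xd = x * rad + 2.0 * d.p1 * x * y + d.p2 * (r2 + 2.0 * x * x)
    yd = y * rad + d.p1 * (r2 + 2.0 * y * y) + 2.0 * d.p2 * x * y
    return np.stack([xd, yd], axis=-1)


def apply_distortion(points: np.ndarray, d: DistortionParams) -> np.ndarray:
    """Forward-distort normalized (x', y') points to observed pixels (u, v).

    ``points`` is (..., 2) in normalized coordinates; returns the same shape
    in pixel coordinates.
    """
    xy = np.asarray(points, dtype=float)
    dist = _distort_normalized(xy, d)
    uv = np.empty_like(dist)
    uv[..., 0] = d.fx * dist[..., 0] + d.cx
    uv[..., 1] = d.fy * dist[..., 1] + d.cy
    return uv


def pinhole_project(points: np.ndarray, d: DistortionParams) -> np.ndarray:
    """Distortion-free projection of normalized points to pixels."""
    xy = np.asarray(points, dtype=float)
    uv = np.empty_like(xy)
    uv[..., 0] = d.fx * xy[..., 0] + d.cx
    uv[..., 1] = d.fy * xy[..., 1] + d.cy
    return uv


def pinhole_backproject(pixels: np.ndarray, d: DistortionParams) -> np.ndarray:
    """Inverse of :func:`pinhole_project` (the Newton starting point)."""
    uv = np.asarray(pixels, dtype=float)
    xy = np.empty_like(uv)
    xy[..., 0] = (uv[..., 0] - d.cx) / d.fx
    xy[..., 1] = (uv[..., 1] - d.cy) / d.fy
    return xy


def invert_distortion(
    pixels: np.ndarray,
    d: DistortionParams,
    tol: float = 1e-8,
    max_iter: int = 50,
    fd_step: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray]:
    """Undistort observed pixels to normalized (x', y') coordinates.

    Newton iteration on the forward map with a forward-difference Jacobian,
    started from the pinhole back-projection.  Returns ``(normalized,
    converged)`` where ``converged`` flags points whose forward image lies
    within ``tol`` pixels of the observation; non-converged points (e.g. in
    a fold-over regime of extreme distortion) must be excluded by the caller.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    uv = np.atleast_2d(np.asarray(pixels, dtype=float))
    z = pinhole_backproject(uv, d)
    if d.is_identity:
        return z.reshape(np.shape(pixels)), np.ones(uv.shape[:-1], dtype=bool).reshape(
            np.shape(pixels)[:-1]
        )
    target = uv
    active = np.ones(len(z), dtype=bool)
    for _ in range(max_iter):
        f = apply_distortion(z, d) - target
        err = np.linalg.norm(f, axis=-1)
        active = err > tol
        if not active.any():
            break
        za = z[active]
        fa = f[active]
        # forward-difference 2x2 Jacobian, solved in closed form per point
        fx_ = (apply_distortion(za + [fd_step, 0.0], d) - apply_distortion(za, d)) / fd_step
        fy_ = (apply_distortion(za + [0.0, fd_step], d) - apply_distortion(za, d)) / fd_step
        j00, j10 = fx_[:, 0], fx_[:, 1]
        j01, j11 = fy_[:, 0], fy_[:, 1]
        det = j00 * j11 - j01 * j10
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        dx = (j11 * fa[:, 0] - j01 * fa[:, 1]) / det
        dy = (-j10 * fa[:, 0] + j00 * fa[:, 1]) / det
        step = np.stack([dx, dy], axis=-1)
        step = np.where(np.isfinite(step), step, 0.0)
        z[active] = za - step
    final_err = np.linalg.norm(apply_distortion(z, d) - target, axis=-1)
    converged = final_err <= tol
    return z.reshape(np.shape(pixels)), converged.reshape(np.shape(pixels)[:-1])


def undistort_pixels(
    pixels: np.ndarray, d: DistortionParams, tol: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Map observed pixels to ideal (pinhole) pixels: P(U_d(q)).

    This is the per-point correction applied before poses in the bundle
    problem.  Identity distortion returns the input unchanged.
    """
    if d.is_identity:
        arr = np.asarray(pixels, dtype=float)
        return arr, np.ones(arr.shape[:-1], dtype=bool)
    normalized, converged = invert_distortion(pixels, d, tol=tol, max_iter=max_iter)
    return pinhole_project(normalized, d), converged
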