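"""Constrained 2-D poses and the global-coordinate conventions of the mosaic.

A pose maps tile-frame points to global (virtual slide) coordinates:

    g = s * R(theta) @ p + (a, b)

with the tile origin at the top-left pixel center, x rightward, y downward,
and theta measured in the same (y-down) frame.  Three constraint modes are
supported: ``T`` (translation only), ``TR`` (translation + rotation) and
``TRS`` (translation + rotation + isotropic scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODES = ("T", "TR", "TRS")

#: number of free parameters per mode
MODE_NPARAMS = {"T": 2, "TR": 3, "TRS": 4}


def _check_mode(mode: str) -> str:
    if mode not in MODES:
        raise ValueError(f"unknown pose mode {mode!r}; expected one of {MODES}")
    return mode


@dataclass
class Pose:
    """Constrained affine placement of one tile in global coordinates."""

    mode: str = "T"
    a: float = 0.0
    b: float = 0.0
    theta: float = 0.0
    s: float = 1.0

    def __post_init__(self) -> None:
        _check_mode(self.mode)
        if self.mode == "T":
            self.theta = 0.0
            self.s = 1.0
        elif self.mode == "TR":
            self.s = 1.0
        if self.s <= 0:
            raise ValueError("pose scale must be positive")

    # -- application ---------------------------------------------------
    def rotation(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) tile-frame (x, y) points into global coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = self.s * pts @ self.rotation().T + np.array([self.a, self.b])
        return out

    def invert(self) -> "Pose":
        """Pose mapping global coordinates back into the tile frame."""
        R_inv = self.rotation().T
        t = -(R_inv @ np.array([self.a, self.b])) / self.s
        return Pose(mode=self.mode, a=t[0], b=t[1], theta=-self.theta, s=1.0 / self.s)

    def compose(self, other: "Pose") -> "Pose":
        """Return self ∘ other (apply ``other`` first, then ``self``)."""
        mode = self.mode if MODE_NPARAMS[self.mode] >= MODE_NPARAMS[other.mode] else other.mode
        t = self.apply(np.array([[other.a, other.b]]))[0]
        return Pose(
            mode=mode,
            a=t[0],
            b=t[1],
            theta=_wrap_angle(self.theta + other.theta),
            s=self.s * other.s,
        )

    # -- (de)serialization ---------------------------------------------
    def params(self) -> np.ndarray:
        """Free parameters under the mode constraint."""
        return np.array([self.a, self.b, self.theta, self.s][: MODE_NPARAMS[self.mode]])

    @classmethod
    def from_params(cls, mode: str, vec: np.ndarray) -> "Pose":
        vec = np.asarray(vec, dtype=float)
        n = MODE_NPARAMS[_check_mode(mode)]
        full = [0.0, 0.0, 0.0, 1.0]
        full[:n] = list(vec[:n])
        return cls(mode=mode, a=full[0], b=full[1], theta=full[2], s=full[3])

    def to_dict(self) -> dict:
        return {"mode": self.mode, "a": self.a, "b": self.b, "theta": self.theta, "s": self.s}

    @classmethod
    def from_dict(cls, d: dict) -> "Pose":
        return cls(mode=d["mode"], a=d["a"], b=d["b"], theta=d["theta"], s=d["s"])

    def is_identity(self, tol: float = 0.0) -> bool:
        return (
            abs(self.a) <= tol
            and abs(self.b) <= tol
            and abs(self.theta) <= tol
            and abs(self.s - 1.0) <= tol
        )


def _wrap_angle(theta: float) -> float:
    """Wrap into (-pi, pi]."""
    wrapped = (theta + np.pi) % (2 * np.pi) - np.pi
    if wrapped == -np.pi:
        wrapped = np.pi
    return float(wrapped)


def tile_corners(width: int, height: int) -> np.ndarray:
    """Corner pixel-center coordinates of a w×h tile, (4, 2) in (x, y)."""
    return np.array(
        [[0.0, 0.0], [width - 1.0, 0.0], [width - 1.0, height - 1.0], [0.0, height - 1.0]]
    )


def projected_bbox(pose: Pose, width: int, height: int) -> tuple[float, float, float, float]:
    """Axis-aligned (xmin, ymin, xmax, ymax) of the tile projected by ``pose``."""
    corners = pose.apply(tile_corners(width, height))
    xmin, ymin = corners.min(axis=0)
    xmax, ymax = corners.max(axis=0)
    return float(xmin), float(ymin), float(xmax), float(ymax)


def bbox_intersection_area(
    box_a: tuple[float, float, float, float], box_b: tuple[float, float, float, float]
) -> float:
    w = min(box_a[2], box_b[2]) - max(box_a[0], box_b[0])
    h = min(box_a[3], box_b[3]) - max(box_a[1], box_b[1])
    return max(0.0, w) * max(0.0, h)


# Backwards-friendly aliases matching the two roles a pose plays.
PoseParams = Pose
RelativePose = Pose
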