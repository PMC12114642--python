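"""Feature detection, descriptor matching and constrained pairwise pose fitting.

Detection runs on full-resolution grayscale tiles (color input is reduced to
luma first).  SIFT is the default detector; ORB is available for binary
descriptors.  Matching applies Lowe's nearest-neighbor ratio test.  The
relative transform between two tiles is fitted under a constraint mode
(translation only / +rotation / +scale) inside a consensus loop, because
microscope stages translate but tissue texture produces outlier matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage.feature import ORB, SIFT

from .geometry import MODE_NPARAMS, Pose, _check_mode

SUPPORTED_DETECTORS = ("SIFT", "AKAZE", "ORB", "BRISK", "KAZE")
#: detectors with an implementation in this build
AVAILABLE_DETECTORS = ("SIFT", "ORB")

DEFAULT_RATIO = 0.75
RANSAC_INLIER_TOL = 3.0  # px
RANSAC_CONFIDENCE = 0.995
RANSAC_MAX_ITER = 2000
MIN_INLIERS = 8
MIN_INLIER_RATIO = 0.2
#: minimal support per mode, enforced before consensus
MIN_SUPPORT = {"T": 1, "TR": 2, "TRS": 2}


class ConfigurationError(ValueError):
    """Raised for unsupported detector names / invalid modes."""


@dataclass
class Keypoint:
    x: float
    y: float
    scale: float = 1.0
    response: float = 0.0


@dataclass
class FeatureSet:
    """Keypoints + descriptors from one tile."""

    detector_name: str
    positions: np.ndarray  # (N, 2) subpixel (x, y)
    scales: np.ndarray  # (N,)
    responses: np.ndarray  # (N,)
    descriptors: np.ndarray  # (N, D) float or bool

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def keypoints(self) -> list[Keypoint]:
        return [
            Keypoint(x=float(p[0]), y=float(p[1]), scale=float(s), response=float(r))
            for p, s, r in zip(self.positions, self.scales, self.responses)
        ]

    @property
    def is_binary(self) -> bool:
        return self.descriptors.dtype == bool

    @classmethod
    def empty(cls, detector_name: str, descriptor_width: int = 0) -> "FeatureSet":
        return cls(
            detector_name=detector_name,
            positions=np.empty((0, 2)),
            scales=np.empty(0),
            responses=np.empty(0),
            descriptors=np.empty((0, descriptor_width)),
        )


@dataclass
class MatchPair:
    point_a: tuple[float, float]
    point_b: tuple[float, float]
    distance: float
    inlier: bool = False


def to_gray(image: np.ndarray) -> np.ndarray:
    """Reduce a color raster to luma; pass grayscale through unchanged."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        rgb = img[..., :3].astype(float)
        luma = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
        return luma
    raise ValueError(f"unsupported image shape {img.shape}")


def detect_features(image: np.ndarray, detector_name: str = "SIFT") -> FeatureSet:
    """Detect keypoints and descriptors on one tile.

    Deterministic for a fixed image and detector.  An image too small or too
    flat for the detector yields an empty :class:`FeatureSet`, not an error.
    """
    name = detector_name.upper()
    if name not in SUPPORTED_DETECTORS:
        raise ConfigurationError(
            f"unsupported detector {detector_name!r}; supported: {SUPPORTED_DETECTORS}"
        )
    if name not in AVAILABLE_DETECTORS:
        raise ConfigurationError(
            f"detector {name} is not available in this build; available: {AVAILABLE_DETECTORS}"
        )
    img = to_gray(image).astype(float)
    if img.size == 0:
        raise ValueError("empty image")
    try:
        if name == "SIFT":
            det = SIFT()
            det.detect_and_extract(img)
            # positions are subpixel (row, col); convert to (x, y)
            pos = det.positions[:, ::-1].astype(float)
            return FeatureSet(
                detector_name=name,
                positions=pos,
                scales=det.sigmas.astype(float),
                responses=np.zeros(len(pos)),
                descriptors=det.descriptors.astype(float),
            )
        det = ORB()
        det.detect_and_extract(img)
        pos = det.keypoints[:, ::-1].astype(float)
        return FeatureSet(
            detector_name=name,
            positions=pos,
            scales=det.scales.astype(float),
            responses=det.responses.astype(float),
            descriptors=det.descriptors,
        )
    except (RuntimeError, ValueError, IndexError):
        # flat or tiny images: "no features" is a valid result
        return FeatureSet.empty(name)


def match_features(
    a: FeatureSet, b: FeatureSet, ratio: float = DEFAULT_RATIO
) -> list[MatchPair]:
    """Nearest-neighbor matching from ``a`` into ``b`` with the ratio test.

    Each keypoint of ``a`` appears in at most one pair.  Float descriptors
    are compared with L2 distance, binary ones with Hamming distance.
    """
    if len(a) == 0 or len(b) == 0:
        return []
    if a.detector_name != b.detector_name:
        raise ValueError("feature sets must come from the same detector")
    if a.is_binary:
        dists = cdist(a.descriptors, b.descriptors, metric="hamming") * a.descriptors.shape[1]
    else:
        dists = cdist(a.descriptors, b.descriptors, metric="euclidean")
    order = np.argsort(dists, axis=1)
    best = order[:, 0]
    d1 = dists[np.arange(len(a)), best]
    if dists.shape[1] >= 2:
        d2 = dists[np.arange(len(a)), order[:, 1]]
    else:
        d2 = np.full(len(a), np.inf)
    with np.errstate(invalid="ignore", divide="ignore"):
        keep = (d1 == 0.0) | (d1 < ratio * d2)
    pairs = [
        MatchPair(
            point_a=(float(a.positions[i, 0]), float(a.positions[i, 1])),
            point_b=(float(b.positions[best[i], 0]), float(b.positions[best[i], 1])),
            distance=float(d1[i]),
        )
        for i in np.flatnonzero(keep)
    ]
    return pairs


def pairs_to_arrays(pairs: list[MatchPair]) -> tuple[np.ndarray, np.ndarray]:
    pa = np.array([p.point_a for p in pairs], dtype=float).reshape(-1, 2)
    pb = np.array([p.point_b for p in pairs], dtype=float).reshape(-1, 2)
    return pa, pb


def fit_constrained(pa: np.ndarray, pb: np.ndarray, mode: str) -> Pose:
    """Closed-form least-squares pose taking points ``pb`` onto ``pa``.

    mode T: translation = mean(pa - pb).  TR/TRS: the 2-D Procrustes
    (Umeyama) solution, with s forced to 1 for TR.
    """
    _check_mode(mode)
    if len(pa) < MIN_SUPPORT[mode]:
        raise ValueError(f"mode {mode} needs ≥ {MIN_SUPPORT[mode]} pairs")
    if mode == "T":
        t = (pa - pb).mean(axis=0)
        return Pose(mode="T", a=float(t[0]), b=float(t[1]))
    mu_a = pa.mean(axis=0)
    mu_b = pb.mean(axis=0)
    A = pa - mu_a
    B = pb - mu_b
    cov = A.T @ B / len(pa)  # maps B-dev to A-dev
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    R = U @ D @ Vt
    theta = float(np.arctan2(R[1, 0], R[0, 0]))
    if mode == "TRS":
        var_b = (B**2).sum() / len(pb)
        s = float((S * np.diag(D)).sum() / var_b) if var_b > 0 else 1.0
        if s <= 0:
            s = 1.0
    else:
        s = 1.0
    t = mu_a - s * (R @ mu_b)
    return Pose(mode=mode, a=float(t[0]), b=float(t[1]), theta=theta, s=s)


def _residuals(pose: Pose, pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    return np.linalg.norm(pose.apply(pb) - pa, axis=1)


def estimate_constrained_pose(
    pairs: list[MatchPair],
    mode: str = "T",
    inlier_tol: float = RANSAC_INLIER_TOL,
    min_inliers: int = MIN_INLIERS,
    min_inlier_ratio: float = MIN_INLIER_RATIO,
    max_iter: int = RANSAC_MAX_ITER,
    confidence: float = RANSAC_CONFIDENCE,
    rng: np.random.Generator | None = None,
) -> tuple[Pose, np.ndarray] | None:
    """Robustly fit the constrained relative pose mapping tile-B points to tile-A.

    Returns ``(pose, inlier_flags)`` or ``None`` when no consensus reaches
    ``min_inliers`` and ``min_inlier_ratio`` — the "matching unsuccessful"
    branch of the registration flow.  For mode T every pair's offset is tried
    as a candidate (exhaustive consensus, deterministic); TR/TRS run a seeded
    RANSAC over 2-pair samples.  The final pose is refit on all inliers.
    """
    _check_mode(mode)
    if len(pairs) < max(MIN_SUPPORT[mode], 1):
        return None
    pa, pb = pairs_to_arrays(pairs)
    n = len(pa)

    best_inliers: np.ndarray | None = None
    if mode == "T":
        # exhaustive: each pair proposes a translation
        offsets = pa - pb  # (n, 2)
        # pairwise consistency: |offset_i - offset_j| < tol  ⇒ j inlier to model i
        diff = offsets[:, None, :] - offsets[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        counts = (dist <= inlier_tol).sum(axis=1)
        best = int(np.argmax(counts))
        best_inliers = dist[best] <= inlier_tol
    else:
        rng = rng or np.random.default_rng(0)
        best_count = -1
        iters_needed = max_iter
        i = 0
        while i < min(iters_needed, max_iter):
            idx = rng.choice(n, size=2, replace=False)
            if np.allclose(pb[idx[0]], pb[idx[1]]):
                i += 1
                continue
            try:
                cand = fit_constrained(pa[idx], pb[idx], mode)
            except (ValueError, np.linalg.LinAlgError):
                i += 1
                continue
            inl = _residuals(cand, pa, pb) <= inlier_tol
            c = int(inl.sum())
            if c > best_count:
                best_count = c
                best_inliers = inl
                w = max(c / n, 1e-9)
                denom = np.log(max(1e-12, 1 - w**2))
                if denom < 0:
                    iters_needed = int(np.ceil(np.log(1 - confidence) / denom))
            i += 1

    if best_inliers is None or best_inliers.sum() < MIN_SUPPORT[mode]:
        return None
    # refit on inliers, then re-evaluate the inlier set once
    pose = fit_constrained(pa[best_inliers], pb[best_inliers], mode)
    inl = _residuals(pose, pa, pb) <= inlier_tol
    if inl.sum() >= MIN_SUPPORT[mode]:
        pose = fit_constrained(pa[inl], pb[inl], mode)
    else:
        inl = best_inliers
    n_inl = int(inl.sum())
    if n_inl < min_inliers or n_inl / n < min_inlier_ratio:
        return None
    for p, flag in zip(pairs, inl):
        p.inlier = bool(flag)
    return pose, inl
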