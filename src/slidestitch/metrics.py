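"""Evaluation surface: reprojection RMS, sharpness, sampling, growth rates.

The headline quantity is the reprojection RMS over all matched point pairs,

    RMS = sqrt( (1/N) Σ_i ‖p_i(1) − p_i(2)‖² )

where p_i(1), p_i(2) are the two global-frame projections of the i-th pair.
Because a sequential-only run's graph contains only chain edges (whose
residuals are small by construction even when the mosaic has drifted), the
module also provides :func:`evaluation_rms`, which rebuilds a common edge
set from *all* overlapping tile pairs before scoring — the fair way to
compare runs with and without additional matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from . import features as ft
from .bundle import reprojection_residuals, rms_of
from .geometry import Pose, bbox_intersection_area, projected_bbox
from .graph import MatchEdge, MosaicGraph
from .synthgen import GroundTruth


@dataclass
class EvalReport:
    rms: float
    n_pairs: int
    dropped_pairs: int = 0
    trial_slope: float = float("nan")
    time_slope: float = float("nan")
    sharpness: list[tuple[float, float, float]] = field(default_factory=list)
    pose_error: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rms": self.rms,
            "n_pairs": self.n_pairs,
            "dropped_pairs": self.dropped_pairs,
            "trial_slope": self.trial_slope,
            "time_slope": self.time_slope,
            "sharpness": [list(s) for s in self.sharpness],
            "pose_error": {str(k): v for k, v in self.pose_error.items()},
        }


def rms_reprojection(graph: MosaicGraph, include_distortion: bool = False) -> float:
    """Reprojection RMS over all inlier pairs of all edges."""
    if graph.total_pairs() == 0:
        raise ValueError("graph has no matched pairs")
    res, dropped = reprojection_residuals(
        graph, include_distortion=include_distortion, return_dropped=True
    )
    return rms_of(res)


def evaluation_rms(
    graph: MosaicGraph,
    include_distortion: bool = False,
    overlap_min_frac: float = 0.02,
    detector: str = "SIFT",
    mode: str = "T",
    seed: int = 0,
) -> tuple[float, int]:
    """RMS over an edge set rebuilt from every overlapping tile pair.

    All tile pairs whose projected boxes overlap (under the graph's frozen
    poses) are feature-matched; pairwise-consensus inliers form the
    evaluation pairs; residuals use the frozen poses.  Existing edges are
    reused.  Returns ``(rms, n_pairs)``.
    """
    eval_graph = MosaicGraph()
    eval_graph.anchor_id = graph.anchor_id
    eval_graph.tiles = graph.tiles
    eval_graph.poses = graph.poses
    eval_graph.distortion = graph.distortion
    for e in graph.edges:
        eval_graph.add_edge(e)
    ids = graph.tile_ids
    for a_pos, i in enumerate(ids):
        ti = graph.tiles[i]
        box_i = projected_bbox(graph.poses[i], ti.width, ti.height)
        for j in ids[a_pos + 1 :]:
            if eval_graph.has_edge(i, j):
                continue
            tj = graph.tiles[j]
            box_j = projected_bbox(graph.poses[j], tj.width, tj.height)
            if bbox_intersection_area(box_i, box_j) < overlap_min_frac * ti.width * ti.height:
                continue
            if ti.features is None or tj.features is None:
                continue
            pairs = ft.match_features(ti.features, tj.features)
            res = ft.estimate_constrained_pose(
                pairs, mode=mode, rng=np.random.default_rng((seed, i, j))
            )
            if res is None:
                continue
            _, inl = res
            pa, pb = ft.pairs_to_arrays(pairs)
            eval_graph.add_edge(
                MatchEdge(tile_i=i, tile_j=j, points_i=pa[inl], points_j=pb[inl])
            )
    if eval_graph.total_pairs() == 0:
        raise ValueError("no evaluation pairs found")
    return (
        rms_reprojection(eval_graph, include_distortion=include_distortion),
        eval_graph.total_pairs(),
    )


# ---------------------------------------------------------------------------
# sharpness
# ---------------------------------------------------------------------------

_LAPLACIAN = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)
_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)


def sharpness_metrics(region: np.ndarray) -> tuple[float, float, float]:
    """(Laplacian response variance, Tenengrad, Brenner gradient).

    Laplacian variance: variance of the 3×3 Laplacian response; Tenengrad:
    mean squared Sobel gradient magnitude; Brenner: mean squared horizontal
    second difference at shift 2.  Border pixels where the kernels would
    read outside the region are excluded from the statistics.
    """
    img = ft.to_gray(region).astype(float)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("region must be at least 3×3")
    lap = ndi.convolve(img, _LAPLACIAN, mode="constant")[1:-1, 1:-1]
    laplacian_var = float(lap.var())
    gx = ndi.convolve(img, _SOBEL_X, mode="constant")[1:-1, 1:-1]
    gy = ndi.convolve(img, _SOBEL_X.T, mode="constant")[1:-1, 1:-1]
    tenengrad = float(np.mean(gx**2 + gy**2))
    diff = img[:, 2:] - img[:, :-2]
    brenner = float(np.mean(diff**2))
    return laplacian_var, tenengrad, brenner


def sample_regions(
    slide: np.ndarray,
    n: int = 50,
    size: int = 512,
    seed: int = 0,
    min_foreground_frac: float = 0.5,
    max_tries: int = 20000,
) -> list[tuple[int, int]]:
    """Random non-overlapping size×size regions over non-background areas.

    Returns (x, y) top-left corners, deterministic per seed.  Background is
    the black fill of uncovered canvas; a region qualifies when at least
    ``min_foreground_frac`` of its pixels are non-background.  If fewer than
    ``n`` disjoint regions fit, returns as many as found with a warning.
    """
    img = ft.to_gray(slide)
    h, w = img.shape
    if h < size or w < size:
        raise ValueError("slide smaller than the region size")
    rng = np.random.default_rng(seed)
    fg = img > 0
    # integral image for O(1) foreground counting per candidate
    integral = np.pad(fg.astype(np.int64).cumsum(0).cumsum(1), ((1, 0), (1, 0)))

    def fg_count(x, y):
        return (
            integral[y + size, x + size]
            - integral[y, x + size]
            - integral[y + size, x]
            + integral[y, x]
        )

    chosen: list[tuple[int, int]] = []
    need = min_foreground_frac * size * size
    for _ in range(max_tries):
        if len(chosen) == n:
            break
        x = int(rng.integers(0, w - size + 1))
        y = int(rng.integers(0, h - size + 1))
        if fg_count(x, y) < need:
            continue
        if any(abs(x - cx) < size and abs(y - cy) < size for cx, cy in chosen):
            continue
        chosen.append((x, y))
    if len(chosen) < n:
        # deterministic sweep to pick up whatever disjoint space is left
        for y in range(0, h - size + 1, size):
            for x in range(0, w - size + 1, size):
                if len(chosen) == n:
                    break
                if fg_count(x, y) < need:
                    continue
                if any(abs(x - cx) < size and abs(y - cy) < size for cx, cy in chosen):
                    continue
                chosen.append((x, y))
    if len(chosen) < n:
        warnings.warn(
            f"only {len(chosen)} of {n} requested regions fit the non-background area",
            stacklevel=2,
        )
    return chosen


def extract_regions(slide: np.ndarray, corners: list[tuple[int, int]], size: int):
    return [slide[y : y + size, x : x + size] for x, y in corners]


def review_sheet(regions: list[np.ndarray], columns: int = 10, gap: int = 4) -> np.ndarray:
    """Tile sampled regions into one contact sheet for visual misalignment
    review (misalignment judgment itself stays a human task)."""
    if not regions:
        raise ValueError("no regions to lay out")
    size = regions[0].shape[0]
    rows = int(np.ceil(len(regions) / columns))
    chan = regions[0].shape[2:] if regions[0].ndim == 3 else ()
    sheet = np.zeros(
        (rows * (size + gap) - gap, columns * (size + gap) - gap) + chan,
        dtype=regions[0].dtype,
    )
    for k, region in enumerate(regions):
        r, c = divmod(k, columns)
        y = r * (size + gap)
        x = c * (size + gap)
        sheet[y : y + region.shape[0], x : x + region.shape[1]] = region
    return sheet


def downsample(slide: np.ndarray, target_max_side: int) -> np.ndarray:
    """Area down-sampling used to compare sharpness across instruments at a
    common resolution."""
    from skimage.transform import resize

    h, w = slide.shape[:2]
    factor = max(h, w) / float(target_max_side)
    if factor <= 1.0:
        return slide
    out_shape = (int(round(h / factor)), int(round(w / factor))) + slide.shape[2:]
    out = resize(slide.astype(float), out_shape, anti_aliasing=True)
    return out.astype(slide.dtype) if np.issubdtype(slide.dtype, np.integer) is False \
        else np.clip(np.round(out), 0, 255).astype(slide.dtype)


# ---------------------------------------------------------------------------
# growth rates and ground-truth scoring
# ---------------------------------------------------------------------------

def fit_growth_rates(trial_log, time_log) -> tuple[float, float]:
    """OLS slopes of matching-trial counts and registration times vs index."""
    trial = np.asarray(trial_log, dtype=float)
    times = np.asarray(time_log, dtype=float)
    if len(trial) < 2 or len(times) < 2:
        raise ValueError("need at least two registrations to fit a slope")
    xt = np.arange(1, len(trial) + 1, dtype=float)
    xm = np.arange(1, len(times) + 1, dtype=float)
    trial_slope = float(np.polyfit(xt, trial, 1)[0])
    time_slope = float(np.polyfit(xm, times, 1)[0])
    return trial_slope, time_slope


def pose_recovery_error(
    graph: MosaicGraph, truth: GroundTruth, align: str = "translation"
) -> dict[int, float]:
    """Per-tile translation error (px) after removing the gauge freedom.

    ``align='translation'`` subtracts the anchor's offset (T mode);
    ``align='similarity'`` fits a global 2-D similarity on tile translations
    first (for TRS sessions, where scale and orientation are also free).
    Tiles missing from the graph are reported as NaN.
    """
    est_ids = [i for i in graph.tile_ids if i in truth.true_poses]
    est = np.array([[graph.poses[i].a, graph.poses[i].b] for i in est_ids])
    true = np.array([[truth.true_poses[i].a, truth.true_poses[i].b] for i in est_ids])
    if align == "similarity" and len(est_ids) >= 2:
        pose = ft.fit_constrained(true, est, "TRS")
        aligned = pose.apply(est)
    else:
        anchor = graph.anchor_id
        k = est_ids.index(anchor)
        aligned = est - est[k] + true[k]
    err = {i: float(np.linalg.norm(aligned[k] - true[k]))
           for k, i in enumerate(est_ids)}
    for i in truth.true_poses:
        if i not in err:
            err[i] = float("nan")
    return err
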