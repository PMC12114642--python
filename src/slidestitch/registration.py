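"""The real-time stage: place each incoming tile into the growing mosaic.

Flow per tile: extract features → match against the previous tile → on
failure, fall back to matching against all earlier tiles (most recent
first) → filter earlier tiles by projected overlap and run additional
matching against them → every ``ba_interval`` registrations, run a brief
bundle adjustment → refresh the preview.  A tile that matches nothing is
held as *pending* and retried after later successes, so a discontinuous
acquisition (imaging resumes far from the previous field) never loses data.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from . import features as ft
from .bundle import brief_bundle_adjust
from .geometry import Pose, bbox_intersection_area, projected_bbox
from .graph import MatchEdge, MosaicGraph, Tile

MATCHING_MODES = ("sequential_plus_additional", "sequential_only", "brute_force")

DEFAULT_BA_INTERVAL = 10
DEFAULT_BA_ITERATIONS = 1
DEFAULT_OVERLAP_MIN_FRAC = 0.05


@dataclass
class RegistrationState:
    """Mutable per-session registration bookkeeping."""

    mode: str = "T"
    detector: str = "SIFT"
    matching_mode: str = "sequential_plus_additional"
    ba_interval: int = DEFAULT_BA_INTERVAL
    ba_iterations_per_trigger: int = DEFAULT_BA_ITERATIONS
    overlap_min_frac: float = DEFAULT_OVERLAP_MIN_FRAC
    ratio: float = ft.DEFAULT_RATIO
    min_inliers: int = ft.MIN_INLIERS
    seed: int = 0
    n_registered: int = 0
    trial_log: list[int] = field(default_factory=list)
    time_log: list[float] = field(default_factory=list)
    ba_trigger_log: list[int] = field(default_factory=list)
    pending: list[Tile] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ba_interval < 1:
            raise ValueError("ba_interval must be ≥ 1")
        if self.matching_mode not in MATCHING_MODES:
            raise ValueError(f"matching_mode must be one of {MATCHING_MODES}")

    def rng_for(self, i: int, j: int) -> np.random.Generator:
        # per-pair generator so results do not depend on attempt order
        return np.random.default_rng((self.seed, i, j))


def ensure_features(tile: Tile, state: RegistrationState) -> None:
    if tile.features is None:
        if tile.pixels is None:
            # resumed session: tiles come back from the checkpoint rasterless
            from .imgio import read_image

            if not tile.source_path:
                raise ValueError(f"tile {tile.id} has no pixels to detect features on")
            tile.pixels = read_image(tile.source_path)
        tile.features = ft.detect_features(tile.pixels, state.detector)


def _try_match(
    graph: MosaicGraph, state: RegistrationState, tile: Tile, other_id: int
) -> tuple[Pose, np.ndarray, list[ft.MatchPair]] | None:
    """Match ``tile`` (new) against a registered tile; returns B→A relative pose."""
    other = graph.tiles[other_id]
    ensure_features(other, state)
    ensure_features(tile, state)
    pairs = ft.match_features(other.features, tile.features, ratio=state.ratio)
    if not pairs:
        return None
    result = ft.estimate_constrained_pose(
        pairs,
        mode=state.mode,
        min_inliers=state.min_inliers,
        rng=state.rng_for(other_id, tile.id),
    )
    if result is None:
        return None
    pose, inl = result
    return pose, inl, pairs


def _make_edge(
    tile_a: int, tile_b: int, pairs: list[ft.MatchPair], inl: np.ndarray, rel: Pose
) -> MatchEdge:
    pa, pb = ft.pairs_to_arrays(pairs)
    pa, pb = pa[inl], pb[inl]
    if tile_a < tile_b:
        return MatchEdge(tile_i=tile_a, tile_j=tile_b, points_i=pa, points_j=pb,
                         relative_pose=rel)
    return MatchEdge(tile_i=tile_b, tile_j=tile_a, points_i=pb, points_j=pa,
                     relative_pose=rel)


def find_overlap_candidates(
    graph: MosaicGraph,
    pose: Pose,
    w: int,
    h: int,
    overlap_min_frac: float = DEFAULT_OVERLAP_MIN_FRAC,
    exclude: set[int] | None = None,
) -> list[int]:
    """Registered tiles whose projected boxes overlap a query tile's box.

    Overlap is measured as intersection area of axis-aligned bounding boxes
    of the projected corners, thresholded at ``overlap_min_frac`` of the
    query tile's area.  Tiles in ``exclude`` (typically those already
    sharing an edge with the query) are skipped.
    """
    exclude = exclude or set()
    qbox = projected_bbox(pose, w, h)
    area_min = overlap_min_frac * w * h
    out = []
    for tid in graph.tile_ids:
        if tid in exclude:
            continue
        t = graph.tiles[tid]
        tbox = projected_bbox(graph.poses[tid], t.width, t.height)
        if bbox_intersection_area(qbox, tbox) >= area_min:
            out.append(tid)
    return out


def fallback_match_all(
    graph: MosaicGraph, state: RegistrationState, tile: Tile, skip: set[int]
) -> tuple[int, Pose, np.ndarray, list[ft.MatchPair], int] | None:
    """Re-attempt matching against all earlier tiles, most recent first.

    Returns ``(neighbor_id, relative_pose, inliers, pairs, n_attempts)`` for
    the first success, or ``None``; every attempt counts toward the trial
    log either way.
    """
    attempts = 0
    for tid in sorted(graph.tile_ids, reverse=True):
        if tid in skip:
            continue
        attempts += 1
        res = _try_match(graph, state, tile, tid)
        if res is not None:
            pose, inl, pairs = res
            return tid, pose, inl, pairs, attempts
    return None if attempts >= 0 else None  # pragma: no cover


def register_tile(
    graph: MosaicGraph, state: RegistrationState, tile: Tile
) -> tuple[MosaicGraph, str]:
    """Register one tile; returns the graph and an outcome string.

    Outcomes: ``registered`` (sequential or additional matching placed it),
    ``registered_via_fallback``, ``pending`` (no overlap found; tile held
    for retry), ``duplicate`` (same source path seen before; no-op).
    """
    if tile.source_path and tile.source_path in graph.source_paths():
        return graph, "duplicate"
    t0 = time.perf_counter()
    if len(graph) == 0:
        ensure_features(tile, state)
        graph.add_tile(tile, Pose(mode=state.mode))
        state.n_registered += 1
        state.trial_log.append(0)
        state.time_log.append(time.perf_counter() - t0)
        return graph, "registered"

    attempts = 0
    outcome = None
    neighbor = None
    rel = None
    inl = None
    pairs = None

    prev_id = max(graph.tile_ids)
    if state.matching_mode == "brute_force":
        # worst case: try every previous tile, keep all successful edges
        successes = []
        for tid in sorted(graph.tile_ids, reverse=True):
            attempts += 1
            res = _try_match(graph, state, tile, tid)
            if res is not None:
                successes.append((tid, *res))
        if successes:
            neighbor, rel, inl, pairs = successes[0]
            outcome = "registered"
    else:
        attempts += 1
        res = _try_match(graph, state, tile, prev_id)
        if res is not None:
            neighbor, rel, inl, pairs = prev_id, *res
            outcome = "registered"
        elif state.matching_mode == "sequential_only":
            pass  # strict chain: exactly one attempt per registration
        else:
            fb = fallback_match_all(graph, state, tile, skip={prev_id})
            if fb is not None:
                neighbor, rel, inl, pairs, extra = fb
                attempts += extra
                outcome = "registered_via_fallback"
            else:
                attempts += len(graph.tile_ids) - 1

    if outcome is None:
        state.pending.append(tile)
        state.trial_log.append(attempts)
        state.time_log.append(time.perf_counter() - t0)
        return graph, "pending"

    pose = graph.poses[neighbor].compose(rel)
    graph.add_tile(tile, pose)
    graph.add_edge(_make_edge(neighbor, tile.id, pairs, inl, rel))

    if state.matching_mode == "brute_force":
        for tid, rel_o, inl_o, pairs_o in successes[1:]:
            if not graph.has_edge(tid, tile.id):
                graph.add_edge(_make_edge(tid, tile.id, pairs_o, inl_o, rel_o))
    elif state.matching_mode == "sequential_plus_additional":
        candidates = find_overlap_candidates(
            graph,
            pose,
            tile.width,
            tile.height,
            overlap_min_frac=state.overlap_min_frac,
            exclude=graph.neighbors(tile.id) | {tile.id},
        )
        for tid in candidates:
            attempts += 1
            res = _try_match(graph, state, tile, tid)
            if res is not None:
                rel_o, inl_o, pairs_o = res
                graph.add_edge(_make_edge(tid, tile.id, pairs_o, inl_o, rel_o))

    state.n_registered += 1
    state.trial_log.append(attempts)
    if (
        state.matching_mode != "sequential_only"
        and state.n_registered % state.ba_interval == 0
        and graph.edges
    ):
        brief_bundle_adjust(graph, iterations=state.ba_iterations_per_trigger,
                            mode=state.mode)
        state.ba_trigger_log.append(state.n_registered)
    state.time_log.append(time.perf_counter() - t0)

    # retry held tiles, oldest first, now that the mosaic has grown
    if state.pending:
        still = []
        retry, state.pending = state.pending[:], []
        for p in retry:
            graph, oc = register_tile(graph, state, p)
            if oc == "pending":
                # register_tile re-appended it; pull back out to preserve order
                still.append(state.pending.pop())
        state.pending = still
    return graph, outcome


def render_preview(graph: MosaicGraph, scale: float = 0.1) -> np.ndarray:
    """Project all tiles at reduced resolution; later tiles overwrite earlier.

    The preview is advisory: nearest/bilinear resampled, no seams or
    blending, black background.
    """
    if not (0 < scale <= 1):
        raise ValueError("scale must be in (0, 1]")
    if len(graph) == 0:
        return np.zeros((0, 0))
    boxes = [
        projected_bbox(graph.poses[tid], graph.tiles[tid].width, graph.tiles[tid].height)
        for tid in graph.tile_ids
    ]
    xmin = min(b[0] for b in boxes)
    ymin = min(b[1] for b in boxes)
    xmax = max(b[2] for b in boxes)
    ymax = max(b[3] for b in boxes)
    out_w = max(1, int(np.ceil((xmax - xmin + 1) * scale)))
    out_h = max(1, int(np.ceil((ymax - ymin + 1) * scale)))
    sample = next(
        (t.pixels for t in graph.tiles.values() if t.pixels is not None), None
    )
    if sample is None:
        return np.zeros((0, 0))
    channels = sample.shape[2] if sample.ndim == 3 else 1
    canvas = np.zeros((out_h, out_w, channels) if channels > 1 else (out_h, out_w),
                      dtype=sample.dtype)
    for tid in graph.tile_ids:
        t = graph.tiles[tid]
        if t.pixels is None:
            continue
        box = projected_bbox(graph.poses[tid], t.width, t.height)
        x0 = int(np.floor((box[0] - xmin) * scale))
        y0 = int(np.floor((box[1] - ymin) * scale))
        x1 = min(out_w, int(np.ceil((box[2] - xmin + 1) * scale)))
        y1 = min(out_h, int(np.ceil((box[3] - ymin + 1) * scale)))
        if x1 <= x0 or y1 <= y0:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        gx = xs / scale + xmin
        gy = ys / scale + ymin
        inv = graph.poses[tid].invert()
        src = inv.apply(np.stack([gx.ravel(), gy.ravel()], axis=1))
        sx = src[:, 0].reshape(ys.shape)
        sy = src[:, 1].reshape(ys.shape)
        valid = (sx >= 0) & (sx <= t.width - 1) & (sy >= 0) & (sy <= t.height - 1)
        if not valid.any():
            continue
        if channels > 1:
            for c in range(channels):
                vals = ndi.map_coordinates(
                    t.pixels[..., c].astype(float), [sy, sx], order=1, mode="constant"
                )
                canvas[ys[valid], xs[valid], c] = vals[valid].astype(canvas.dtype)
        else:
            vals = ndi.map_coordinates(
                t.pixels.astype(float), [sy, sx], order=1, mode="constant"
            )
            canvas[ys[valid], xs[valid]] = vals[valid].astype(canvas.dtype)
    return canvas
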