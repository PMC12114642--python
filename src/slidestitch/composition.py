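"""Composition stage: produce the final virtual slide raster.

After the convergence-run bundle adjustment, each tile is undistorted and
warped into the global canvas by inverse mapping (for every canvas pixel,
back-project through the pose, then forward-distort to find the source
pixel), seams assign every multiply-covered pixel to exactly one tile,
optional exposure gains equalize overlap brightness, and optional
multi-band blending hides the seams.  Rendering is chunked so peak memory
stays bounded by the chunk size, and the output is bit-identical for any
chunk size: every per-pixel decision (sampling, seam ownership, gain)
depends only on global quantities, never on chunk boundaries.

With seams on and exposure/blending off (evaluation mode) each output pixel
equals exactly one source tile's resampled value, which keeps residual
misalignments visible instead of smoothing them away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .distortion import DistortionParams, apply_distortion, pinhole_backproject
from .geometry import Pose, bbox_intersection_area, projected_bbox, tile_corners
from .graph import MosaicGraph, Tile


@dataclass
class Canvas:
    """Global frame of the output raster."""

    origin: tuple[int, int]  # global (x, y) of the output's top-left pixel
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("canvas must be non-degenerate")


@dataclass
class WarpedTile:
    tile_id: int
    raster: np.ndarray
    mask: np.ndarray
    offset: tuple[int, int]  # (x, y) within the canvas


@dataclass
class ComposeOptions:
    seams: bool = True
    exposure_compensation: bool = False
    blending: bool = False
    chunk_px: int = 1024
    background: float = 0.0
    blend_bands: int = 5

    def __post_init__(self) -> None:
        if self.chunk_px < 256:
            raise ValueError("chunk_px must be ≥ 256")

    @classmethod
    def evaluation_mode(cls, **kw) -> "ComposeOptions":
        """Seam-partition overwrite with exposure/blending off."""
        return cls(seams=True, exposure_compensation=False, blending=False, **kw)


def _projected_corners(tile: Tile, pose: Pose, d: DistortionParams | None) -> np.ndarray:
    """Global positions of the tile's (undistorted) corner pixels."""
    from .distortion import undistort_pixels

    corners = tile_corners(tile.width, tile.height)
    if d is not None and not d.is_identity:
        corners, _ = undistort_pixels(corners, d)
    return pose.apply(corners)


def compute_canvas(graph: MosaicGraph) -> Canvas:
    """Tight integer bounding box of all projected tile corners."""
    if len(graph) == 0:
        raise ValueError("empty graph has no canvas")
    pts = np.concatenate(
        [
            _projected_corners(graph.tiles[tid], graph.poses[tid], graph.distortion)
            for tid in graph.tile_ids
        ]
    )
    x0 = int(np.floor(pts[:, 0].min()))
    y0 = int(np.floor(pts[:, 1].min()))
    x1 = int(np.ceil(pts[:, 0].max()))
    y1 = int(np.ceil(pts[:, 1].max()))
    return Canvas(origin=(x0, y0), width=x1 - x0 + 1, height=y1 - y0 + 1)


def _source_coords(
    pose: Pose, d: DistortionParams | None, gx: np.ndarray, gy: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Observed-tile pixel coordinates that land on global points (gx, gy)."""
    inv = pose.invert()
    ideal = inv.apply(np.stack([gx.ravel(), gy.ravel()], axis=1))
    if d is not None and not d.is_identity:
        normalized = pinhole_backproject(ideal, d)
        observed = apply_distortion(normalized, d)
    else:
        observed = ideal
    sx = observed[:, 0].reshape(gx.shape)
    sy = observed[:, 1].reshape(gx.shape)
    return sx, sy


def _sample(tile_pixels: np.ndarray, sy: np.ndarray, sx: np.ndarray) -> np.ndarray:
    """Bilinear sampling, channel-aware, float output."""
    if tile_pixels.ndim == 2:
        return ndi.map_coordinates(tile_pixels.astype(float), [sy, sx], order=1)
    chans = [
        ndi.map_coordinates(tile_pixels[..., c].astype(float), [sy, sx], order=1)
        for c in range(tile_pixels.shape[2])
    ]
    return np.stack(chans, axis=-1)


def warp_tile(
    tile: Tile, pose: Pose, d: DistortionParams | None, canvas: Canvas
) -> WarpedTile:
    """Resample one tile into (its bounding-box region of) the canvas."""
    if pose.s == 0:
        raise ValueError("degenerate pose")
    box = projected_bbox(pose, tile.width, tile.height)
    pad = 4  # distortion can push content slightly past the pinhole bbox
    x0 = max(0, int(np.floor(box[0])) - canvas.origin[0] - pad)
    y0 = max(0, int(np.floor(box[1])) - canvas.origin[1] - pad)
    x1 = min(canvas.width, int(np.ceil(box[2])) - canvas.origin[0] + pad + 1)
    y1 = min(canvas.height, int(np.ceil(box[3])) - canvas.origin[1] + pad + 1)
    if x1 <= x0 or y1 <= y0:
        raise ValueError("tile projects outside the canvas")
    gy, gx = np.mgrid[y0:y1, x0:x1].astype(float)
    gx += canvas.origin[0]
    gy += canvas.origin[1]
    sx, sy = _source_coords(pose, d, gx, gy)
    mask = (sx >= 0) & (sx <= tile.width - 1) & (sy >= 0) & (sy <= tile.height - 1)
    raster = _sample(tile.pixels, sy, sx)
    raster[~mask] = 0
    return WarpedTile(tile_id=tile.id, raster=raster, mask=mask, offset=(x0, y0))


# ---------------------------------------------------------------------------
# seams / exposure
# ---------------------------------------------------------------------------

def _tile_centers(graph: MosaicGraph) -> dict[int, np.ndarray]:
    centers = {}
    for tid in graph.tile_ids:
        t = graph.tiles[tid]
        c = np.array([(t.width - 1) / 2.0, (t.height - 1) / 2.0])
        centers[tid] = graph.poses[tid].apply(c[None, :])[0]
    return centers


def find_seams(warped: list[WarpedTile], centers: dict[int, np.ndarray] | None = None,
               canvas: Canvas | None = None) -> dict[int, np.ndarray]:
    """Partition covered pixels among tiles (Voronoi by projected tile center).

    Every multiply-covered pixel goes to exactly one tile — the one whose
    projected center is nearest (ties broken toward the lower tile id);
    singly-covered pixels keep their tile.  Returns one boolean seam mask
    per tile, in the same (offset-cropped) frame as its validity mask.
    """
    if not warped:
        raise ValueError("no warped tiles")
    if centers is None:
        # fall back to warped-region centroids
        centers = {
            w.tile_id: np.array(
                [w.offset[0] + w.mask.shape[1] / 2.0, w.offset[1] + w.mask.shape[0] / 2.0]
            )
            for w in warped
        }
    seam_masks: dict[int, np.ndarray] = {}
    for w in warped:
        h, ww = w.mask.shape
        yy, xx = np.mgrid[0:h, 0:ww].astype(float)
        gx = xx + w.offset[0] + (canvas.origin[0] if canvas else 0)
        gy = yy + w.offset[1] + (canvas.origin[1] if canvas else 0)
        cx, cy = centers[w.tile_id]
        own_d = (gx - cx) ** 2 + (gy - cy) ** 2
        own = w.mask.copy()
        for o in warped:
            if o.tile_id == w.tile_id:
                continue
            # overlap of the two cropped regions, in w's frame
            ox0 = max(w.offset[0], o.offset[0])
            oy0 = max(w.offset[1], o.offset[1])
            ox1 = min(w.offset[0] + ww, o.offset[0] + o.mask.shape[1])
            oy1 = min(w.offset[1] + h, o.offset[1] + o.mask.shape[0])
            if ox1 <= ox0 or oy1 <= oy0:
                continue
            wy = slice(oy0 - w.offset[1], oy1 - w.offset[1])
            wx = slice(ox0 - w.offset[0], ox1 - w.offset[0])
            oy = slice(oy0 - o.offset[1], oy1 - o.offset[1])
            ox = slice(ox0 - o.offset[0], ox1 - o.offset[0])
            ocx, ocy = centers[o.tile_id]
            other_d = (gx[wy, wx] - ocx) ** 2 + (gy[wy, wx] - ocy) ** 2
            both = w.mask[wy, wx] & o.mask[oy, ox]
            if o.tile_id < w.tile_id:
                lose = both & (other_d <= own_d[wy, wx])
            else:
                lose = both & (other_d < own_d[wy, wx])
            own[wy, wx] &= ~lose
        seam_masks[w.tile_id] = own
    return seam_masks


def exposure_gains(warped: list[WarpedTile], eps: float = 0.01) -> dict[int, float]:
    """Per-tile multiplicative gains equalizing overlap-region brightness.

    Minimizes Σ_pairs (g_i μ_ij − g_j μ_ji)² + eps Σ (g_i − 1)² where μ_ij is
    tile i's mean intensity over its overlap with tile j; the regularizer
    anchors the global gain at 1.
    """
    ids = [w.tile_id for w in warped]
    idx = {tid: k for k, tid in enumerate(ids)}
    n = len(ids)
    A = eps * np.eye(n)
    rhs = eps * np.ones(n)
    for i, wi in enumerate(warped):
        for wj in warped[i + 1 :]:
            ox0 = max(wi.offset[0], wj.offset[0])
            oy0 = max(wi.offset[1], wj.offset[1])
            ox1 = min(wi.offset[0] + wi.mask.shape[1], wj.offset[0] + wj.mask.shape[1])
            oy1 = min(wi.offset[1] + wi.mask.shape[0], wj.offset[1] + wj.mask.shape[0])
            if ox1 <= ox0 or oy1 <= oy0:
                continue
            si = (slice(oy0 - wi.offset[1], oy1 - wi.offset[1]),
                  slice(ox0 - wi.offset[0], ox1 - wi.offset[0]))
            sj = (slice(oy0 - wj.offset[1], oy1 - wj.offset[1]),
                  slice(ox0 - wj.offset[0], ox1 - wj.offset[0]))
            both = wi.mask[si] & wj.mask[sj]
            if both.sum() < 16:
                continue
            ri = wi.raster[si] if wi.raster.ndim == 2 else wi.raster[si].mean(axis=-1)
            rj = wj.raster[sj] if wj.raster.ndim == 2 else wj.raster[sj].mean(axis=-1)
            mi = float(ri[both].mean())
            mj = float(rj[both].mean())
            a, b = idx[wi.tile_id], idx[wj.tile_id]
            A[a, a] += mi * mi
            A[b, b] += mj * mj
            A[a, b] -= mi * mj
            A[b, a] -= mi * mj
    g = np.linalg.solve(A, rhs)
    return {tid: float(g[idx[tid]]) for tid in ids}


# ---------------------------------------------------------------------------
# final render
# ---------------------------------------------------------------------------

def _tiles_touching(graph: MosaicGraph, canvas: Canvas, x0, y0, x1, y1) -> list[int]:
    box = (x0 + canvas.origin[0] - 4, y0 + canvas.origin[1] - 4,
           x1 + canvas.origin[0] + 4, y1 + canvas.origin[1] + 4)
    out = []
    for tid in graph.tile_ids:
        t = graph.tiles[tid]
        tb = projected_bbox(graph.poses[tid], t.width, t.height)
        if bbox_intersection_area(box, tb) > 0:
            out.append(tid)
    return out


def compose_slide(
    graph: MosaicGraph,
    options: ComposeOptions | None = None,
    channel: str | None = None,
    tile_loader=None,
) -> np.ndarray:
    """Render the virtual slide.

    ``tile_loader(tile) -> ndarray`` supplies pixels when tiles were dropped
    from memory (or to substitute a non-reference channel's raster).
    Uncovered canvas stays at the background value (black), mirroring how
    cavities with no captured field appear as blanks in a real slide.
    """
    options = options or ComposeOptions()
    if len(graph) == 0:
        raise ValueError("nothing to compose")
    canvas = compute_canvas(graph)
    centers = _tile_centers(graph)

    def pixels_of(tile: Tile) -> np.ndarray:
        if channel is not None:
            # non-reference channels ride on the reference tile's pose
            from .imgio import read_image

            path = tile.channel_paths.get(channel)
            if path is None:
                raise ValueError(f"tile {tile.id} has no {channel!r} channel")
            return read_image(path)
        if tile_loader is not None:
            return tile_loader(tile)
        if tile.pixels is None:
            raise ValueError(f"tile {tile.id} has no pixels; pass a tile_loader")
        return tile.pixels

    sample = pixels_of(graph.tiles[graph.anchor_id])
    nchan = sample.shape[2] if sample.ndim == 3 else 1
    dtype = sample.dtype
    shape = (canvas.height, canvas.width) + ((nchan,) if nchan > 1 else ())
    out = np.full(shape, options.background, dtype=dtype)

    gains: dict[int, float] = {}
    if options.exposure_compensation:
        warped_all = [
            warp_tile(_with_pixels(graph.tiles[tid], pixels_of(graph.tiles[tid])),
                      graph.poses[tid], graph.distortion, canvas)
            for tid in graph.tile_ids
        ]
        gains = exposure_gains(warped_all)
        del warped_all

    if options.blending:
        return _compose_blended(graph, canvas, centers, options, gains, pixels_of, out)

    step = options.chunk_px
    for y0 in range(0, canvas.height, step):
        for x0 in range(0, canvas.width, step):
            y1 = min(canvas.height, y0 + step)
            x1 = min(canvas.width, x0 + step)
            tids = _tiles_touching(graph, canvas, x0, y0, x1, y1)
            if not tids:
                continue
            gy, gx = np.mgrid[y0:y1, x0:x1].astype(float)
            gx += canvas.origin[0]
            gy += canvas.origin[1]
            best_d = np.full(gx.shape, np.inf)
            owner_val = np.zeros(gx.shape + ((nchan,) if nchan > 1 else ()))
            covered = np.zeros(gx.shape, dtype=bool)
            for tid in sorted(tids):
                # ascending order + strict inequality ⇒ ties go to the lower id
                t = graph.tiles[tid]
                sx, sy = _source_coords(graph.poses[tid], graph.distortion, gx, gy)
                mask = (sx >= 0) & (sx <= t.width - 1) & (sy >= 0) & (sy <= t.height - 1)
                if not mask.any():
                    continue
                vals = _sample(pixels_of(t), sy, sx)
                if options.exposure_compensation and tid in gains:
                    vals = vals * gains[tid]
                if options.seams:
                    cx, cy = centers[tid]
                    dist = (gx - cx) ** 2 + (gy - cy) ** 2
                    take = mask & (dist < best_d)
                    best_d[take] = dist[take]
                else:
                    take = mask  # overwrite compositing in tile order
                owner_val[take] = vals[take]
                covered |= mask
            block = out[y0:y1, x0:x1]
            vals_cast = np.clip(np.round(owner_val), 0, _dtype_max(dtype)) \
                if np.issubdtype(dtype, np.integer) else owner_val
            block[covered] = vals_cast[covered].astype(dtype)
            out[y0:y1, x0:x1] = block
    return out


def _with_pixels(tile: Tile, pixels: np.ndarray) -> Tile:
    if tile.pixels is pixels:
        return tile
    return Tile(id=tile.id, source_path=tile.source_path, width=tile.width,
                height=tile.height, pixels=pixels, channel_paths=tile.channel_paths)


def _dtype_max(dtype) -> float:
    return float(np.iinfo(dtype).max) if np.issubdtype(dtype, np.integer) else np.inf


def _compose_blended(graph, canvas, centers, options, gains, pixels_of, out):
    """Multi-band blending over the seam partition (full-canvas pyramids)."""
    nchan = out.shape[2] if out.ndim == 3 else 1
    warped = [
        warp_tile(_with_pixels(graph.tiles[tid], pixels_of(graph.tiles[tid])),
                  graph.poses[tid], graph.distortion, canvas)
        for tid in graph.tile_ids
    ]
    seams = find_seams(warped, centers=centers, canvas=canvas)
    bands = options.blend_bands
    sigma = 2.0
    acc = [np.zeros(out.shape, dtype=float) for _ in range(bands)]
    wacc = [np.zeros((canvas.height, canvas.width), dtype=float) for _ in range(bands)]
    covered = np.zeros((canvas.height, canvas.width), dtype=bool)
    for w in warped:
        x0, y0 = w.offset
        h, ww = w.mask.shape
        raster = w.raster * gains.get(w.tile_id, 1.0) if gains else w.raster
        weight = seams[w.tile_id].astype(float)
        covered[y0 : y0 + h, x0 : x0 + ww] |= w.mask
        gauss = raster.astype(float)
        for b in range(bands):
            if b < bands - 1:
                low = ndi.gaussian_filter(gauss, sigma, axes=(0, 1)) \
                    if gauss.ndim == 3 else ndi.gaussian_filter(gauss, sigma)
                band_img = gauss - low
                gauss = low
            else:
                band_img = gauss
            weight = ndi.gaussian_filter(weight, sigma) if b > 0 else weight
            wb = weight * w.mask
            if band_img.ndim == 3:
                acc[b][y0 : y0 + h, x0 : x0 + ww] += band_img * wb[..., None]
            else:
                acc[b][y0 : y0 + h, x0 : x0 + ww] += band_img * wb
            wacc[b][y0 : y0 + h, x0 : x0 + ww] += wb
    result = np.zeros(out.shape, dtype=float)
    for b in range(bands):
        wsafe = np.where(wacc[b] > 1e-8, wacc[b], 1.0)
        if result.ndim == 3:
            result += acc[b] / wsafe[..., None]
        else:
            result += acc[b] / wsafe
    dtype = out.dtype
    if np.issubdtype(dtype, np.integer):
        result = np.clip(np.round(result), 0, _dtype_max(dtype))
    result = result.astype(dtype)
    out[covered] = result[covered]
    return out


# ---------------------------------------------------------------------------
# output files
# ---------------------------------------------------------------------------

def save_slide(path: str, slide: np.ndarray, overview_path: str | None = None,
               pyramid_levels: int = 3, tile_px: int = 256) -> None:
    """Write a tiled (pyramidal) TIFF plus an optional PNG overview."""
    import tifffile

    big = slide.nbytes > 2**32
    subresolutions = max(0, pyramid_levels - 1)
    with tifffile.TiffWriter(path, bigtiff=big) as tif:
        kwargs = dict(tile=(tile_px, tile_px))
        tif.write(slide, subifds=subresolutions, **kwargs)
        level = slide
        for _ in range(subresolutions):
            level = level[::2, ::2]
            tif.write(level, subfiletype=1, **kwargs)
    if overview_path:
        import imageio.v3 as iio

        ov = slide
        while max(ov.shape[:2]) > 2048:
            ov = ov[::2, ::2]
        if ov.dtype != np.uint8:
            scale = _dtype_max(ov.dtype) if np.issubdtype(ov.dtype, np.integer) else (
                ov.max() or 1.0
            )
            ov = np.clip(ov.astype(float) / scale * 255.0, 0, 255).astype(np.uint8)
        iio.imwrite(overview_path, ov)
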