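"""Synthetic manual-acquisition simulator with known ground truth.

Generates a textured ground-truth specimen plane, plans an
overlap-maintaining capture trajectory (serpentine, center-out clockwise
spiral, deliberately discontinuous, or random walk), and renders each tile
through a camera model that applies Brown–Conrady lens distortion,
multiplicative exposure jitter and additive Gaussian sensor noise.  Every
quantity is reproducible from the spec's seed, and the ground-truth sidecar
(true poses + true distortion) is sufficient to score a stitcher
independently.

Texture regimes mimic the hard cases of real histology: ``tissue_blobs``
(dense multi-scale structure, plenty of features), ``homogeneous``
(low-contrast repetitive texture, e.g. liver parenchyma, where matching is
fragile) and ``sparse`` (isolated structures over empty background, e.g.
lung).
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage as ndi

from .distortion import DistortionParams, apply_distortion, pinhole_backproject
from .geometry import Pose

TEXTURES = ("tissue_blobs", "homogeneous", "sparse")
TRAJECTORIES = ("serpentine", "spiral", "discontinuous", "random_walk")

#: default distortion for recovery experiments: visible but invertible
def default_test_distortion(tile_w: int, tile_h: int) -> DistortionParams:
    d = DistortionParams.identity(tile_w, tile_h)
    d.fx = d.fy = float(tile_w)
    d.k1 = -0.05
    d.k2 = 0.01
    return d


@dataclass
class SceneSpec:
    """Description of one synthetic acquisition."""

    plane_size: tuple[int, int] = (1024, 1024)  # (width, height)
    texture: str = "tissue_blobs"
    tile_size: tuple[int, int] = (160, 160)  # (width, height)
    overlap_frac: float = 0.2
    trajectory: str = "serpentine"
    n_tiles: int = 9
    distortion: DistortionParams | None = None  # None → identity camera
    noise_sigma: float = 0.0  # gray levels
    exposure_jitter: float = 0.0  # fractional, ±
    seed: int = 0
    pose_mode: str = "T"
    rotation_jitter: float = 0.01  # radians, used when pose_mode != "T"
    #: manual-stage placement wobble, fraction of tile size per axis; the
    #: hand never reproduces a perfect grid
    jitter_frac: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.overlap_frac < 1):
            raise ValueError("overlap_frac must be in (0, 1)")
        if self.texture not in TEXTURES:
            raise ValueError(f"texture must be one of {TEXTURES}")
        if self.trajectory not in TRAJECTORIES:
            raise ValueError(f"trajectory must be one of {TRAJECTORIES}")

    def camera(self) -> DistortionParams:
        return self.distortion or DistortionParams.identity(*self.tile_size)

    def to_dict(self) -> dict:
        return {
            "plane_size": list(self.plane_size),
            "texture": self.texture,
            "tile_size": list(self.tile_size),
            "overlap_frac": self.overlap_frac,
            "trajectory": self.trajectory,
            "n_tiles": self.n_tiles,
            "distortion": self.distortion.to_dict() if self.distortion else None,
            "noise_sigma": self.noise_sigma,
            "exposure_jitter": self.exposure_jitter,
            "seed": self.seed,
            "pose_mode": self.pose_mode,
            "rotation_jitter": self.rotation_jitter,
            "jitter_frac": self.jitter_frac,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        d["plane_size"] = tuple(d["plane_size"])
        d["tile_size"] = tuple(d["tile_size"])
        if d.get("distortion"):
            d["distortion"] = DistortionParams.from_dict(d["distortion"])
        return cls(**d)


@dataclass
class GroundTruth:
    """True poses and camera of a synthetic acquisition."""

    true_poses: dict[int, Pose]
    true_distortion: DistortionParams
    plane: np.ndarray | None
    spec: SceneSpec | None = None

    def to_dict(self) -> dict:
        return {
            "true_poses": {str(k): v.to_dict() for k, v in self.true_poses.items()},
            "true_distortion": self.true_distortion.to_dict(),
            "spec": self.spec.to_dict() if self.spec else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            true_poses={int(k): Pose.from_dict(v) for k, v in d["true_poses"].items()},
            true_distortion=DistortionParams.from_dict(d["true_distortion"]),
            plane=None,
            spec=SceneSpec.from_dict(d["spec"]) if d.get("spec") else None,
        )


# ---------------------------------------------------------------------------
# plane textures
# ---------------------------------------------------------------------------

def _blob_field(shape, rng, n_blobs, scale_range, amp_range) -> np.ndarray:
    h, w = shape
    img = np.zeros(shape)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        sy = rng.uniform(*scale_range)
        sx = rng.uniform(*scale_range)
        ang = rng.uniform(0, np.pi)
        amp = rng.uniform(*amp_range) * rng.choice([-1.0, 1.0])
        ext = 3.0 * max(sx, sy)
        y0, y1 = max(0, int(cy - ext)), min(h, int(cy + ext) + 1)
        x0, x1 = max(0, int(cx - ext)), min(w, int(cx + ext) + 1)
        if y1 <= y0 or x1 <= x0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        ca, sa = np.cos(ang), np.sin(ang)
        u = (xx - cx) * ca + (yy - cy) * sa
        v = -(xx - cx) * sa + (yy - cy) * ca
        img[y0:y1, x0:x1] += amp * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))
    return img


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the ground-truth plane and plan the trajectory.

    Deterministic for a fixed seed.  Returns the 8-bit plane raster and a
    :class:`GroundTruth` with the planned true poses and camera.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    w, h = spec.plane_size
    area_scale = (w * h) / (1024.0 * 1024.0)
    if spec.texture == "tissue_blobs":
        n_blobs = max(50, int(800 * area_scale))
        img = _blob_field((h, w), rng, n_blobs, (2.0, 14.0), (40.0, 110.0))
        img += ndi.gaussian_filter(rng.normal(0, 25.0, (h, w)), 1.5)
        img = 120.0 + img
    elif spec.texture == "homogeneous":
        # parenchyma-like: dense low-contrast cells with rare vessel-scale
        # landmarks, the regime where feature matching is weakest
        n_cells = int(30 * w * h / 1000)
        ys = rng.uniform(0, h, n_cells)
        xs = rng.uniform(0, w, n_cells)
        amp = rng.uniform(0.4, 1.0, n_cells) * 16.0 * rng.choice([-1.0, 1.0], n_cells)
        canvas = np.zeros((h, w))
        np.add.at(canvas, (ys.astype(int), xs.astype(int)), amp)
        img = np.full((h, w), 150.0) + ndi.gaussian_filter(canvas, 2.5) * 8.0
        img += _blob_field((h, w), rng, max(3, int(0.3 * w * h / 14400)),
                           (4.0, 9.0), (25.0, 45.0))
        img += ndi.gaussian_filter(rng.normal(0, 3.0, (h, w)), 1.5)
    else:  # sparse
        n_blobs = max(6, int(25 * area_scale))
        img = np.full((h, w), 15.0)
        img += np.abs(_blob_field((h, w), rng, n_blobs, (6.0, 20.0), (120.0, 200.0)))
        img += ndi.gaussian_filter(rng.normal(0, 3.0, (h, w)), 1.0)
    plane = np.clip(img, 0, 255).astype(np.uint8)
    poses = plan_trajectory(spec)
    gt = GroundTruth(
        true_poses=dict(enumerate(poses)),
        true_distortion=spec.camera(),
        plane=plane,
        spec=spec,
    )
    return plane, gt


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _grid_shape(n: int) -> tuple[int, int]:
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    return rows, cols


def _serpentine_offsets(n: int, step_x: int, step_y: int) -> list[tuple[int, int]]:
    rows, cols = _grid_shape(n)
    out = []
    for r in range(rows):
        cs = range(cols) if r % 2 == 0 else range(cols - 1, -1, -1)
        for c in cs:
            out.append((c * step_x, r * step_y))
            if len(out) == n:
                return out
    return out


def _spiral_offsets(n: int, step_x: int, step_y: int) -> list[tuple[int, int]]:
    """Clockwise square spiral on the grid lattice, starting at the center."""
    x = y = 0
    out = [(0, 0)]
    # clockwise in image coordinates (y down): right, down, left, up
    dirs = [(1, 0), (0, 1), (-1, 0), (0, -1)]
    leg = 1
    d = 0
    while len(out) < n:
        for _ in range(2):
            dx, dy = dirs[d % 4]
            for _ in range(leg):
                x, y = x + dx, y + dy
                out.append((x, y))
                if len(out) == n:
                    break
            if len(out) == n:
                break
            d += 1
        leg += 1
    cells = np.array(out[:n])
    cells -= cells.min(axis=0)
    return [(int(cx) * step_x, int(cy) * step_y) for cx, cy in cells]


def _overlap_area(o1, o2, tw, th) -> float:
    w = tw - abs(o1[0] - o2[0])
    h = th - abs(o1[1] - o2[1])
    return max(0.0, w) * max(0.0, h)


def _apply_jitter(offsets, spec: "SceneSpec", rng) -> list[tuple[float, float]]:
    """Perturb grid positions like a hand-driven stage, keeping the
    overlap-maintenance contract for every consecutive pair that had one."""
    tw, th = spec.tile_size
    sigma = spec.jitter_frac * tw
    need = spec.overlap_frac * tw * th
    out = [tuple(map(float, offsets[0]))]
    for i in range(1, len(offsets)):
        # the hand steps from wherever it actually is, by the nominal move
        nominal = (
            out[-1][0] + (offsets[i][0] - offsets[i - 1][0]),
            out[-1][1] + (offsets[i][1] - offsets[i - 1][1]),
        )
        had_overlap = _overlap_area(offsets[i - 1], offsets[i], tw, th) > 0
        chosen = nominal
        for _ in range(50):
            cand = (nominal[0] + rng.normal(0, sigma), nominal[1] + rng.normal(0, sigma))
            if not had_overlap or _overlap_area(out[-1], cand, tw, th) >= need:
                chosen = cand
                break
        out.append(chosen)
    mnx = min(o[0] for o in out)
    mny = min(o[1] for o in out)
    return [(x - mnx, y - mny) for x, y in out]


def plan_trajectory(spec: SceneSpec) -> list[Pose]:
    """True poses along the acquisition path (pose 0 is the anchor origin... in
    plane coordinates; the anchor convention is applied by consumers).

    Consecutive tiles overlap by ≥ ``overlap_frac`` except at the deliberate
    jump of the discontinuous mode, whose tile overlaps an earlier,
    non-previous tile instead.
    """
    tw, th = spec.tile_size
    pw, ph = spec.plane_size
    margin = 8  # room for distortion displacement at tile corners
    step_x = int(round(tw * (1 - spec.overlap_frac)))
    step_y = int(round(th * (1 - spec.overlap_frac)))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))

    if spec.trajectory in ("serpentine", "discontinuous"):
        offsets = _serpentine_offsets(spec.n_tiles, step_x, step_y)
        if spec.trajectory == "discontinuous" and spec.n_tiles >= 4:
            # move a mid-sequence tile to the end: the final capture jumps
            # back over already-imaged territory with no overlap with its
            # immediate predecessor
            k = spec.n_tiles // 2
            offsets = offsets[:k] + offsets[k + 1 :] + [offsets[k]]
    elif spec.trajectory == "spiral":
        offsets = _spiral_offsets(spec.n_tiles, step_x, step_y)
    else:  # random_walk
        offsets = [(0, 0)]
        x = y = 0
        for _ in range(spec.n_tiles - 1):
            for _attempt in range(100):
                dx, dy = rng.choice([(step_x, 0), (-step_x, 0), (0, step_y), (0, -step_y)])
                nx, ny = x + dx, y + dy
                if 0 <= nx <= pw - tw - 2 * margin and 0 <= ny <= ph - th - 2 * margin:
                    x, y = nx, ny
                    break
            offsets.append((x, y))
        mins = np.min(offsets, axis=0)
        offsets = [(int(ox - mins[0]), int(oy - mins[1])) for ox, oy in offsets]

    if spec.jitter_frac > 0:
        offsets = _apply_jitter(offsets, spec, rng)

    max_x = max(o[0] for o in offsets)
    max_y = max(o[1] for o in offsets)
    if max_x + tw + 2 * margin > pw or max_y + th + 2 * margin > ph:
        raise ValueError(
            f"{spec.n_tiles} tiles of {spec.tile_size} do not fit a "
            f"{spec.plane_size} plane with overlap {spec.overlap_frac}"
        )
    poses = []
    for ox, oy in offsets:
        theta = 0.0
        if spec.pose_mode in ("TR", "TRS") and spec.rotation_jitter > 0:
            theta = float(rng.normal(0, spec.rotation_jitter))
        poses.append(
            Pose(mode=spec.pose_mode, a=float(ox + margin), b=float(oy + margin),
                 theta=theta)
        )
    return poses


# ---------------------------------------------------------------------------
# camera
# ---------------------------------------------------------------------------

def _distorted_source_grid(tw: int, th: int, d: DistortionParams) -> np.ndarray:
    """Ideal (pinhole) tile coordinates observed at each integer tile pixel.

    The camera renders observed pixel (u, v) with the plane content at the
    ideal position P⁻¹ ∘ forward-distortion⁻¹ … equivalently: the observed
    image is the ideal image warped by the forward model, so the source of
    (u, v) is the ideal pixel whose forward distortion lands on (u, v).  We
    build that map by inverting the forward model on the pixel grid.
    """
    from .distortion import invert_distortion, pinhole_project

    vv, uu = np.mgrid[0:th, 0:tw]
    obs = np.stack([uu.ravel(), vv.ravel()], axis=1).astype(float)
    if d.is_identity:
        return obs.reshape(th, tw, 2)
    normalized, ok = invert_distortion(obs, d, tol=1e-9, max_iter=60)
    if not ok.all():
        raise ValueError("camera distortion is not invertible over the tile")
    ideal = pinhole_project(normalized, d)
    return ideal.reshape(th, tw, 2)


_GRID_CACHE: dict = {}


def capture_tile(
    plane: np.ndarray,
    pose: Pose,
    d: DistortionParams,
    noise_sigma: float = 0.0,
    exposure_jitter: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render one observed tile from the plane through the camera model.

    Sampling path per observed pixel: undo the lens distortion to find the
    ideal tile coordinate, apply the pose to find the plane coordinate, and
    sample the plane bilinearly.  Then one multiplicative exposure factor
    per tile and additive Gaussian sensor noise.
    """
    th = int(round(2 * d.cy))
    tw = int(round(2 * d.cx))
    key = (tw, th, tuple(sorted(d.to_dict().items())))
    if key not in _GRID_CACHE:
        _GRID_CACHE[key] = _distorted_source_grid(tw, th, d)
    ideal = _GRID_CACHE[key]
    src = pose.apply(ideal.reshape(-1, 2)).reshape(th, tw, 2)
    if (
        src[..., 0].min() < 0
        or src[..., 1].min() < 0
        or src[..., 0].max() > plane.shape[1] - 1
        or src[..., 1].max() > plane.shape[0] - 1
    ):
        raise ValueError("pose places the tile (incl. distortion) outside the plane")
    vals = ndi.map_coordinates(plane.astype(float), [src[..., 1], src[..., 0]], order=1)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    if exposure_jitter > 0:
        vals = vals * (1.0 + rng.uniform(-exposure_jitter, exposure_jitter))
    if noise_sigma > 0:
        vals = vals + rng.normal(0, noise_sigma, vals.shape)
    return np.clip(np.round(vals), 0, 255).astype(np.uint8)


def render_acquisition(spec: SceneSpec) -> tuple[list[np.ndarray], GroundTruth]:
    """Generate the full in-memory acquisition: tile rasters + ground truth."""
    plane, gt = generate_scene(spec)
    cam = spec.camera()
    tiles = [
        capture_tile(
            plane,
            gt.true_poses[i],
            cam,
            noise_sigma=spec.noise_sigma,
            exposure_jitter=spec.exposure_jitter,
            seed=spec.seed * 100003 + i,
        )
        for i in range(spec.n_tiles)
    ]
    return tiles, gt


def emit_acquisition(
    spec: SceneSpec, out_dir: str, interval_ms: float = 0.0
) -> GroundTruth:
    """Write the acquisition as sequentially named TIFFs plus a sidecar.

    ``interval_ms`` spaces out the file writes to emulate a live microscope
    session for the folder watcher.  The ground-truth JSON sidecar
    (``ground_truth.json``) holds true poses, distortion and the spec; the
    plane is saved as ``plane.tif``.
    """
    os.makedirs(out_dir, exist_ok=True)
    tiles, gt = render_acquisition(spec)
    # ground truth lives in a subfolder so folder watchers see only tiles
    truth_dir = os.path.join(out_dir, "truth")
    os.makedirs(truth_dir, exist_ok=True)
    tifffile.imwrite(os.path.join(truth_dir, "plane.tif"), gt.plane)
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(gt.to_dict(), fh)
    for i, raster in enumerate(tiles):
        if interval_ms > 0 and i > 0:
            time.sleep(interval_ms / 1000.0)
        path = os.path.join(out_dir, f"tile_{i:04d}.tif")
        tifffile.imwrite(path + ".part", raster)
        os.replace(path + ".part", path)
    return gt


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset(name: str, seed: int = 0) -> SceneSpec:
    """Named acquisition scenarios used by the CLI and the evaluation runs."""
    presets = {
        "grid9": SceneSpec(
            plane_size=(640, 640), tile_size=(160, 160), n_tiles=9,
            trajectory="serpentine", overlap_frac=0.2, seed=seed,
        ),
        "spiral25": SceneSpec(
            plane_size=(900, 900), tile_size=(160, 160), n_tiles=25,
            trajectory="spiral", overlap_frac=0.25, seed=seed,
        ),
        "liver-stress": SceneSpec(
            plane_size=(640, 640), tile_size=(160, 160), n_tiles=9,
            trajectory="serpentine", texture="homogeneous", overlap_frac=0.3,
            seed=seed,
        ),
        "discontinuous10": SceneSpec(
            plane_size=(800, 640), tile_size=(160, 160), n_tiles=10,
            trajectory="discontinuous", overlap_frac=0.25, seed=seed,
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return presets[name]
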