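"""Shared fixtures: synthetic scenes and registered mosaics.

Heavy end-to-end runs are session-scoped so the whole suite pays for each
acquisition once.
"""

from __future__ import annotations

import copy

import numpy as np
import pytest

from slidestitch.bundle import full_bundle_adjust
from slidestitch.graph import MosaicGraph, Tile
from slidestitch.metrics import rms_reprojection
from slidestitch.registration import RegistrationState, register_tile
from slidestitch.synthgen import (
    SceneSpec,
    default_test_distortion,
    generate_scene,
    render_acquisition,
)


def register_all(tiles, state=None, **state_kwargs):
    """Run the registration engine over in-memory tile rasters."""
    state = state or RegistrationState(**state_kwargs)
    graph = MosaicGraph()
    outcomes = []
    for i, raster in enumerate(tiles):
        tile = Tile(
            id=i,
            source_path=f"mem://{i}",
            width=raster.shape[1],
            height=raster.shape[0],
            pixels=raster,
        )
        graph, outcome = register_tile(graph, state, tile)
        outcomes.append(outcome)
    return graph, state, outcomes


@pytest.fixture(scope="session")
def blob_image():
    """One feature-rich 512×512 synthetic tissue image (seed 1)."""
    spec = SceneSpec(plane_size=(512, 512), tile_size=(128, 128), n_tiles=4, seed=1)
    plane, _ = generate_scene(spec)
    return plane


@pytest.fixture(scope="session")
def grid9_scene():
    """Noiseless 3×3 serpentine acquisition with identity camera."""
    spec = SceneSpec(
        plane_size=(640, 640), tile_size=(160, 160), n_tiles=9,
        trajectory="serpentine", overlap_frac=0.2, seed=1,
    )
    tiles, gt = render_acquisition(spec)
    return spec, tiles, gt


@pytest.fixture(scope="session")
def grid9_run(grid9_scene):
    spec, tiles, gt = grid9_scene
    graph, state, outcomes = register_all(tiles, seed=1)
    return graph, state, outcomes, gt


@pytest.fixture(scope="session")
def discontinuous10_scene():
    spec = SceneSpec(
        plane_size=(800, 640), tile_size=(160, 160), n_tiles=10,
        trajectory="discontinuous", overlap_frac=0.25, seed=1,
    )
    tiles, gt = render_acquisition(spec)
    return spec, tiles, gt


@pytest.fixture(scope="session")
def distortion30_scene():
    """30-tile serpentine captured through a barrel-distorting camera."""
    d = default_test_distortion(256, 256)
    spec = SceneSpec(
        plane_size=(1500, 1300), tile_size=(256, 256), n_tiles=30,
        trajectory="serpentine", overlap_frac=0.3, seed=1,
        distortion=d, noise_sigma=3.0, exposure_jitter=0.05,
    )
    tiles, gt = render_acquisition(spec)
    return spec, tiles, gt


@pytest.fixture(scope="session")
def distortion30_runs(distortion30_scene):
    """Registered graph + composition BA with and without distortion block."""
    spec, tiles, gt = distortion30_scene
    graph, state, _ = register_all(tiles, seed=1)
    poses0 = copy.deepcopy(graph.poses)

    g_no = copy.deepcopy(graph)
    g_no = full_bundle_adjust(g_no, include_distortion=False)
    rms_no = rms_reprojection(g_no, include_distortion=False)

    graph.poses = poses0
    graph.distortion = None
    g_yes = full_bundle_adjust(graph, include_distortion=True, max_iter=200)
    rms_yes = rms_reprojection(g_yes, include_distortion=True)
    return {
        "gt": gt,
        "graph_without": g_no,
        "graph_with": g_yes,
        "rms_without": rms_no,
        "rms_with": rms_yes,
    }
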