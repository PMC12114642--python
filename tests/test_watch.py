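"""Folder monitoring, readiness, live/batch equivalence, checkpointing."""

import json
import os
import threading
import time

import numpy as np
import pytest
import tifffile

from slidestitch.graph import load_project, save_project
from slidestitch.metrics import rms_reprojection
from slidestitch.registration import RegistrationState
from slidestitch.synthgen import SceneSpec, emit_acquisition, preset
from slidestitch.watch import (
    FileEvent,
    WatchConfig,
    is_file_ready,
    load_session,
    run_batch_session,
    run_live_session,
    watch_folder,
)

FAST = dict(poll_interval_ms=20.0, stability_window_ms=40.0)


def state(**kw):
    base = dict(seed=1)
    base.update(kw)
    return RegistrationState(**base)


class TestWatcher:
    def test_no_writes_no_calls(self, tmp_path):
        calls = []
        session = watch_folder(WatchConfig(folder=str(tmp_path), **FAST), calls.append)
        time.sleep(0.2)
        session.stop()
        assert calls == []

    def test_sequential_writes_in_order(self, tmp_path):
        calls = []
        session = watch_folder(WatchConfig(folder=str(tmp_path), **FAST), calls.append)
        img = np.zeros((16, 16), dtype=np.uint8)
        for name in ("a.tif", "b.tif", "c.tif"):
            tifffile.imwrite(tmp_path / name, img)
            time.sleep(0.15)
        time.sleep(0.3)
        session.stop()
        assert [os.path.basename(p) for p in calls] == ["a.tif", "b.tif", "c.tif"]

    def test_extension_filter(self, tmp_path):
        calls = []
        session = watch_folder(WatchConfig(folder=str(tmp_path), **FAST), calls.append)
        (tmp_path / "notes.txt").write_text("not an image")
        time.sleep(0.3)
        session.stop()
        assert calls == []

    def test_duplicate_detection_single_call(self, tmp_path):
        # a file event seen repeatedly over several polls fires once
        calls = []
        session = watch_folder(WatchConfig(folder=str(tmp_path), **FAST), calls.append)
        tifffile.imwrite(tmp_path / "a.tif", np.zeros((16, 16), dtype=np.uint8))
        time.sleep(0.5)
        session.stop()
        assert len(calls) == 1

    def test_missing_folder_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            WatchConfig(folder=str(tmp_path / "nope"))


class TestReadiness:
    def test_complete_file_is_ready(self, tmp_path):
        p = tmp_path / "ok.tif"
        tifffile.imwrite(p, np.zeros((16, 16), dtype=np.uint8))
        cfg = WatchConfig(folder=str(tmp_path), **FAST)
        ev = FileEvent(path=str(p), detected_at=time.time(),
                       size_at_detection=p.stat().st_size)
        assert is_file_ready(ev, cfg)

    def test_growing_file_not_ready(self, tmp_path):
        p = tmp_path / "slow.tif"
        p.write_bytes(b"II*\x00")
        cfg = WatchConfig(folder=str(tmp_path), stability_window_ms=150.0,
                          poll_interval_ms=20.0)
        stop = threading.Event()

        def writer():
            with open(p, "ab") as fh:
                while not stop.is_set():
                    fh.write(b"\x00" * 64)
                    fh.flush()
                    time.sleep(0.02)

        t = threading.Thread(target=writer)
        t.start()
        try:
            ev = FileEvent(path=str(p), detected_at=time.time(),
                           size_at_detection=p.stat().st_size)
            assert not is_file_ready(ev, cfg)
        finally:
            stop.set()
            t.join()

    def test_zero_byte_placeholder_not_ready(self, tmp_path):
        p = tmp_path / "empty.tif"
        p.touch()
        cfg = WatchConfig(folder=str(tmp_path), **FAST)
        ev = FileEvent(path=str(p), detected_at=time.time(), size_at_detection=0)
        assert not is_file_ready(ev, cfg)


@pytest.fixture(scope="module")
def acquisition(tmp_path_factory):
    out = tmp_path_factory.mktemp("acq")
    spec = SceneSpec(plane_size=(640, 640), tile_size=(160, 160), n_tiles=9,
                     trajectory="serpentine", overlap_frac=0.2, seed=3)
    gt = emit_acquisition(spec, str(out))
    return out, gt


class TestSessions:
    def test_live_equals_batch(self, acquisition, tmp_path):
        src, _ = acquisition
        live_dir = tmp_path / "live"
        live_dir.mkdir()

        batch_graph = run_batch_session(str(src), state())

        def feeder():
            for name in sorted(os.listdir(src)):
                if name.startswith("tile_"):
                    data = (src / name).read_bytes()
                    part = live_dir / (name + ".part")
                    part.write_bytes(data)
                    os.replace(part, live_dir / name)
                    time.sleep(0.12)

        t = threading.Thread(target=feeder)
        t.start()
        live_graph = run_live_session(
            WatchConfig(folder=str(live_dir), **FAST),
            state(),
            stop_after=9,
            idle_timeout_s=20.0,
        )
        t.join()
        assert len(live_graph) == len(batch_graph) == 9
        for tid in batch_graph.tile_ids:
            assert live_graph.poses[tid].a == batch_graph.poses[tid].a
            assert live_graph.poses[tid].b == batch_graph.poses[tid].b
        assert rms_reprojection(live_graph) == rms_reprojection(batch_graph)

    def test_checkpoint_resume_matches_uninterrupted(self, acquisition, tmp_path):
        src, _ = acquisition
        project = tmp_path / "project.json"
        work = tmp_path / "work"
        work.mkdir()
        names = sorted(n for n in os.listdir(src) if n.startswith("tile_"))

        # the session dies after 5 of 9 tiles have been written and registered
        for n in names[:5]:
            (work / n).write_bytes((src / n).read_bytes())
        run_batch_session(str(work), state(), project_path=str(project))

        # acquisition continues while the stitcher is down
        for n in names[5:]:
            (work / n).write_bytes((src / n).read_bytes())

        graph, resumed_state = load_session(str(project), seed=1)
        assert len(graph) == 5
        graph = run_batch_session(str(work), resumed_state, graph=graph)
        assert len(graph) == 9

        uninterrupted = run_batch_session(str(work), state())
        assert rms_reprojection(graph) == rms_reprojection(uninterrupted)

    def test_project_round_trip_preserves_rms(self, acquisition, tmp_path):
        src, _ = acquisition
        g = run_batch_session(str(src), state())
        path = tmp_path / "p.json"
        save_project(str(path), g)
        g2, _ = load_project(str(path))
        assert rms_reprojection(g2) == rms_reprojection(g)

    def test_empty_session_valid_empty_project(self, tmp_path):
        project = tmp_path / "p.json"
        g = run_live_session(
            WatchConfig(folder=str(tmp_path), **FAST),
            state(),
            project_path=str(project),
            idle_timeout_s=0.3,
        )
        assert len(g) == 0
        g2, _ = load_project(str(project))
        assert len(g2) == 0

    def test_undecodable_file_skipped_without_consuming_id(self, acquisition, tmp_path):
        src, _ = acquisition
        mixed = tmp_path / "mixed"
        mixed.mkdir()
        names = sorted(n for n in os.listdir(src) if n.startswith("tile_"))
        for n in names[:3]:
            (mixed / n).write_bytes((src / n).read_bytes())
        (mixed / "tile_0001a.tif").write_bytes(b"garbage not a tiff")
        g = run_batch_session(str(mixed), state())
        assert len(g) == 3
        assert sorted(g.tile_ids) == [0, 1, 2]


class TestChannels:
    def test_reference_channel_drives_and_others_attach(self, tmp_path):
        spec = SceneSpec(plane_size=(640, 640), tile_size=(160, 160), n_tiles=4,
                         trajectory="serpentine", overlap_frac=0.3, seed=5)
        from slidestitch.synthgen import render_acquisition

        tiles, _ = render_acquisition(spec)
        for i, r in enumerate(tiles):
            tifffile.imwrite(tmp_path / f"img_{i:02d}_c1.tif", r)
            tifffile.imwrite(tmp_path / f"img_{i:02d}_c2.tif", (r // 2).astype(np.uint8))
        cfg = WatchConfig(
            folder=str(tmp_path),
            ordering="lexicographic",
            channels={"dapi": "*_c1.tif", "phalloidin": "*_c2.tif"},
            ref_channel="dapi",
        )
        g = run_batch_session(str(tmp_path), state(), config=cfg)
        assert len(g) == 4
        for t in g.tiles.values():
            assert t.source_path.endswith("_c1.tif")
            assert t.channel_paths["phalloidin"].endswith("_c2.tif")

        # the second channel composes with the reference channel's poses
        from slidestitch.composition import ComposeOptions, compose_slide

        ref = compose_slide(g, ComposeOptions.evaluation_mode(chunk_px=512))
        other = compose_slide(g, ComposeOptions.evaluation_mode(chunk_px=512),
                              channel="phalloidin")
        assert other.shape == ref.shape
        assert other.mean() < ref.mean()  # the dimmed channel stays dimmer
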