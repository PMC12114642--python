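"""Loosely coupled acquisition controller: folder monitoring and sessions.

The stitcher is one-way coupled to any acquisition software through the
file system: it polls a folder for newly written image files, waits until
each file is completely written (size stable across a window *and*
decodable), and feeds tiles to the registration engine in arrival order.
Batch mode processes an existing folder in lexicographic order, so the two
modes are interchangeable on the same files: same order, same graph.
"""

from __future__ import annotations

import fnmatch
import os
import threading
import time
from dataclasses import dataclass, field

from .graph import MosaicGraph, Tile, save_project
from .imgio import IMAGE_EXTENSIONS, can_decode, read_image
from .registration import RegistrationState, register_tile, render_preview


@dataclass
class WatchConfig:
    folder: str
    extensions: frozenset = frozenset(IMAGE_EXTENSIONS)
    poll_interval_ms: float = 50.0
    stability_window_ms: float = 200.0
    ordering: str = "event_time"  # or "lexicographic"
    channels: dict[str, str] = field(default_factory=dict)  # name -> filename glob
    ref_channel: str | None = None

    def __post_init__(self) -> None:
        if self.poll_interval_ms <= 0:
            raise ValueError("poll_interval_ms must be positive")
        if not os.path.isdir(self.folder):
            raise FileNotFoundError(f"watch folder does not exist: {self.folder}")
        if self.channels and self.ref_channel not in self.channels:
            raise ValueError("ref_channel must name one of the configured channels")

    def matches(self, name: str) -> bool:
        return name.rsplit(".", 1)[-1].lower() in self.extensions

    def channel_of(self, name: str) -> str | None:
        for chan, pattern in self.channels.items():
            if fnmatch.fnmatch(name, pattern):
                return chan
        return None


@dataclass
class FileEvent:
    path: str
    detected_at: float
    size_at_detection: int


def is_file_ready(event: FileEvent, config: WatchConfig) -> bool:
    """A file is ready when its size held still for the stability window
    and it decodes as an image (creation events fire before writes finish)."""
    try:
        size0 = os.path.getsize(event.path)
    except OSError:
        return False
    time.sleep(config.stability_window_ms / 1000.0)
    try:
        size1 = os.path.getsize(event.path)
    except OSError:
        return False
    if size1 != size0 or size1 == 0:
        return False
    return can_decode(event.path)


class WatchSession:
    """Background polling of one folder; ``handler(path)`` once per file."""

    def __init__(self, config: WatchConfig, handler, ignore_existing: bool = True):
        self.config = config
        self.handler = handler
        self._seen: set[str] = set()
        self._pending_events: dict[str, FileEvent] = {}
        self._stop = threading.Event()
        self.error: Exception | None = None
        if ignore_existing:
            self._seen.update(self._scan())
        self._thread = threading.Thread(target=self._run, daemon=True)
        self._thread.start()

    def _scan(self) -> list[str]:
        names = [
            n
            for n in os.listdir(self.config.folder)
            if self.config.matches(n)
        ]
        return [os.path.join(self.config.folder, n) for n in sorted(names)]

    def _run(self) -> None:
        try:
            while not self._stop.is_set():
                for path in self._scan():
                    if path in self._seen or path in self._pending_events:
                        continue
                    self._pending_events[path] = FileEvent(
                        path=path,
                        detected_at=time.time(),
                        size_at_detection=os.path.getsize(path),
                    )
                ready = []
                for path, ev in list(self._pending_events.items()):
                    if is_file_ready(ev, self.config):
                        ready.append((ev.detected_at, path))
                        del self._pending_events[path]
                if self.config.ordering == "lexicographic":
                    ready.sort(key=lambda t: t[1])
                else:
                    ready.sort()
                for _, path in ready:
                    self._seen.add(path)
                    self.handler(path)
                self._stop.wait(self.config.poll_interval_ms / 1000.0)
        except Exception as exc:  # folder vanished mid-session, handler error…
            self.error = exc

    def stop(self) -> None:
        self._stop.set()
        self._thread.join(timeout=10)
        if self.error is not None:
            raise self.error


def watch_folder(config: WatchConfig, handler, ignore_existing: bool = True) -> WatchSession:
    return WatchSession(config, handler, ignore_existing=ignore_existing)


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def _ingest(
    graph: MosaicGraph,
    state: RegistrationState,
    path: str,
    config: WatchConfig,
    project_path: str | None,
    preview_scale: float | None,
) -> str | None:
    """Read one file, register it, checkpoint.  Returns the outcome."""
    name = os.path.basename(path)
    if config.channels:
        chan = config.channel_of(name)
        if chan is None:
            return None
        if chan != config.ref_channel:
            # non-reference channels ride along with the reference tile
            _attach_channel(graph, state, path, chan, config)
            return None
    try:
        pixels = read_image(path)
    except Exception:
        return None  # undecodable: logged-and-skipped, no tile id consumed
    tile = Tile(
        id=_next_tile_id(graph, state),
        source_path=path,
        width=pixels.shape[1],
        height=pixels.shape[0],
        pixels=pixels,
    )
    graph, outcome = register_tile(graph, state, tile)
    if preview_scale:
        preview = render_preview(graph, scale=preview_scale)
        if project_path and preview.size:
            import imageio.v3 as iio

            iio.imwrite(f"{project_path}.preview.png", preview)
    if project_path:
        save_project(
            project_path,
            graph,
            extra={"logs": {"trials": state.trial_log, "times": state.time_log,
                            "ba_triggers": state.ba_trigger_log}},
        )
    return outcome


def _next_tile_id(graph: MosaicGraph, state: RegistrationState) -> int:
    used = set(graph.tile_ids) | {t.id for t in state.pending}
    return max(used) + 1 if used else 0


def _attach_channel(graph, state, path, chan, config) -> None:
    stem = _channel_stem(os.path.basename(path), config.channels[chan])
    for t in graph.tiles.values():
        if _channel_stem(os.path.basename(t.source_path),
                         config.channels[config.ref_channel]) == stem:
            t.channel_paths[chan] = path
            return


def _channel_stem(name: str, pattern: str) -> str:
    # strip the pattern's fixed suffix/prefix around the '*'
    pre, _, post = pattern.partition("*")
    stem = name
    if pre and stem.startswith(pre):
        stem = stem[len(pre):]
    if post and stem.endswith(post):
        stem = stem[: -len(post)]
    return stem


def load_session(project_path: str, **state_kwargs) -> tuple[MosaicGraph, RegistrationState]:
    """Reload a checkpointed session for resuming after an interruption."""
    from .graph import load_project

    graph, meta = load_project(project_path)
    state = RegistrationState(**state_kwargs)
    logs = meta.get("logs", {})
    state.trial_log = list(logs.get("trials", []))
    state.time_log = list(logs.get("times", []))
    state.ba_trigger_log = list(logs.get("ba_triggers", []))
    state.n_registered = len(graph)
    return graph, state


def run_batch_session(
    folder: str,
    state: RegistrationState,
    config: WatchConfig | None = None,
    project_path: str | None = None,
    preview_scale: float | None = None,
    graph: MosaicGraph | None = None,
) -> MosaicGraph:
    """Process all files already in a folder, lexicographic order."""
    config = config or WatchConfig(folder=folder, ordering="lexicographic")
    graph = graph if graph is not None else MosaicGraph()
    names = sorted(n for n in os.listdir(folder) if config.matches(n))
    for name in names:
        path = os.path.join(folder, name)
        if path in graph.source_paths():
            continue  # resume: already registered in the checkpoint
        _ingest(graph, state, path, config, project_path, preview_scale)
    return graph


def run_live_session(
    config: WatchConfig,
    state: RegistrationState,
    project_path: str | None = None,
    preview_scale: float | None = None,
    stop_after: int | None = None,
    idle_timeout_s: float | None = None,
    graph: MosaicGraph | None = None,
) -> MosaicGraph:
    """Watch a folder live; returns the graph when the session ends.

    The session ends after ``stop_after`` registered tiles, or when no new
    file has arrived for ``idle_timeout_s`` seconds (whichever comes first;
    at least one must be given).  State is checkpointed to ``project_path``
    after every registration so a killed session resumes losslessly.
    """
    if stop_after is None and idle_timeout_s is None:
        raise ValueError("give stop_after and/or idle_timeout_s")
    graph = graph if graph is not None else MosaicGraph()
    last_event = [time.time()]

    def handler(path: str) -> None:
        _ingest(graph, state, path, config, project_path, preview_scale)
        last_event[0] = time.time()

    session = watch_folder(config, handler, ignore_existing=False)
    try:
        while True:
            if session.error is not None:
                break
            if stop_after is not None and len(graph) + len(state.pending) >= stop_after:
                break
            if idle_timeout_s is not None and time.time() - last_event[0] > idle_timeout_s:
                break
            time.sleep(0.02)
    finally:
        session.stop()
    if project_path:
        save_project(
            project_path,
            graph,
            extra={"logs": {"trials": state.trial_log, "times": state.time_log,
                            "ba_triggers": state.ba_trigger_log}},
        )
    return graph
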