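"""The mosaic state: tiles, match edges, poses and shared distortion.

A :class:`MosaicGraph` is the whole session in one object.  It serializes to
a JSON project file (poses, inlier match points, logs, config) so a session
can be checkpointed after every registration and resumed bit-exactly:
reloading reproduces the same reprojection RMS.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .distortion import DistortionParams
from .geometry import Pose


@dataclass
class Tile:
    """One captured field of view."""

    id: int
    source_path: str
    width: int
    height: int
    pixels: np.ndarray | None = None  # raster reference; may be dropped after features
    features: object | None = None  # FeatureSet, filled by the registration layer
    channel_paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("tile dimensions must be positive")


@dataclass
class MatchEdge:
    """Inlier point correspondences between tiles i and j (i < j)."""

    tile_i: int
    tile_j: int
    points_i: np.ndarray  # (N, 2) observed pixels in tile i frame
    points_j: np.ndarray  # (N, 2) observed pixels in tile j frame
    relative_pose: Pose | None = None

    def __post_init__(self) -> None:
        if self.tile_i >= self.tile_j:
            raise ValueError("edges are stored with tile_i < tile_j")
        self.points_i = np.asarray(self.points_i, dtype=float).reshape(-1, 2)
        self.points_j = np.asarray(self.points_j, dtype=float).reshape(-1, 2)
        if len(self.points_i) != len(self.points_j):
            raise ValueError("edge point lists must pair up")

    @property
    def n_pairs(self) -> int:
        return len(self.points_i)


class MosaicGraph:
    """Tiles + edges + poses + one shared distortion block."""

    def __init__(self) -> None:
        self.tiles: dict[int, Tile] = {}
        self.poses: dict[int, Pose] = {}
        self.edges: list[MatchEdge] = []
        self._edge_index: set[tuple[int, int]] = set()
        self.distortion: DistortionParams | None = None  # identity until composition
        self.anchor_id: int | None = None
        self.composed_after_ba: bool = False

    # -- structure -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def tile_ids(self) -> list[int]:
        return sorted(self.tiles)

    def add_tile(self, tile: Tile, pose: Pose) -> None:
        if tile.id in self.tiles:
            raise ValueError(f"tile id {tile.id} already registered")
        if self.anchor_id is None:
            # registration always anchors at the identity; standalone graphs
            # (e.g. composition of externally posed tiles) may not
            self.anchor_id = tile.id
        self.tiles[tile.id] = tile
        self.poses[tile.id] = pose

    def has_edge(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self._edge_index

    def add_edge(self, edge: MatchEdge) -> None:
        key = (edge.tile_i, edge.tile_j)
        if key in self._edge_index:
            raise ValueError(f"duplicate edge {key}")
        if edge.tile_i not in self.tiles or edge.tile_j not in self.tiles:
            raise ValueError("edge references unknown tiles")
        self.edges.append(edge)
        self._edge_index.add(key)

    def neighbors(self, tile_id: int) -> set[int]:
        out = set()
        for e in self.edges:
            if e.tile_i == tile_id:
                out.add(e.tile_j)
            elif e.tile_j == tile_id:
                out.add(e.tile_i)
        return out

    def is_connected(self) -> bool:
        if not self.tiles:
            return True
        seen = {self.anchor_id}
        frontier = [self.anchor_id]
        adj: dict[int, set[int]] = {t: set() for t in self.tiles}
        for e in self.edges:
            adj[e.tile_i].add(e.tile_j)
            adj[e.tile_j].add(e.tile_i)
        while frontier:
            u = frontier.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    frontier.append(v)
        return len(seen) == len(self.tiles)

    def total_pairs(self) -> int:
        return sum(e.n_pairs for e in self.edges)

    def source_paths(self) -> set[str]:
        return {t.source_path for t in self.tiles.values()}

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "anchor_id": self.anchor_id,
            "composed_after_ba": self.composed_after_ba,
            "distortion": self.distortion.to_dict() if self.distortion else None,
            "tiles": [
                {
                    "id": t.id,
                    "source_path": t.source_path,
                    "width": t.width,
                    "height": t.height,
                    "channel_paths": t.channel_paths,
                }
                for t in (self.tiles[i] for i in self.tile_ids)
            ],
            "poses": {str(i): self.poses[i].to_dict() for i in self.tile_ids},
            "edges": [
                {
                    "tile_i": e.tile_i,
                    "tile_j": e.tile_j,
                    "points_i": e.points_i.tolist(),
                    "points_j": e.points_j.tolist(),
                    "relative_pose": e.relative_pose.to_dict() if e.relative_pose else None,
                }
                for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MosaicGraph":
        g = cls()
        g.anchor_id = d.get("anchor_id")
        g.composed_after_ba = bool(d.get("composed_after_ba", False))
        if d.get("distortion"):
            g.distortion = DistortionParams.from_dict(d["distortion"])
        for td in d.get("tiles", []):
            t = Tile(
                id=td["id"],
                source_path=td["source_path"],
                width=td["width"],
                height=td["height"],
                channel_paths=td.get("channel_paths", {}),
            )
            g.tiles[t.id] = t
            g.poses[t.id] = Pose.from_dict(d["poses"][str(t.id)])
        for ed in d.get("edges", []):
            e = MatchEdge(
                tile_i=ed["tile_i"],
                tile_j=ed["tile_j"],
                points_i=np.array(ed["points_i"], dtype=float).reshape(-1, 2),
                points_j=np.array(ed["points_j"], dtype=float).reshape(-1, 2),
                relative_pose=Pose.from_dict(ed["relative_pose"])
                if ed.get("relative_pose")
                else None,
            )
            g.edges.append(e)
            g._edge_index.add((e.tile_i, e.tile_j))
        return g


def save_project(path: str, graph: MosaicGraph, extra: dict | None = None) -> None:
    """Write the session state as a JSON project file (atomic replace)."""
    doc = {"format": "slidestitch-project", "version": 1, "graph": graph.to_dict()}
    if extra:
        doc.update(extra)
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        json.dump(doc, fh)
    os.replace(tmp, path)


def load_project(path: str) -> tuple[MosaicGraph, dict]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "slidestitch-project":
        raise ValueError(f"{path} is not a slidestitch project file")
    graph = MosaicGraph.from_dict(doc["graph"])
    meta = {k: v for k, v in doc.items() if k not in ("format", "version", "graph")}
    return graph, meta
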