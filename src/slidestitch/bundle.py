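"""Levenberg–Marquardt bundle adjustment of tile poses and shared distortion.

The bundle problem minimizes reprojection errors of matched feature pairs:
for a pair observed at pixels q_i (tile i) and q_j (tile j), the residual is

    r = T_i(U(q_i)) − T_j(U(q_j))

where U undistorts observed pixels back to ideal pinhole pixels (identity
while the distortion block is disabled) and T is the tile's constrained
affine pose.  The damped update per iteration is

    x_{k+1} = x_k − (JᵀJ + λI)⁻¹ Jᵀ r

with λ divided by 10 on an accepted step (squared-residual sum decreased)
and multiplied by 10 on a rejected one (parameters revert).  The anchor
tile's pose is excluded from the parameter vector (gauge fixing), and one
shared distortion block serves all tiles, because the optical system does
not change between fields of view.

Pose Jacobians are analytic; the distortion block uses forward-difference
numeric derivatives (the inverse distortion map has no closed form).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distortion import DEFAULT_OPTIMIZED_COEFFS, DistortionParams, undistort_pixels
from .geometry import MODE_NPARAMS, Pose
from .graph import MosaicGraph

LAMBDA_INIT = 1e-3
FD_STEP = 1e-6


@dataclass
class BundleProblem:
    """Parameter layout and LM state for one adjustment run."""

    mode: str
    free_ids: list[int]  # non-anchor tile ids, ordered
    include_distortion: bool = False
    coeff_names: tuple[str, ...] = DEFAULT_OPTIMIZED_COEFFS
    lam: float = LAMBDA_INIT
    dropped_pairs: int = 0

    @property
    def n_pose_params(self) -> int:
        return MODE_NPARAMS[self.mode] * len(self.free_ids)

    @property
    def n_params(self) -> int:
        return self.n_pose_params + (len(self.coeff_names) if self.include_distortion else 0)

    def pack(self, graph: MosaicGraph) -> np.ndarray:
        parts = [graph.poses[i].params() for i in self.free_ids]
        if self.include_distortion:
            d = graph.distortion
            parts.append(d.coeffs(self.coeff_names))
        return np.concatenate(parts) if parts else np.empty(0)

    def unpack(self, graph: MosaicGraph, x: np.ndarray) -> None:
        npp = MODE_NPARAMS[self.mode]
        for k, tid in enumerate(self.free_ids):
            graph.poses[tid] = Pose.from_params(self.mode, x[k * npp : (k + 1) * npp])
        if self.include_distortion:
            graph.distortion = graph.distortion.with_coeffs(
                self.coeff_names, x[self.n_pose_params :]
            )


def make_problem(
    graph: MosaicGraph,
    mode: str | None = None,
    include_distortion: bool = False,
    coeff_names: tuple[str, ...] = DEFAULT_OPTIMIZED_COEFFS,
) -> BundleProblem:
    if not graph.edges:
        raise ValueError("bundle adjustment needs at least one edge")
    if mode is None:
        mode = graph.poses[graph.anchor_id].mode
    free_ids = [i for i in graph.tile_ids if i != graph.anchor_id]
    if include_distortion and graph.distortion is None:
        any_tile = graph.tiles[graph.anchor_id]
        graph.distortion = DistortionParams.identity(any_tile.width, any_tile.height)
    return BundleProblem(
        mode=mode,
        free_ids=free_ids,
        include_distortion=include_distortion,
        coeff_names=coeff_names,
    )


def _stack_observations(graph: MosaicGraph):
    """Concatenate edge pairs: observed pixels and tile indices per pair."""
    qi, qj, ti, tj = [], [], [], []
    for e in graph.edges:
        qi.append(e.points_i)
        qj.append(e.points_j)
        ti.append(np.full(e.n_pairs, e.tile_i, dtype=int))
        tj.append(np.full(e.n_pairs, e.tile_j, dtype=int))
    return (
        np.concatenate(qi),
        np.concatenate(qj),
        np.concatenate(ti),
        np.concatenate(tj),
    )


def _undistort_all(
    points: np.ndarray, graph: MosaicGraph, include_distortion: bool
) -> tuple[np.ndarray, np.ndarray]:
    if not include_distortion or graph.distortion is None or graph.distortion.is_identity:
        return np.asarray(points, dtype=float), np.ones(len(points), dtype=bool)
    return undistort_pixels(points, graph.distortion, tol=1e-8, max_iter=50)


def reprojection_residuals(
    graph: MosaicGraph, include_distortion: bool = False, return_dropped: bool = False
):
    """Residual vector over all inlier pairs, 2 components per pair.

    Ordering is deterministic: edge order, then pair order, (x, y)
    interleaved.  Pairs whose undistortion diverges are dropped and counted.
    """
    if not graph.edges:
        raise ValueError("graph has no edges")
    qi, qj, ti, tj = _stack_observations(graph)
    ui, oki = _undistort_all(qi, graph, include_distortion)
    uj, okj = _undistort_all(qj, graph, include_distortion)
    ok = oki & okj
    res = _pose_residuals(graph, ui, uj, ti, tj)
    res = res[ok]
    dropped = int((~ok).sum())
    flat = res.reshape(-1)
    if return_dropped:
        return flat, dropped
    return flat


def _pose_residuals(graph, ui, uj, ti, tj) -> np.ndarray:
    """(N, 2) residuals T_i(ui) − T_j(uj), vectorized over tiles."""
    res = np.empty_like(ui)
    gi = np.empty_like(ui)
    gj = np.empty_like(uj)
    for tid in graph.tile_ids:
        mask = ti == tid
        if mask.any():
            gi[mask] = graph.poses[tid].apply(ui[mask])
        mask = tj == tid
        if mask.any():
            gj[mask] = graph.poses[tid].apply(uj[mask])
    res = gi - gj
    return res


def rms_of(residuals: np.ndarray) -> float:
    """RMS of per-pair Euclidean errors from an interleaved residual vector."""
    if residuals.size == 0:
        return 0.0
    per_pair = residuals.reshape(-1, 2)
    return float(np.sqrt(np.mean(np.sum(per_pair**2, axis=1))))


def _build_jacobian(
    problem: BundleProblem,
    graph: MosaicGraph,
    qi,
    qj,
    ti,
    tj,
    ui,
    uj,
    ok,
) -> np.ndarray:
    """Dense Jacobian of the residuals w.r.t. the packed parameters."""
    npp = MODE_NPARAMS[problem.mode]
    idx_of = {tid: k for k, tid in enumerate(problem.free_ids)}
    n_pairs = int(ok.sum())
    J = np.zeros((2 * n_pairs, problem.n_params))
    sel = np.flatnonzero(ok)
    row_of = {int(p): r for r, p in enumerate(sel)}

    def fill_block(tile_ids, upts, sign):
        for tid in np.unique(tile_ids[sel]):
            tid = int(tid)
            if tid not in idx_of:
                continue  # anchor: gauge-fixed
            col = idx_of[tid] * npp
            pose = graph.poses[tid]
            mask = np.flatnonzero((tile_ids == tid) & ok)
            rows = np.array([row_of[int(m)] for m in mask])
            p = upts[mask]
            J[2 * rows, col + 0] = sign  # d/da
            J[2 * rows + 1, col + 1] = sign  # d/db
            if npp >= 3:
                c, s_ = np.cos(pose.theta), np.sin(pose.theta)
                # d(s R p)/dθ = s R'(θ) p
                dx = pose.s * (-s_ * p[:, 0] - c * p[:, 1])
                dy = pose.s * (c * p[:, 0] - s_ * p[:, 1])
                J[2 * rows, col + 2] = sign * dx
                J[2 * rows + 1, col + 2] = sign * dy
            if npp >= 4:
                c, s_ = np.cos(pose.theta), np.sin(pose.theta)
                J[2 * rows, col + 3] = sign * (c * p[:, 0] - s_ * p[:, 1])
                J[2 * rows + 1, col + 3] = sign * (s_ * p[:, 0] + c * p[:, 1])

    fill_block(ti, ui, +1.0)
    fill_block(tj, uj, -1.0)

    if problem.include_distortion:
        base = _pose_residuals(graph, ui, uj, ti, tj)[ok].reshape(-1)
        d0 = graph.distortion
        for k, name in enumerate(problem.coeff_names):
            d_pert = d0.with_coeffs([name], [getattr(d0, name) + FD_STEP])
            graph.distortion = d_pert
            ui_p, _ = _undistort_all(qi, graph, True)
            uj_p, _ = _undistort_all(qj, graph, True)
            pert = _pose_residuals(graph, ui_p, uj_p, ti, tj)[ok].reshape(-1)
            J[:, problem.n_pose_params + k] = (pert - base) / FD_STEP
        graph.distortion = d0
    return J


def lm_iterate(
    problem: BundleProblem, graph: MosaicGraph
) -> tuple[MosaicGraph, float, bool]:
    """One damped Gauss–Newton step; mutates the graph only on acceptance.

    Returns ``(graph, lambda, accepted)``.
    """
    qi, qj, ti, tj = _stack_observations(graph)
    ui, oki = _undistort_all(qi, graph, problem.include_distortion)
    uj, okj = _undistort_all(qj, graph, problem.include_distortion)
    ok = oki & okj
    problem.dropped_pairs = int((~ok).sum())
    r = _pose_residuals(graph, ui, uj, ti, tj)[ok].reshape(-1)
    sse0 = float(r @ r)
    if problem.n_params == 0:
        return graph, problem.lam, True
    J = _build_jacobian(problem, graph, qi, qj, ti, tj, ui, uj, ok)
    JtJ = J.T @ J
    g = J.T @ r
    A = JtJ + problem.lam * np.eye(problem.n_params)
    try:
        step = np.linalg.solve(A, g)
    except np.linalg.LinAlgError:
        step = np.linalg.lstsq(A, g, rcond=None)[0]

    x0 = problem.pack(graph)
    problem.unpack(graph, x0 - step)
    r_new, _ = reprojection_residuals(
        graph, include_distortion=problem.include_distortion, return_dropped=True
    )
    sse1 = float(r_new @ r_new)
    if sse1 < sse0 or np.allclose(step, 0.0):
        problem.lam = max(problem.lam / 10.0, 1e-15)
        return graph, problem.lam, True
    problem.unpack(graph, x0)  # revert
    problem.lam *= 10.0
    return graph, problem.lam, False


def brief_bundle_adjust(
    graph: MosaicGraph, iterations: int = 1, mode: str | None = None
) -> MosaicGraph:
    """The registration-stage adjustment: a fixed handful of LM iterations.

    Distortion is never included here; the real-time stage trades accuracy
    for speed and leaves the precise correction to composition.
    """
    if not graph.edges:
        return graph
    problem = make_problem(graph, mode=mode, include_distortion=False)
    for _ in range(iterations):
        lm_iterate(problem, graph)
    return graph


def full_bundle_adjust(
    graph: MosaicGraph,
    include_distortion: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
    mode: str | None = None,
    coeff_names: tuple[str, ...] = DEFAULT_OPTIMIZED_COEFFS,
) -> MosaicGraph:
    """Composition-stage adjustment: iterate LM until the RMS converges.

    With ``include_distortion`` one shared distortion block (default
    k1, k2, p1, p2) is optimized jointly with all non-anchor poses.
    """
    if not graph.edges:
        return graph
    problem = make_problem(
        graph, mode=mode, include_distortion=include_distortion, coeff_names=coeff_names
    )
    prev_rms = rms_of(reprojection_residuals(graph, include_distortion=include_distortion))
    rejects = 0
    for _ in range(max_iter):
        graph, _, accepted = lm_iterate(problem, graph)
        if accepted:
            rejects = 0
            cur = rms_of(
                reprojection_residuals(graph, include_distortion=include_distortion)
            )
            if prev_rms > 0 and abs(prev_rms - cur) / max(prev_rms, 1e-30) < tol:
                break
            prev_rms = cur
        else:
            rejects += 1
            if rejects >= 8:  # λ grew 8 decades with no progress: converged
                break
    graph.composed_after_ba = True
    return graph
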