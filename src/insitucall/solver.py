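"""Global position solving and mosaic merging.

The refined constraint graph is an overconstrained linear system: each
constraint contributes the equations s_ij (x'_j - x'_i) = s_ij dx'_ij and
s_ij (y'_j - y'_i) = s_ij dy'_ij, weighted by its ZNCC score so that
reliable constraints dominate. The default solver minimizes the
score-weighted sum of absolute residuals (least absolute deviations) as a
linear program with slack variables — robust to erroneous constraints that
survive filtering. Alternatives: weighted least squares, a maximum-score
spanning tree, and a per-cycle solve followed by one rigid translation per
cycle.

The system is translation-invariant, so one anchor tile is pinned to the
origin. Final positions are integers: either the continuous optimum is
rounded, or the position variables are constrained to integers in the LP.
Merging deliberately avoids fractional resampling — interpolation smears
the ~2 px amplicon dots that downstream base calling depends on.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from insitucall.tiles import (
    INTER_CYCLE,
    INTRA_CYCLE,
    Constraint,
    ConstraintGraph,
    GlobalPositions,
)

#: weight floor: anti-correlated pairs that survive imputation keep a tiny
#: positive weight so the LP stays well-posed
MIN_WEIGHT = 1e-3


def _weight(c: Constraint) -> float:
    s = c.score if c.score is not None else 0.0
    return max(float(s), MIN_WEIGHT)


def _check_refined(constraints: Iterable[Constraint]) -> None:
    for c in constraints:
        if c.dx_refined is None or c.dy_refined is None:
            raise ValueError(
                f"constraint ({c.i}, {c.j}) has no refined offset; "
                "run refine_constraints / filter_and_impute first"
            )


def _components(tile_ids: Sequence[int], constraints: Sequence[Constraint]):
    g = nx.Graph()
    g.add_nodes_from(tile_ids)
    g.add_edges_from((c.i, c.j) for c in constraints)
    return [sorted(comp) for comp in nx.connected_components(g)]


def weighted_mae_objective(
    constraints: Sequence[Constraint], positions: dict[int, tuple[float, float]]
) -> float:
    """Score-weighted sum of absolute residuals of both axes."""
    total = 0.0
    for c in constraints:
        w = _weight(c)
        px, py = positions[c.i]
        qx, qy = positions[c.j]
        total += w * abs((qx - px) - c.dx_refined)
        total += w * abs((qy - py) - c.dy_refined)
    return total


def _solve_axis_lp(
    ids: Sequence[int],
    constraints: Sequence[Constraint],
    offsets: Sequence[float],
    anchor: int,
    integer: bool,
) -> dict[int, float]:
    """LAD solve of one axis: min sum(t+u) s.t. w(x_j - x_i) - t + u = w d."""
    var = {tid: k for k, tid in enumerate(i for i in ids if i != anchor)}
    n_pos = len(var)
    n_con = len(constraints)
    if n_con == 0:
        if n_pos:
            raise ValueError("no constraints to place non-anchor tiles")
        return {anchor: 0.0}
    rows, cols, vals = [], [], []
    b = np.empty(n_con)
    for r, (c, d) in enumerate(zip(constraints, offsets)):
        w = _weight(c)
        if c.j != anchor:
            rows.append(r)
            cols.append(var[c.j])
            vals.append(w)
        if c.i != anchor:
            rows.append(r)
            cols.append(var[c.i])
            vals.append(-w)
        rows.extend([r, r])
        cols.extend([n_pos + 2 * r, n_pos + 2 * r + 1])
        vals.extend([-1.0, 1.0])
        b[r] = w * d
    n_var = n_pos + 2 * n_con
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n_con, n_var))
    cost = np.concatenate([np.zeros(n_pos), np.ones(2 * n_con)])
    bounds = [(None, None)] * n_pos + [(0, None)] * (2 * n_con)
    integrality = None
    if integer:
        integrality = np.concatenate([np.ones(n_pos), np.zeros(2 * n_con)])
    res = linprog(
        cost, A_eq=A, b_eq=b, bounds=bounds, method="highs", integrality=integrality
    )
    if not res.success:
        raise RuntimeError(f"LP solver failed: status {res.status} ({res.message})")
    out = {anchor: 0.0}
    for tid, k in var.items():
        out[tid] = float(res.x[k])
    return out


def _solve_mae(ids, constraints, anchor, integer):
    xs = _solve_axis_lp(ids, constraints, [c.dx_refined for c in constraints], anchor, integer)
    ys = _solve_axis_lp(ids, constraints, [c.dy_refined for c in constraints], anchor, integer)
    return {i: (xs[i], ys[i]) for i in ids}


def _solve_mse(ids, constraints, anchor):
    """Score-weighted least squares with the anchor row removed (gauge)."""
    var = {tid: k for k, tid in enumerate(i for i in ids if i != anchor)}
    n = len(var)
    A = np.zeros((len(constraints), n))
    bx = np.empty(len(constraints))
    by = np.empty(len(constraints))
    for r, c in enumerate(constraints):
        w = _weight(c)
        if c.j != anchor:
            A[r, var[c.j]] += w
        if c.i != anchor:
            A[r, var[c.i]] -= w
        bx[r] = w * c.dx_refined
        by[r] = w * c.dy_refined
    sol_x, *_ = np.linalg.lstsq(A, bx, rcond=None)
    sol_y, *_ = np.linalg.lstsq(A, by, rcond=None)
    out = {anchor: (0.0, 0.0)}
    for tid, k in var.items():
        out[tid] = (float(sol_x[k]), float(sol_y[k]))
    return out


def _solve_spanning_tree(ids, constraints, anchor):
    """Maximum-score spanning tree; offsets accumulated along tree edges."""
    g = nx.Graph()
    g.add_nodes_from(ids)
    for c in constraints:
        w = _weight(c)
        if not g.has_edge(c.i, c.j) or g[c.i][c.j]["weight"] < w:
            g.add_edge(c.i, c.j, weight=w, constraint=c)
    tree = nx.maximum_spanning_tree(g, weight="weight")
    pos = {anchor: (0.0, 0.0)}
    for parent, child in nx.bfs_edges(tree, anchor):
        c = tree[parent][child]["constraint"]
        px, py = pos[parent]
        if c.i == parent:
            pos[child] = (px + c.dx_refined, py + c.dy_refined)
        else:
            pos[child] = (px - c.dx_refined, py - c.dy_refined)
    return pos


def _solve_per_cycle(graph: ConstraintGraph, ids, anchor, integer):
    """MAE solve within each cycle; cycles tied by one median translation."""
    cycles = sorted({graph.tiles[i].cycle for i in ids})
    by_cycle = {cy: [i for i in ids if graph.tiles[i].cycle == cy] for cy in cycles}
    intra = [c for c in graph.constraints if c.kind == INTRA_CYCLE]
    inter = [c for c in graph.constraints if c.kind == INTER_CYCLE]

    local: dict[int, tuple[float, float]] = {}
    for cy in cycles:
        members = by_cycle[cy]
        sub = [c for c in intra if graph.tiles[c.i].cycle == cy]
        comps = _components(members, sub)
        if len(comps) > 1:
            raise ValueError(
                f"cycle {cy} intra-cycle constraints are disconnected: components {comps}"
            )
        cy_anchor = anchor if graph.tiles[anchor].cycle == cy else members[0]
        local.update(_solve_mae(members, sub, cy_anchor, integer))

    ref_cycle = graph.tiles[anchor].cycle
    shift: dict[int, tuple[float, float]] = {ref_cycle: (0.0, 0.0)}
    placed = {ref_cycle}
    remaining = [cy for cy in cycles if cy != ref_cycle]
    while remaining:
        progressed = False
        for cy in list(remaining):
            tx, ty = [], []
            for c in inter:
                ci, cj = graph.tiles[c.i].cycle, graph.tiles[c.j].cycle
                if ci in placed and cj == cy:
                    sx, sy = shift[ci]
                    tx.append(local[c.i][0] + sx + c.dx_refined - local[c.j][0])
                    ty.append(local[c.i][1] + sy + c.dy_refined - local[c.j][1])
                elif cj in placed and ci == cy:
                    sx, sy = shift[cj]
                    tx.append(local[c.j][0] + sx - c.dx_refined - local[c.i][0])
                    ty.append(local[c.j][1] + sy - c.dy_refined - local[c.i][1])
            if tx:
                shift[cy] = (float(np.median(tx)), float(np.median(ty)))
                placed.add(cy)
                remaining.remove(cy)
                progressed = True
        if not progressed:
            raise ValueError(
                f"cycles {sorted(remaining)} have no inter-cycle constraints "
                "to any placed cycle"
            )
    return {
        i: (
            local[i][0] + shift[graph.tiles[i].cycle][0],
            local[i][1] + shift[graph.tiles[i].cycle][1],
        )
        for i in ids
    }


def solve_positions(
    graph: ConstraintGraph,
    method: str = "mae",
    integer_mode: str = "round",
    anchor: Optional[int] = None,
) -> GlobalPositions:
    """Solve the constraint graph for global integer tile positions.

    Parameters
    ----------
    method : {"mae", "mse", "spanning_tree", "per_cycle"}
        ``mae`` (default) minimizes the score-weighted sum of absolute
        residuals by linear programming; ``mse`` solves the score-weighted
        normal equations; ``spanning_tree`` accumulates refined offsets
        along the maximum-score spanning tree; ``per_cycle`` runs the MAE
        solver on each cycle independently and then aligns cycles with a
        single translation each (the median of their inter-cycle offsets).
    integer_mode : {"round", "ilp"}
        ``round`` rounds the continuous optimum (cheap; at most 1 px from
        optimal); ``ilp`` constrains position variables to integers in the
        LP (exact, cost can be high). Only meaningful for LP-based methods.
    anchor : tile id
        Gauge anchor; fixed at (0, 0). Defaults to the lowest tile id.

    Raises
    ------
    ValueError
        If the graph is disconnected (lists the components) or constraints
        are not refined.
    """
    ids = sorted(graph.tiles)
    constraints = graph.constraints
    _check_refined(constraints)
    comps = _components(ids, constraints)
    if len(comps) > 1:
        raise ValueError(f"constraint graph is disconnected: components {comps}")
    if anchor is None:
        anchor = ids[0]
    if anchor not in graph.tiles:
        raise ValueError(f"anchor tile {anchor} not in graph")
    if integer_mode not in ("round", "ilp"):
        raise ValueError(f"unknown integer_mode {integer_mode!r}")
    use_ilp = integer_mode == "ilp"

    if method == "mae":
        pos = _solve_mae(ids, constraints, anchor, use_ilp)
    elif method == "mse":
        pos = _solve_mse(ids, constraints, anchor)
    elif method == "spanning_tree":
        pos = _solve_spanning_tree(ids, constraints, anchor)
    elif method == "per_cycle":
        pos = _solve_per_cycle(graph, ids, anchor, use_ilp)
    else:
        raise ValueError(f"unknown method {method!r}")

    ax, ay = pos[anchor]
    final = {
        i: (int(round(x - ax)), int(round(y - ay))) for i, (x, y) in pos.items()
    }
    objective = weighted_mae_objective(constraints, {i: p for i, p in final.items()})
    return GlobalPositions(positions=final, anchor=anchor, method=method, objective=objective)


def merge_mosaic(
    images: Sequence[np.ndarray],
    positions: Sequence[tuple[int, int]],
    mode: str = "mean",
    canvas_origin: Optional[tuple[int, int]] = None,
    canvas_shape: Optional[tuple[int, int]] = None,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Merge placed tiles of one cycle into a stitched image.

    ``images`` are 2-D (H, W) or 3-D channel-first (C, H, W) arrays;
    ``positions`` the matching integer (x, y) top-left corners. Overlaps
    are resolved per pixel by ``mean`` (average of all covering tiles) or
    ``nearest_center`` (the value from the tile whose center is closest).
    Uncovered canvas is 0. The same placement applies to every channel, so
    fiducial-derived positions carry over to the nucleotide channels.

    Returns the stitched image and the canvas origin (x, y). Pass
    ``canvas_origin``/``canvas_shape`` to merge several cycles onto one
    common canvas.
    """
    if len(images) != len(positions):
        raise ValueError(
            f"{len(images)} images but {len(positions)} positions"
        )
    if not images:
        raise ValueError("no images to merge")
    if mode not in ("mean", "nearest_center"):
        raise ValueError(f"unknown merge mode {mode!r}")
    imgs = [np.asarray(im) for im in images]
    three_d = imgs[0].ndim == 3
    shapes = [(im.shape[-2], im.shape[-1]) for im in imgs]

    if canvas_origin is None:
        ox = min(p[0] for p in positions)
        oy = min(p[1] for p in positions)
    else:
        ox, oy = canvas_origin
    if canvas_shape is None:
        H = max(p[1] + s[0] for p, s in zip(positions, shapes)) - oy
        W = max(p[0] + s[1] for p, s in zip(positions, shapes)) - ox
    else:
        H, W = canvas_shape

    n_ch = imgs[0].shape[0] if three_d else 1
    acc = np.zeros((n_ch, H, W), dtype=np.float64)
    if mode == "mean":
        count = np.zeros((H, W), dtype=np.int64)
    else:
        best = np.full((H, W), np.inf)

    for im, (px, py), (h, w) in zip(imgs, positions, shapes):
        x0, y0 = px - ox, py - oy
        cx0, cy0 = max(0, x0), max(0, y0)
        cx1, cy1 = min(W, x0 + w), min(H, y0 + h)
        if cx1 <= cx0 or cy1 <= cy0:
            continue
        sub = im[..., cy0 - y0 : cy1 - y0, cx0 - x0 : cx1 - x0]
        if not three_d:
            sub = sub[None]
        if mode == "mean":
            acc[:, cy0:cy1, cx0:cx1] += sub
            count[cy0:cy1, cx0:cx1] += 1
        else:
            yy = np.arange(cy0, cy1)[:, None] - (y0 + (h - 1) / 2.0)
            xx = np.arange(cx0, cx1)[None, :] - (x0 + (w - 1) / 2.0)
            dist = yy**2 + xx**2
            closer = dist < best[cy0:cy1, cx0:cx1]
            best[cy0:cy1, cx0:cx1][closer] = dist[closer]
            for ch in range(n_ch):
                acc[ch, cy0:cy1, cx0:cx1][closer] = sub[ch][closer]

    if mode == "mean":
        covered = count > 0
        acc[:, covered] /= count[covered]

    dtype = imgs[0].dtype
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        out = np.clip(np.rint(acc), info.min, info.max).astype(dtype)
    else:
        out = acc.astype(dtype)
    if not three_d:
        out = out[0]
    return out, (ox, oy)


def merge_cycles(
    images_by_cycle: dict[int, Sequence[np.ndarray]],
    positions_by_cycle: dict[int, Sequence[tuple[int, int]]],
    mode: str = "mean",
) -> dict[int, np.ndarray]:
    """Merge every cycle onto one shared canvas so cycles stay comparable."""
    all_pos = [p for ps in positions_by_cycle.values() for p in ps]
    all_shape = [
        (im.shape[-2], im.shape[-1])
        for ims in images_by_cycle.values()
        for im in ims
    ]
    ox = min(p[0] for p in all_pos)
    oy = min(p[1] for p in all_pos)
    H = max(p[1] + s[0] for p, s in zip(all_pos, all_shape)) - oy
    W = max(p[0] + s[1] for p, s in zip(all_pos, all_shape)) - ox
    out = {}
    for cy, ims in images_by_cycle.items():
        merged, _ = merge_mosaic(
            ims,
            positions_by_cycle[cy],
            mode=mode,
            canvas_origin=(ox, oy),
            canvas_shape=(H, W),
        )
        out[cy] = merged
    return out
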