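"""Pairwise constraint refinement and filtering.

Each constraint is refined with a modified phase cross-correlation: the
circular cross-correlation of the two fiducial images is computed in the
frequency domain, the top correlation peaks are expanded into their four
circular-ambiguity interpretations, and every candidate offset is scored
with the zero-normalized cross-correlation (ZNCC) of the overlap it implies.
The best-scoring candidate becomes the refined offset.

Erroneous constraints (blank overlap regions, sparse plating) are detected
by comparing each score against a null distribution: the ZNCC scores of
far-apart (non-overlapping) tile pairs. Constraints below the null
percentile are removed and re-estimated from a robust linear model of the
stage geometry fitted to the surviving constraints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from sklearn.linear_model import LinearRegression, RANSACRegressor

from insitucall.tiles import (
    STATUS_FILTERED,
    STATUS_IMPUTED,
    STATUS_REFINED,
    ConstraintGraph,
    Tile,
)

_EPS = 1e-12


def zncc(region_a: np.ndarray, region_b: np.ndarray) -> float:
    """Zero-normalized cross-correlation of two equally-shaped regions.

    The score is the cosine of the angle between the mean-subtracted,
    unit-normalized flattened regions — invariant to any affine intensity
    change a*I + b with a > 0, and bounded in [-1, 1]. A region with zero
    intensity variance carries no alignment information and scores 0.
    """
    if region_a.shape != region_b.shape:
        raise ValueError(f"shape mismatch: {region_a.shape} vs {region_b.shape}")
    a = np.asarray(region_a, dtype=np.float64).ravel()
    b = np.asarray(region_b, dtype=np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na < _EPS or nb < _EPS:
        return 0.0
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


@dataclass
class RegistrationResult:
    """Outcome of registering one tile pair.

    ``dx, dy`` is the argmax-ZNCC candidate offset (position of the second
    image relative to the first, in pixels of the common frame); ``score``
    its ZNCC; ``candidates`` all (dx, dy, score) triples examined. ``usable``
    is False when every candidate implied a zero-area or zero-variance
    overlap.
    """

    dx: int
    dy: int
    score: float
    candidates: list[tuple[int, int, float]] = field(default_factory=list)
    usable: bool = True


def _overlap_slices(shape_a, shape_b, dx: int, dy: int):
    """Index slices of the overlap of image b placed at (dx, dy) on image a."""
    ha, wa = shape_a
    hb, wb = shape_b
    y0, y1 = max(0, dy), min(ha, hb + dy)
    x0, x1 = max(0, dx), min(wa, wb + dx)
    if y1 <= y0 or x1 <= x0:
        return None
    return (
        (slice(y0, y1), slice(x0, x1)),
        (slice(y0 - dy, y1 - dy), slice(x0 - dx, x1 - dx)),
    )


def _score_offset(img_a: np.ndarray, img_b: np.ndarray, dx: int, dy: int) -> float:
    sl = _overlap_slices(img_a.shape, img_b.shape, dx, dy)
    if sl is None:
        return 0.0
    return zncc(img_a[sl[0]], img_b[sl[1]])


def _as_image(obj) -> np.ndarray:
    img = obj.image if isinstance(obj, Tile) else obj
    if img is None:
        raise ValueError("tile has no image loaded")
    return np.asarray(img, dtype=np.float64)


def _to_common_resolution(img_a, img_b, scale_a, scale_b):
    """Resample the pair onto the finer pixel grid present in the pair.

    The image with the larger pixel size is upscaled (bilinear) by the scale
    ratio so both images share the finer resolution; offsets found on that
    grid are converted back to common-frame pixels with the returned factor.
    """
    fine = min(scale_a, scale_b)
    if scale_a > fine:
        img_a = ndimage.zoom(img_a, scale_a / fine, order=1, grid_mode=True, mode="nearest")
    if scale_b > fine:
        img_b = ndimage.zoom(img_b, scale_b / fine, order=1, grid_mode=True, mode="nearest")
    return img_a, img_b, fine


def phase_correlate(
    tile_i,
    tile_j,
    initial_offset: Optional[tuple[float, float]] = None,
    n_peaks: int = 2,
    window: bool = False,
) -> RegistrationResult:
    """Register a tile pair by modified phase cross-correlation.

    The circular cross-correlation is evaluated via forward/inverse FFT
    (a translation in the spatial domain is a linear phase term in the
    frequency domain). Because the correlation is circular, each peak
    (px, py) is ambiguous among four true offsets (px, py), (px - W, py),
    (px, py - H), (px - W, py - H); the top ``n_peaks`` peaks therefore
    yield ``4 * n_peaks`` candidate offsets, each scored with the ZNCC of
    the overlap it implies. The best-scoring candidate wins; the initial
    stage offset, when given, is the fallback reported when no candidate
    implies a usable overlap.

    Accepts :class:`~insitucall.tiles.Tile` objects or bare 2-D arrays. If
    tile scale factors differ the coarser image is upscaled to the finer
    grid before correlation and the offset is reported in common-frame
    pixels.

    Candidates implying a zero-area overlap score 0; if every candidate is
    degenerate the result has score 0 and ``usable=False``.
    """
    scale_a = tile_i.scale if isinstance(tile_i, Tile) else 1.0
    scale_b = tile_j.scale if isinstance(tile_j, Tile) else 1.0
    img_a = _as_image(tile_i)
    img_b = _as_image(tile_j)
    img_a, img_b, fine = _to_common_resolution(img_a, img_b, scale_a, scale_b)

    H = max(img_a.shape[0], img_b.shape[0])
    W = max(img_a.shape[1], img_b.shape[1])
    a = np.zeros((H, W))
    b = np.zeros((H, W))
    a[: img_a.shape[0], : img_a.shape[1]] = img_a - img_a.mean()
    b[: img_b.shape[0], : img_b.shape[1]] = img_b - img_b.mean()
    if window:
        wy = np.hanning(H)[:, None]
        wx = np.hanning(W)[None, :]
        a = a * wy * wx
        b = b * wy * wx

    fa = np.fft.rfft2(a)
    fb = np.fft.rfft2(b)
    cross = fa * np.conj(fb)
    # phase normalization sharpens the peak for pure translations
    corr = np.fft.irfft2(cross / (np.abs(cross) + _EPS), s=(H, W))

    flat = corr.ravel()
    k = min(max(n_peaks, 1), flat.size)
    peak_idx = np.argpartition(flat, -k)[-k:]
    peak_idx = peak_idx[np.argsort(flat[peak_idx])[::-1]]

    candidates: list[tuple[int, int]] = []
    for idx in peak_idx:
        py, px = divmod(int(idx), W)
        for cx in (px, px - W):
            for cy in (py, py - H):
                if (cx, cy) not in candidates:
                    candidates.append((cx, cy))

    scored: list[tuple[int, int, float]] = []
    best = None
    best_area = -1
    for cx, cy in candidates:
        sl = _overlap_slices(img_a.shape, img_b.shape, cx, cy)
        if sl is None:
            s, area = 0.0, 0
        else:
            s = zncc(img_a[sl[0]], img_b[sl[1]])
            region = img_a[sl[0]]
            area = region.shape[0] * region.shape[1]
        scored.append((cx, cy, s))
        # near-equal scores (e.g. exact circular shifts) resolve toward the
        # interpretation with the larger overlap area
        if best is None or s > best[2] + 1e-9 or (abs(s - best[2]) <= 1e-9 and area > best_area):
            best = (cx, cy, s)
            best_area = area
    assert best is not None
    usable = best_area > 0 and best[2] != 0.0
    if not usable and initial_offset is not None:
        return RegistrationResult(
            dx=int(round(initial_offset[0])),
            dy=int(round(initial_offset[1])),
            score=0.0,
            candidates=scored,
            usable=False,
        )
    # offsets found on the fine grid are expressed in common-frame pixels
    dx = int(round(best[0] * fine))
    dy = int(round(best[1] * fine))
    return RegistrationResult(dx=dx, dy=dy, score=best[2], candidates=scored, usable=usable)


def refine_constraints(graph: ConstraintGraph, n_peaks: int = 2, window: bool = False) -> ConstraintGraph:
    """Refine every constraint in the graph in place.

    Each constraint receives the registered offset, its ZNCC score, and
    status ``refined``. Pairs where registration finds no usable overlap
    keep their initial offset with score 0 (they are removed later by the
    score threshold and imputed).
    """
    for c in graph:
        ti = graph.tiles[c.i]
        tj = graph.tiles[c.j]
        res = phase_correlate(ti, tj, initial_offset=(c.dx, c.dy), n_peaks=n_peaks, window=window)
        if res.score == 0.0:
            c.dx_refined, c.dy_refined = float(c.dx), float(c.dy)
            c.score = 0.0
        else:
            c.dx_refined, c.dy_refined = float(res.dx), float(res.dy)
            c.score = res.score
        c.status = STATUS_REFINED
    return graph


def _far_apart(a: Tile, b: Tile) -> bool:
    # non-overlapping condition: separation of at least two tile extents
    # along x or y guarantees the pair shares no content
    dx = b.x - a.x
    dy = b.y - a.y
    return (
        dx <= -2 * a.w
        or dx >= 2 * b.w
        or dy <= -2 * a.h
        or dy >= 2 * b.h
    )


def compute_score_threshold(
    tiles: Sequence[Tile],
    n_pairs: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
    n_peaks: int = 2,
) -> float:
    """Null-distribution score threshold from far-apart tile pairs.

    Registers ``n_pairs`` randomly sampled pairs of tiles that are far from
    each other (separated by at least two tile extents along x or y, hence
    sharing no content) and returns the given percentile of their ZNCC
    scores. Scores of genuinely overlapping pairs below this threshold are
    indistinguishable from chance.

    Sampling is seeded and reproducible. If fewer than ``n_pairs`` pairs
    qualify, all qualifying pairs are used (with a warning); with none, the
    threshold is 0.
    """
    tiles = list(tiles)
    qualifying = [
        (a, b)
        for ai, a in enumerate(tiles)
        for b in tiles[ai + 1 :]
        if _far_apart(a, b)
    ]
    if not qualifying:
        warnings.warn("no far-apart tile pairs; score threshold set to 0")
        return 0.0
    rng = np.random.default_rng(seed)
    if len(qualifying) > n_pairs:
        idx = rng.choice(len(qualifying), size=n_pairs, replace=False)
        sample = [qualifying[i] for i in idx]
    else:
        if len(qualifying) < n_pairs:
            warnings.warn(
                f"only {len(qualifying)} far-apart pairs available "
                f"(requested {n_pairs}); using all"
            )
        sample = qualifying
    scores = [phase_correlate(a, b, n_peaks=n_peaks).score for a, b in sample]
    return float(np.percentile(scores, percentile))


@dataclass
class RansacParams:
    """Robust stage-model fit parameters.

    ``residual_threshold`` is the floor of the outlier cut in pixels; the
    effective cut adapts upward to 3x the robust scale (1.4826 * MAD) of
    the model residuals, so honest stage-jitter scatter is not flagged
    while grossly wrong registrations (wrong correlation peak) are.
    """

    residual_threshold: float = 3.0
    max_trials: int = 1000
    seed: int = 0


def filter_and_impute(
    graph: ConstraintGraph,
    s_thresh: float,
    ransac_params: Optional[RansacParams] = None,
) -> ConstraintGraph:
    """Remove low-score constraints and re-estimate them from a stage model.

    Constraints scoring below ``s_thresh`` (strict) are removed. A linear
    model mapping initial offsets (dx, dy) to refined offsets (dx', dy') is
    fitted on the survivors with RANSAC; it captures systematic stage
    geometry (consistent travel between tiles, camera angle). RANSAC
    outliers are removed as well. Every removed constraint is replaced by
    the model's prediction with status ``imputed``; imputed constraints are
    weighted no higher than the weakest surviving constraint.

    With too few survivors to fit a model, imputation falls back to the
    identity mapping (dx' = dx) with a warning.
    """
    params = ransac_params or RansacParams()
    for c in graph:
        if c.score is None:
            raise ValueError(f"constraint ({c.i}, {c.j}) is not refined")
    surviving = [c for c in graph if c.score >= s_thresh]
    removed = [c for c in graph if c.score < s_thresh]
    for c in removed:
        c.status = STATUS_FILTERED

    # Stage-model features: the initial offset plus signed per-cycle
    # indicators. Travel between tiles and camera angle are linear in
    # (dx, dy); the plate shift after well re-insertion is exactly one
    # translation per cycle, i.e. an intercept on the cycle-indicator
    # difference. Without the cycle terms every inter-cycle constraint
    # would look like an outlier by construction.
    cycles = sorted({t.cycle for t in graph.tiles.values()})
    cyc_idx = {cy: k for k, cy in enumerate(cycles)}

    def features(cons) -> np.ndarray:
        X = np.zeros((len(cons), 2 + len(cycles)))
        for r, c in enumerate(cons):
            X[r, 0] = c.dx
            X[r, 1] = c.dy
            X[r, 2 + cyc_idx[graph.tiles[c.j].cycle]] += 1.0
            X[r, 2 + cyc_idx[graph.tiles[c.i].cycle]] -= 1.0
        return X

    model = None
    inliers: list = []
    min_fit = 2 + len(cycles) + 1
    if len(surviving) >= max(3, min_fit):
        X = features(surviving)
        Y = np.array([[c.dx_refined, c.dy_refined] for c in surviving])
        try:
            ransac = RANSACRegressor(
                LinearRegression(),
                residual_threshold=params.residual_threshold,
                max_trials=params.max_trials,
                random_state=params.seed,
            )
            ransac.fit(X, Y)
            resid = Y - ransac.predict(X)
            # flag gross registration failures only. Residuals of honest
            # constraints are stage-jitter scatter whose extremes over a
            # few hundred constraints reach ~3-4 robust sigmas; residuals
            # of peak-confusion failures are orders of magnitude larger.
            # A per-axis cut at 6 robust sigmas (scale = 1.4826 * MAD)
            # separates the regimes; the configured pixel threshold is the
            # floor so noise-free data still rejects small inconsistencies.
            scale = 1.4826 * np.median(np.abs(resid), axis=0)
            cut = np.maximum(params.residual_threshold, 6.0 * scale)
            mask = (np.abs(resid) <= cut).all(axis=1)
            if mask.sum() >= 3:
                # final model: ordinary least squares on the inlier set —
                # RANSAC's own consensus-subset fit is noisier
                model = LinearRegression().fit(X[mask], Y[mask])
                for c, ok in zip(surviving, mask):
                    if ok:
                        inliers.append(c)
                    else:
                        c.status = STATUS_FILTERED
                        removed.append(c)
            else:
                warnings.warn("too few RANSAC inliers; using identity imputation")
        except ValueError as exc:
            warnings.warn(f"RANSAC failed ({exc}); using identity imputation")
    else:
        warnings.warn(
            f"only {len(surviving)} surviving constraints; using identity imputation"
        )

    if not removed:
        return graph

    # imputed constraints are weighted like the weakest surviving constraint:
    # enough to anchor tiles that lost all their edges, never dominating
    cap = max(min((c.score for c in (inliers or surviving)), default=0.0), 0.0)
    if model is not None and removed:
        preds = model.predict(features(removed))
    else:
        preds = None
    for k, c in enumerate(removed):
        if preds is not None:
            c.dx_refined, c.dy_refined = float(preds[k][0]), float(preds[k][1])
        else:
            c.dx_refined, c.dy_refined = float(c.dx), float(c.dy)
        c.score = cap
        c.status = STATUS_IMPUTED
    return graph
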