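"""Tile and constraint data model, and adjacency-graph construction.

A multi-cycle acquisition is a set of tiles (fields of view), each with a
stage position, a size, and a cycle index. Overlapping tile pairs become
*constraints*: edges carrying the pixel offset that relates the two tiles.
Intra-cycle edges connect neighboring tiles within one acquisition;
inter-cycle edges connect tiles that image (mostly) the same area in
different cycles. The whole multi-cycle set lives in one graph so that
stitching and cross-cycle alignment are solved jointly.

Coordinate convention: pixel units, origin top-left, x rightward, y downward,
0-based; a tile's (x, y) is its top-left corner in the common
(largest-pixel-size) frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

INTRA_CYCLE = "intra_cycle"
INTER_CYCLE = "inter_cycle"

STATUS_INITIAL = "initial"
STATUS_REFINED = "refined"
STATUS_IMPUTED = "imputed"
STATUS_FILTERED = "filtered"


@dataclass
class Tile:
    """One field-of-view image with its placement metadata.

    Parameters
    ----------
    id : int
        Unique tile index.
    image : ndarray or None
        2-D fiducial-channel intensity array used for registration. May be
        None for purely geometric operations (graph construction, solving).
    x, y : float
        Initial stage position of the top-left corner, in pixels of the
        common coordinate frame.
    w, h : int
        Width and height in pixels of the common frame (i.e. after applying
        ``scale``).
    cycle : int
        Sequencing-cycle index of the acquisition this tile belongs to.
    scale : float
        Relative pixel-size factor: 1.0 when the tile is natively in the
        common frame, e.g. 0.5 for a 20X tile placed in a 10X frame (its
        pixels are half the size, so the raw image is upscaled 2x before
        registration).
    """

    id: int
    image: Optional[np.ndarray]
    x: float
    y: float
    w: int
    h: int
    cycle: int
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"tile {self.id}: non-positive dimensions ({self.w}, {self.h})")
        if self.scale <= 0:
            raise ValueError(f"tile {self.id}: non-positive scale {self.scale}")

    @property
    def area(self) -> float:
        return float(self.w) * float(self.h)


@dataclass
class Constraint:
    """A positional constraint between two overlapping tiles.

    ``dx, dy`` hold the initial offset implied by the stage positions
    (position of tile j minus position of tile i). Registration refines the
    offset to ``dx_refined, dy_refined`` and scores the refined alignment
    with the zero-normalized cross-correlation (``score`` in [-1, 1]).
    ``status`` tracks provenance: refined by registration, filtered out by
    the score threshold / outlier detection, or imputed from the linear
    stage model.
    """

    i: int
    j: int
    dx: float
    dy: float
    kind: str
    dx_refined: Optional[float] = None
    dy_refined: Optional[float] = None
    score: Optional[float] = None
    status: str = STATUS_INITIAL

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError(f"constraint connects tile {self.i} to itself")

    @property
    def refined_offset(self) -> tuple[float, float]:
        if self.dx_refined is None or self.dy_refined is None:
            raise ValueError(f"constraint ({self.i}, {self.j}) has no refined offset")
        return (self.dx_refined, self.dy_refined)


class ConstraintGraph:
    """Tiles plus the constraints connecting them."""

    def __init__(self, tiles: Iterable[Tile], constraints: Iterable[Constraint] = ()):
        self.tiles: dict[int, Tile] = {}
        for t in tiles:
            if t.id in self.tiles:
                raise ValueError(f"duplicate tile id {t.id}")
            self.tiles[t.id] = t
        if not self.tiles:
            raise ValueError("empty tile collection")
        self.constraints: list[Constraint] = []
        self._pairs: set[tuple[int, int]] = set()
        for c in constraints:
            self.add_constraint(c)
        self.score_threshold: Optional[float] = None

    def add_constraint(self, c: Constraint) -> None:
        if c.i not in self.tiles or c.j not in self.tiles:
            raise ValueError(f"constraint ({c.i}, {c.j}) references unknown tile")
        key = (min(c.i, c.j), max(c.i, c.j))
        if key in self._pairs:
            raise ValueError(f"duplicate constraint for pair {key}")
        self._pairs.add(key)
        self.constraints.append(c)

    def __iter__(self) -> Iterator[Constraint]:
        return iter(self.constraints)

    def __len__(self) -> int:
        return len(self.constraints)

    def to_frame(self) -> pd.DataFrame:
        """Constraint dump as a DataFrame (also the CSV resume format)."""
        rows = [
            {
                "i": c.i,
                "j": c.j,
                "kind": c.kind,
                "dx": c.dx,
                "dy": c.dy,
                "dx_refined": c.dx_refined,
                "dy_refined": c.dy_refined,
                "score": c.score,
                "status": c.status,
            }
            for c in self.constraints
        ]
        return pd.DataFrame(rows)

    def apply_frame(self, frame: pd.DataFrame) -> None:
        """Restore refinement results from a previously dumped frame."""
        by_pair = {(min(r.i, r.j), max(r.i, r.j)): r for r in frame.itertuples()}
        for c in self.constraints:
            key = (min(c.i, c.j), max(c.i, c.j))
            if key in by_pair:
                r = by_pair[key]
                sign = 1.0 if r.i == c.i else -1.0
                c.dx_refined = sign * r.dx_refined
                c.dy_refined = sign * r.dy_refined
                c.score = r.score
                c.status = r.status


@dataclass
class GlobalPositions:
    """Integer tile positions in the common mosaic frame.

    The gauge is fixed by anchoring one tile at the origin: the solved
    system determines positions only up to a global translation.
    """

    positions: dict[int, tuple[int, int]]
    anchor: int
    method: str = ""
    objective: Optional[float] = None

    def __getitem__(self, tile_id: int) -> tuple[int, int]:
        return self.positions[tile_id]

    def __len__(self) -> int:
        return len(self.positions)

    def as_array(self, order: Iterable[int]) -> np.ndarray:
        return np.array([self.positions[i] for i in order], dtype=np.int64)


def overlap_fraction(a: Tile, b: Tile) -> float:
    """Fractional overlap of two axis-aligned tiles.

    The intersection extent along x is min(x_i + w_i, x_j + w_j) -
    max(x_i, x_j) (positive iff the intervals intersect), likewise along y;
    the overlap area is normalized by the smaller tile area so that a small
    tile fully inside a large one scores 1.
    """
    ox = min(a.x + a.w, b.x + b.w) - max(a.x, b.x)
    oy = min(a.y + a.h, b.y + b.h) - max(a.y, b.y)
    return max(0.0, ox) * max(0.0, oy) / min(a.area, b.area)


def build_adjacency_graph(
    tiles: Iterable[Tile],
    inter_overlap_min: float = 0.5,
    adjacent_cycles_only: bool = False,
) -> ConstraintGraph:
    """Construct the multi-cycle constraint graph from stage positions.

    Adds an intra-cycle edge for every same-cycle pair whose overlap
    fraction is strictly positive, and an inter-cycle edge for every
    different-cycle pair whose overlap fraction is at least
    ``inter_overlap_min`` (default 0.5: tiles "in the same position" across
    cycles). Each edge stores the initial offset dx = x_j - x_i,
    dy = y_j - y_i with i < j.

    Parameters
    ----------
    adjacent_cycles_only : bool
        If True, inter-cycle edges are only built between consecutive cycle
        indices (cost-saving option; the default connects all cycle pairs).
    """
    tile_list = sorted(tiles, key=lambda t: t.id)
    graph = ConstraintGraph(tile_list)
    n = len(tile_list)
    for ai in range(n):
        a = tile_list[ai]
        for bi in range(ai + 1, n):
            b = tile_list[bi]
            p = overlap_fraction(a, b)
            if a.cycle == b.cycle:
                if p > 0.0:
                    graph.add_constraint(
                        Constraint(a.id, b.id, b.x - a.x, b.y - a.y, INTRA_CYCLE)
                    )
            else:
                if adjacent_cycles_only and abs(a.cycle - b.cycle) != 1:
                    continue
                if p >= inter_overlap_min:
                    graph.add_constraint(
                        Constraint(a.id, b.id, b.x - a.x, b.y - a.y, INTER_CYCLE)
                    )
    return graph


def tiles_from_positions_table(
    frame: pd.DataFrame,
    images: Optional[dict[int, np.ndarray]] = None,
    tile_shape: Optional[tuple[int, int]] = None,
    pixels_per_unit: float = 1.0,
) -> list[Tile]:
    """Build tiles from a positions table.

    The table needs columns ``tile_id, cycle, x, y`` and optionally
    ``scale``. Positions given in microns (or any non-pixel unit) are
    converted with ``pixels_per_unit``. Image arrays are looked up by
    tile_id in ``images``; when absent, ``tile_shape`` (h, w) supplies the
    tile extent.
    """
    required = {"tile_id", "cycle", "x", "y"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"positions table missing columns: {sorted(missing)}")
    tiles = []
    for row in frame.itertuples():
        img = images.get(int(row.tile_id)) if images else None
        scale = float(getattr(row, "scale", 1.0))
        if img is not None:
            h, w = img.shape
            # sizes are expressed in the common frame
            h, w = int(round(h * scale)), int(round(w * scale))
        elif tile_shape is not None:
            h, w = tile_shape
        else:
            raise ValueError("need either images or tile_shape to size tiles")
        tiles.append(
            Tile(
                id=int(row.tile_id),
                image=img,
                x=float(row.x) * pixels_per_unit,
                y=float(row.y) * pixels_per_unit,
                w=w,
                h=h,
                cycle=int(row.cycle),
                scale=scale,
            )
        )
    return tiles


def grid_positions(
    rows: int,
    cols: int,
    tile_w: int,
    tile_h: int,
    overlap: float,
    pattern: str = "row_major",
) -> list[tuple[float, float]]:
    """Nominal tile positions for a declared scanning grid.

    Returns one (x, y) per tile in acquisition order. ``pattern`` is
    ``row_major`` or ``serpentine`` (alternate rows scanned right-to-left,
    the common stage pattern).
    """
    step_x = tile_w * (1.0 - overlap)
    step_y = tile_h * (1.0 - overlap)
    out: list[tuple[float, float]] = []
    for r in range(rows):
        cs: Iterable[int] = range(cols)
        if pattern == "serpentine" and r % 2 == 1:
            cs = range(cols - 1, -1, -1)
        elif pattern not in ("row_major", "serpentine"):
            raise ValueError(f"unknown scan pattern {pattern!r}")
        for c in cs:
            out.append((c * step_x, r * step_y))
    return out
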