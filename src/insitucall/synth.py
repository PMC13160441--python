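"""Synthetic well generator with full ground truth.

Emulates a multi-cycle in situ sequencing acquisition of one well:

* cells as non-overlapping disks (dim in the fiducial channel, labeled in
  the segmentation mask);
* amplicon colonies as ~1.5 px-sigma Gaussian dots placed inside cells,
  each encoding a barcode from a generated library: in cycle c the dot
  lights up in the channel of its barcode's c-th base with amplitude
  A0 * decay^c (signal fades over cycles);
* per-channel linear background buildup (by default in the channels mapped
  to C and A, where fluorophore accumulates in practice);
* additive Gaussian read noise;
* a textured, cycle-invariant fiducial channel (cells on a smooth random
  texture) that registration can lock onto;
* tile cutting with the two acquisition error modes: per-tile intra-cycle
  jitter (stage motor inaccuracy) and a global per-cycle offset (well plate
  removal and replacement between cycles).

Everything derives from a single seed; the truth object retains the real
tile positions, dot locations and per-dot barcodes so every pipeline stage
can be scored.

What this generator does *not* emulate: optical point-spread realism,
vignetting/uneven illumination, nonlinear sample deformation, or
phasing/pre-phasing chemistry errors.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from insitucall.readcall import DEFAULT_CHANNEL_MAP, BarcodeLibrary
from insitucall.tiles import Tile

BASES = "ACGT"


@dataclass
class WellParams:
    """Generation parameters; defaults sized for desk-scale experiments."""

    width: int = 1200
    height: int = 1200
    n_cycles: int = 12
    channel_map: str = DEFAULT_CHANNEL_MAP
    n_cells: int = 80
    cell_radius: tuple[float, float] = (18.0, 28.0)
    n_dots: int = 300
    dot_sigma: float = 1.5
    dot_amplitude: float = 150.0
    decay: float = 0.85
    #: per-cycle additive background increment per channel-map base
    background_rates: dict = field(default_factory=dict)
    #: bases whose channels conventionally accumulate background
    background_bases: str = "CA"
    #: extra noise per unit of accumulated background in a plane — deposits
    #: raise the fluctuation floor of the channels they build up in
    background_noise_factor: float = 0.2
    noise_sigma: float = 2.0
    #: fraction of fluctuation variance that is spatially structured
    #: (smooth, cell-debris/granularity scale) rather than white; real
    #: sequencing planes are structure-dominated, which matters for how
    #: resampling affects dot contrast
    structured_noise_fraction: float = 0.6
    #: Gaussian scale (px) of the structured fluctuation component
    structured_noise_scale: float = 2.0
    n_barcodes: int = 32
    double_barcode: bool = False
    fiducial_cell_amplitude: float = 60.0
    fiducial_texture_amplitude: float = 25.0
    #: pixel-scale structural detail (chromatin granularity, speckle); keeps
    #: the fiducial spectrum broadband the way real nuclear stains are
    fiducial_fine_amplitude: float = 10.0
    fiducial_offset: float = 100.0

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("well dimensions must be positive")
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")
        if len(self.channel_map) != 4 or set(self.channel_map) != set(BASES):
            raise ValueError(f"channel map must permute ACGT, got {self.channel_map!r}")


@dataclass
class SyntheticWellTruth:
    """Ground truth for scoring every pipeline stage."""

    params: WellParams
    seed: int
    library: BarcodeLibrary
    cells: pd.DataFrame  # cell_label, cx, cy, radius, entry index
    dots: pd.DataFrame  # x, y, cell_label, barcode, identifier
    tile_truth: Optional[pd.DataFrame] = None  # tile_id, cycle, x_true, y_true

    def to_json(self) -> str:
        payload = {
            "params": asdict(self.params),
            "seed": self.seed,
            "library": self.library.to_frame().to_dict(orient="list"),
            "cells": self.cells.to_dict(orient="list"),
            "dots": self.dots.to_dict(orient="list"),
        }
        if self.tile_truth is not None:
            payload["tile_truth"] = self.tile_truth.to_dict(orient="list")
        return json.dumps(payload)


def _random_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out = []
    while len(out) < n:
        bc = "".join(BASES[k] for k in rng.integers(0, 4, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def make_library(
    rng: np.random.Generator, n_barcodes: int, length: int, double: bool
) -> BarcodeLibrary:
    """Random unique barcode library (single or ordered-pair entries)."""
    n_codes = 2 * n_barcodes if double else n_barcodes
    codes = _random_barcodes(rng, n_codes, length)
    if double:
        entries = [(codes[2 * k], codes[2 * k + 1]) for k in range(n_barcodes)]
    else:
        entries = [(bc,) for bc in codes]
    ids = [f"BC{k:04d}" for k in range(n_barcodes)]
    return BarcodeLibrary(entries, ids)


def _place_cells(rng: np.random.Generator, params: WellParams):
    """Rejection-sample non-overlapping cell disks away from the border."""
    centers: list[tuple[float, float, float]] = []
    margin = params.cell_radius[1] + 4
    attempts = 0
    while len(centers) < params.n_cells and attempts < params.n_cells * 400:
        attempts += 1
        r = rng.uniform(*params.cell_radius)
        cx = rng.uniform(margin, params.width - margin)
        cy = rng.uniform(margin, params.height - margin)
        if all(
            (cx - ox) ** 2 + (cy - oy) ** 2 >= (r + orad + 6.0) ** 2
            for ox, oy, orad in centers
        ):
            centers.append((cx, cy, r))
    return centers


def _place_dots(
    rng: np.random.Generator,
    cells: Sequence[tuple[float, float, float]],
    n_dots: int,
    min_separation: float = 6.0,
):
    """Place dots well inside cells, pairwise separated so colonies resolve."""
    dots: list[tuple[int, int, int]] = []  # (x, y, cell index)
    attempts = 0
    while len(dots) < n_dots and attempts < n_dots * 400:
        attempts += 1
        ci = int(rng.integers(0, len(cells)))
        cx, cy, r = cells[ci]
        rho = r * 0.7 * math.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        x = int(round(cx + rho * math.cos(theta)))
        y = int(round(cy + rho * math.sin(theta)))
        if all((x - ox) ** 2 + (y - oy) ** 2 >= min_separation**2 for ox, oy, _ in dots):
            dots.append((x, y, ci))
    return dots


def generate_well(
    params: Optional[WellParams] = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, SyntheticWellTruth]:
    """Render a synthetic well.

    Returns ``(well_images, label_mask, truth)`` where ``well_images`` has
    shape (n_cycles, 5, H, W): channel 0 is the fiducial, channels 1-4 the
    nucleotide channels in channel-map order. The fiducial content is
    identical in every cycle (the stain does not change); read noise, when
    enabled, is drawn independently per cycle for every channel including
    the fiducial.
    """
    params = params or WellParams()
    params.validate()
    rng = np.random.default_rng(seed)
    H, W = params.height, params.width

    library = make_library(rng, params.n_barcodes, params.n_cycles, params.double_barcode)

    cells = _place_cells(rng, params)
    cell_entry = rng.integers(0, len(library), size=len(cells))
    label_mask = np.zeros((H, W), dtype=np.int32)
    yy, xx = np.mgrid[0:H, 0:W]
    fiducial = np.full((H, W), params.fiducial_offset)
    fiducial += params.fiducial_texture_amplitude * ndimage.gaussian_filter(
        rng.standard_normal((H, W)), 1.2
    )
    fiducial += params.fiducial_fine_amplitude * rng.standard_normal((H, W))
    for label, (cx, cy, r) in enumerate(cells, start=1):
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        label_mask[disk] = label
        fiducial[disk] += params.fiducial_cell_amplitude
    fiducial = np.clip(fiducial, 0.0, None)

    placed = _place_dots(rng, cells, params.n_dots)
    dot_rows = []
    for x, y, ci in placed:
        entry = library.entries[cell_entry[ci]]
        # double designs: each colony carries one of the cell's two barcodes
        bc = entry[int(rng.integers(0, len(entry)))]
        dot_rows.append(
            {
                "x": x,
                "y": y,
                "cell_label": ci + 1,
                "barcode": bc,
                "identifier": library.identifiers[cell_entry[ci]],
            }
        )
    dots = pd.DataFrame(dot_rows)

    well = np.zeros((params.n_cycles, 5, H, W))
    peak_norm = 2.0 * math.pi * params.dot_sigma**2
    base_rates = dict(params.background_rates)
    for c in range(params.n_cycles):
        well[c, 0] = fiducial
        amp = params.dot_amplitude * params.decay**c * peak_norm
        for ch, base in enumerate(params.channel_map):
            impulses = np.zeros((H, W))
            for row in dot_rows:
                if row["barcode"][c] == base:
                    impulses[row["y"], row["x"]] += amp
            plane = ndimage.gaussian_filter(impulses, params.dot_sigma)
            plane += base_rates.get(base, 0.0) * c
            well[c, ch + 1] = plane
    # plane fluctuations: a floor everywhere plus a component proportional
    # to the accumulated background level; part white (read noise), part
    # smooth structure (granular debris, local fluorophore variation)
    f = params.structured_noise_fraction
    for c in range(params.n_cycles):
        for ch in range(5):
            level = 0.0 if ch == 0 else base_rates.get(params.channel_map[ch - 1], 0.0) * c
            sigma = params.noise_sigma + params.background_noise_factor * level
            if sigma <= 0:
                continue
            field = np.sqrt(1.0 - f) * rng.standard_normal((H, W))
            if f > 0:
                tex = ndimage.gaussian_filter(
                    rng.standard_normal((H, W)), params.structured_noise_scale
                )
                field += np.sqrt(f) * tex / tex.std()
            well[c, ch] += sigma * field

    truth = SyntheticWellTruth(
        params=params,
        seed=seed,
        library=library,
        cells=pd.DataFrame(
            {
                "cell_label": np.arange(1, len(cells) + 1),
                "cx": [c[0] for c in cells],
                "cy": [c[1] for c in cells],
                "radius": [c[2] for c in cells],
                "entry": cell_entry,
            }
        ),
        dots=dots,
    )
    return well, label_mask, truth


def cut_tiles(
    well_images: np.ndarray,
    grid: tuple[int, int] = (4, 4),
    overlap: float = 0.15,
    jitter_sigma: float = 2.0,
    inter_cycle_offset_max: int = 10,
    seed: int = 0,
    pattern: str = "serpentine",
    margin: Optional[int] = None,
) -> tuple[list[np.ndarray], pd.DataFrame, pd.DataFrame]:
    """Cut the well into a tile grid with acquisition-style position error.

    The nominal grid follows the declared scan ``pattern`` with the given
    fractional ``overlap``; each tile's true crop origin adds per-tile
    intra-cycle jitter (Gaussian, sigma ``jitter_sigma``, rounded to
    integers) plus one global inter-cycle offset per cycle (uniform in
    +/- ``inter_cycle_offset_max``; cycle 0 is the reference with zero
    offset). The grid is inset from the well border by ``margin`` pixels
    (default: offset range + 4 jitter sigmas) so positional error never
    pushes a crop off the well — mirroring a scan area inside a larger
    well. A crop that would still leave the well is clamped with a warning
    (its true position then deviates from the additive error model).

    Returns ``(tile_stacks, positions, truth_positions)``: per-tile
    (channels, th, tw) crops; the nominal positions table (what a
    microscope would log: tile_id, cycle, x, y); and the true origins
    (tile_id, cycle, x_true, y_true).
    """
    well_images = np.asarray(well_images)
    if well_images.ndim != 4:
        raise ValueError("well_images must be (cycles, channels, H, W)")
    if not 0.0 < overlap < 1.0:
        raise ValueError(f"overlap must be in (0, 1), got {overlap}")
    n_cycles, _, H, W = well_images.shape
    rows, cols = grid
    if margin is None:
        margin = int(inter_cycle_offset_max + math.ceil(4 * jitter_sigma))
    span_w = W - 2 * margin
    span_h = H - 2 * margin
    tw = math.ceil(span_w / (cols - (cols - 1) * overlap))
    th = math.ceil(span_h / (rows - (rows - 1) * overlap))
    if tw > span_w or th > span_h or span_w <= 0 or span_h <= 0:
        raise ValueError(f"grid {grid} with overlap {overlap} exceeds well size")
    rng = np.random.default_rng(seed)

    nominal: list[tuple[int, int]] = []
    for r in range(rows):
        cs = range(cols)
        if pattern == "serpentine" and r % 2 == 1:
            cs = range(cols - 1, -1, -1)
        elif pattern not in ("row_major", "serpentine"):
            raise ValueError(f"unknown scan pattern {pattern!r}")
        for c in cs:
            nominal.append(
                (
                    margin + int(round(c * tw * (1 - overlap))),
                    margin + int(round(r * th * (1 - overlap))),
                )
            )

    cycle_off = np.zeros((n_cycles, 2), dtype=np.int64)
    if inter_cycle_offset_max > 0 and n_cycles > 1:
        cycle_off[1:] = rng.integers(
            -inter_cycle_offset_max, inter_cycle_offset_max + 1, size=(n_cycles - 1, 2)
        )

    tiles: list[np.ndarray] = []
    pos_rows = []
    truth_rows = []
    tile_id = 0
    for cyc in range(n_cycles):
        for nx, ny in nominal:
            jx, jy = (
                (int(round(v)) for v in rng.normal(0.0, jitter_sigma, size=2))
                if jitter_sigma > 0
                else (0, 0)
            )
            rx = nx + jx + cycle_off[cyc, 0]
            ry = ny + jy + cycle_off[cyc, 1]
            tx = int(np.clip(rx, 0, W - tw))
            ty = int(np.clip(ry, 0, H - th))
            if (tx, ty) != (rx, ry):
                warnings.warn(
                    f"tile {tile_id}: crop ({rx}, {ry}) clamped to ({tx}, {ty})"
                )
            tiles.append(well_images[cyc, :, ty : ty + th, tx : tx + tw].copy())
            pos_rows.append({"tile_id": tile_id, "cycle": cyc, "x": nx, "y": ny})
            truth_rows.append(
                {"tile_id": tile_id, "cycle": cyc, "x_true": tx, "y_true": ty}
            )
            tile_id += 1
    return tiles, pd.DataFrame(pos_rows), pd.DataFrame(truth_rows)


def tiles_for_stitching(
    tile_stacks: Sequence[np.ndarray],
    positions: pd.DataFrame,
    fiducial_channel: int = 0,
) -> list[Tile]:
    """Wrap cut tiles as stitching tiles (fiducial channel as the image)."""
    out = []
    for stack, row in zip(tile_stacks, positions.itertuples()):
        img = stack[fiducial_channel]
        out.append(
            Tile(
                id=int(row.tile_id),
                image=img,
                x=float(row.x),
                y=float(row.y),
                w=img.shape[1],
                h=img.shape[0],
                cycle=int(row.cycle),
            )
        )
    return out
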