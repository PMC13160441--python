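"""High-level pipeline stages chaining the library modules.

These functions are the programmatic equivalents of the CLI subcommands:
stitch a tiled multi-cycle acquisition into aligned per-cycle mosaics,
evaluate residual misalignment, and call + genotype reads from a stitched
stack and a cell label mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from insitucall.evaluate import MisalignmentField, alignment_percentage, block_misalignment
from insitucall.readcall import (
    BarcodeLibrary,
    CellGenotype,
    DotRecord,
    assign_dots_to_cells,
    call_reads,
    consensus_and_match,
    detect_dots,
    filter_stack,
    DEFAULT_CHANNEL_MAP,
)
from insitucall.registration import (
    RansacParams,
    compute_score_threshold,
    filter_and_impute,
    refine_constraints,
)
from insitucall.solver import merge_cycles, solve_positions
from insitucall.synth import tiles_for_stitching
from insitucall.tiles import ConstraintGraph, GlobalPositions, build_adjacency_graph


@dataclass
class StitchConfig:
    inter_overlap_min: float = 0.5
    solver_method: str = "mae"
    integer_mode: str = "round"
    merge_mode: str = "mean"
    threshold_percentile: float = 95.0
    threshold_n_pairs: int = 100
    threshold_seed: int = 0
    n_peaks: int = 2
    ransac: RansacParams = field(default_factory=RansacParams)
    fiducial_channel: int = 0
    anchor: Optional[int] = None


@dataclass
class StitchResult:
    graph: ConstraintGraph
    score_threshold: float
    positions: GlobalPositions
    mosaics: dict[int, np.ndarray]  # cycle -> (channels, H, W) on a shared canvas
    canvas_origin: tuple[int, int]
    #: canvas pixels imaged in every cycle — the area where cross-cycle
    #: comparisons are meaningful
    coverage: Optional[np.ndarray] = None


def run_stitch(
    tile_stacks: Sequence[np.ndarray],
    positions_table: pd.DataFrame,
    config: Optional[StitchConfig] = None,
) -> StitchResult:
    """Stitch and align a multi-cycle tile set.

    ``tile_stacks`` are per-tile (channels, h, w) arrays aligned row-wise
    with ``positions_table`` (columns tile_id, cycle, x, y); the fiducial
    channel drives registration and the derived positions place every
    channel.
    """
    config = config or StitchConfig()
    tiles = tiles_for_stitching(
        tile_stacks, positions_table, fiducial_channel=config.fiducial_channel
    )
    graph = build_adjacency_graph(tiles, inter_overlap_min=config.inter_overlap_min)
    refine_constraints(graph, n_peaks=config.n_peaks)
    s_thresh = compute_score_threshold(
        tiles,
        n_pairs=config.threshold_n_pairs,
        percentile=config.threshold_percentile,
        seed=config.threshold_seed,
        n_peaks=config.n_peaks,
    )
    graph.score_threshold = s_thresh
    filter_and_impute(graph, s_thresh, config.ransac)
    positions = solve_positions(
        graph,
        method=config.solver_method,
        integer_mode=config.integer_mode,
        anchor=config.anchor,
    )

    by_cycle_imgs: dict[int, list[np.ndarray]] = {}
    by_cycle_pos: dict[int, list[tuple[int, int]]] = {}
    for stack, row in zip(tile_stacks, positions_table.itertuples()):
        cy = int(row.cycle)
        by_cycle_imgs.setdefault(cy, []).append(np.asarray(stack))
        by_cycle_pos.setdefault(cy, []).append(positions[int(row.tile_id)])
    mosaics = merge_cycles(by_cycle_imgs, by_cycle_pos, mode=config.merge_mode)
    all_pos = [p for ps in by_cycle_pos.values() for p in ps]
    origin = (min(p[0] for p in all_pos), min(p[1] for p in all_pos))
    H, W = next(iter(mosaics.values())).shape[-2:]
    coverage = np.ones((H, W), dtype=bool)
    for cy, imgs in by_cycle_imgs.items():
        cov = np.zeros((H, W), dtype=bool)
        for im, (px, py) in zip(imgs, by_cycle_pos[cy]):
            h, w = im.shape[-2:]
            cov[py - origin[1] : py - origin[1] + h, px - origin[0] : px - origin[0] + w] = True
        coverage &= cov
    return StitchResult(
        graph=graph,
        score_threshold=s_thresh,
        positions=positions,
        mosaics=mosaics,
        canvas_origin=origin,
        coverage=coverage,
    )


def run_evaluate(
    stitched_fiducials: Sequence[np.ndarray],
    block: int = 200,
    threshold: float = 1.0,
    valid_mask: Optional[np.ndarray] = None,
) -> tuple[MisalignmentField, float]:
    """Block misalignment field and alignment percentage of stitched cycles."""
    fld = block_misalignment(stitched_fiducials, block=block, valid_mask=valid_mask)
    return fld, alignment_percentage(fld, threshold=threshold)


@dataclass
class ReadCallConfig:
    bg_sigma: float = 3.0
    iso_sigma: float = 1.0
    min_sigma: float = 1.0
    max_sigma: float = 3.0
    num_sigma: int = 7
    threshold: float = 0.05
    channel_map: str = DEFAULT_CHANNEL_MAP
    n_keep: int = 2
    double_barcode: Optional[bool] = None
    ordered_pairs: bool = True


def run_callreads(
    stack: np.ndarray,
    label_mask: Optional[np.ndarray] = None,
    config: Optional[ReadCallConfig] = None,
) -> list[DotRecord]:
    """Filter the stack, detect colonies, call reads, assign to cells."""
    config = config or ReadCallConfig()
    extraction, detection = filter_stack(
        stack, bg_sigma=config.bg_sigma, iso_sigma=config.iso_sigma
    )
    locations = detect_dots(
        detection,
        min_sigma=config.min_sigma,
        max_sigma=config.max_sigma,
        num_sigma=config.num_sigma,
        threshold=config.threshold,
    )
    dots = call_reads(extraction, locations, channel_map=config.channel_map)
    if label_mask is not None:
        assign_dots_to_cells(dots, label_mask, image_shape=detection.shape)
    return dots


def run_genotype(
    dots: Sequence[DotRecord],
    library: BarcodeLibrary,
    config: Optional[ReadCallConfig] = None,
) -> list[CellGenotype]:
    config = config or ReadCallConfig()
    return consensus_and_match(
        dots,
        library,
        n_keep=config.n_keep,
        double_barcode=config.double_barcode,
        ordered_pairs=config.ordered_pairs,
    )
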