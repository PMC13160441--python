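"""Amplicon-colony detection, base calling and barcode matching.

Amplicon colonies appear as ~2-3 px dots, bright in exactly one of the four
nucleotide channels per cycle, switching channels across cycles as the
barcode sequence dictates. Everything else is noise to reject: cells are
large, dim-in-all-channels, slowly varying; debris is small but bright in
all channels and static across cycles.

The filter chain exploits these contrasts:

1. subtract a sigma-3 Gaussian blur per (cycle, channel) plane — removes
   large features and the cell background under each dot;
2. z-score each plane — normalizes intensity differences across cycles and
   channels (e.g. fluorophore background building up in the C/A channels);
3. per pixel, subtract the second-largest channel value — keeps only
   single-channel-bright features; blur (sigma 1) and clip at zero;
4. per pixel, standard deviation across cycles, summed over channels —
   colonies change channel every cycle and light up, static features
   vanish.

Dots are detected in the resulting image with Laplacian-of-Gaussian blob
detection; bases are read from the stage-2 stack (background-subtracted,
z-scored) as the argmax channel per cycle; reads are assigned to
segmented cells and per-cell consensus reads are matched against the
barcode library by Levenshtein distance.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import blob_log

#: default channel -> base mapping, in channel order
#: (violet = G, blue = T, green = A, red = C)
DEFAULT_CHANNEL_MAP = "GTAC"


def _check_stack(stack: np.ndarray) -> np.ndarray:
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 4:
        raise ValueError(
            f"expected a (cycles, channels, H, W) stack, got shape {stack.shape}"
        )
    return stack


def background_subtract(stack: np.ndarray, sigma: float = 3.0) -> np.ndarray:
    """Subtract a Gaussian blur from every (cycle, channel) plane.

    The blur sigma is chosen larger than the dot size, so the subtraction
    flattens cells and slowly-varying background fluorescence while leaving
    the small colonies intact; the cell background beneath each dot is
    removed before intensities are extracted. Output may be negative.
    """
    stack = _check_stack(stack)
    return stack - ndimage.gaussian_filter(stack, sigma=sigma, axes=(-2, -1))


def zscore_normalize(stack: np.ndarray) -> np.ndarray:
    """Z-score every (cycle, channel) plane independently.

    Equalizes the large intensity swings across cycles (signal decay) and
    between channels (differential background buildup). A zero-variance
    plane carries no signal and is set to 0 with a warning.
    """
    stack = _check_stack(stack)
    mean = stack.mean(axis=(-2, -1), keepdims=True)
    std = stack.std(axis=(-2, -1), keepdims=True)
    bad = std[..., 0, 0] == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance plane(s) set to 0")
    out = np.zeros_like(stack)
    np.divide(stack - mean, std, out=out, where=std > 0)
    return out


def channel_isolation(stack: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Keep only single-channel-bright signal.

    Per pixel and cycle, the second-largest channel value is subtracted
    from every channel, leaving at most one strictly positive channel per
    pixel. A small Gaussian blur removes the noise this sharpening
    amplifies, then negatives are clipped to zero.
    """
    stack = _check_stack(stack)
    if stack.shape[1] < 2:
        raise ValueError("channel isolation needs at least 2 channels")
    second = np.partition(stack, -2, axis=1)[:, -2:-1]
    out = stack - second
    out = ndimage.gaussian_filter(out, sigma=sigma, axes=(-2, -1))
    return np.clip(out, 0.0, None)


def cycle_std_projection(stack: np.ndarray) -> np.ndarray:
    """Collapse the stack to a 2-D detection image.

    Per-pixel population standard deviation across cycles, summed over
    channels: colonies switch channels every cycle and score high; debris
    and residual cell signal are static and score low.
    """
    stack = _check_stack(stack)
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 cycles for the cycle std projection")
    return stack.std(axis=0, ddof=0).sum(axis=0)


def filter_stack(
    stack: np.ndarray, bg_sigma: float = 3.0, iso_sigma: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Run the full filter chain.

    Returns ``(extraction_stack, detection_image)``: the
    background-subtracted, z-scored stack from which base intensities are
    read, and the channel-isolated cycle-std projection in which dots are
    detected.
    """
    extraction = zscore_normalize(background_subtract(stack, sigma=bg_sigma))
    detection = cycle_std_projection(channel_isolation(extraction, sigma=iso_sigma))
    return extraction, detection


def detect_dots(
    detection_image: np.ndarray,
    min_sigma: float = 1.0,
    max_sigma: float = 3.0,
    num_sigma: int = 7,
    threshold: float = 0.05,
) -> np.ndarray:
    """Laplacian-of-Gaussian blob detection on the detection image.

    Returns an (n, 3) array of (x, y, radius) with radius = sigma * sqrt(2)
    of the best-responding scale. The sigma range brackets the 2-3 px
    colony size.
    """
    img = np.asarray(detection_image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"detection image must be 2-D, got shape {img.shape}")
    blobs = blob_log(
        img,
        min_sigma=min_sigma,
        max_sigma=max_sigma,
        num_sigma=num_sigma,
        threshold=threshold,
    )
    if blobs.size == 0:
        return np.empty((0, 3))
    out = np.empty_like(blobs)
    out[:, 0] = blobs[:, 1]  # x
    out[:, 1] = blobs[:, 0]  # y
    out[:, 2] = blobs[:, 2] * np.sqrt(2.0)
    return out


@dataclass
class DotRecord:
    """One detected amplicon colony and its called read."""

    x: float
    y: float
    radius: float
    intensities: np.ndarray  # (cycles, channels) at the dot pixel
    read: str
    cell_label: int = 0
    #: per-cycle margin between the best and runner-up channel
    margins: Optional[np.ndarray] = None


def call_reads(
    filtered_stack: np.ndarray,
    locations: np.ndarray,
    channel_map: str = DEFAULT_CHANNEL_MAP,
) -> list[DotRecord]:
    """Call one read per detected dot.

    Intensities are read from the background-subtracted, z-scored stack at
    the dot's nearest integer pixel (no sub-pixel interpolation — resampling
    attenuates the dots it would be measuring). The base for each cycle is
    the channel-map letter of the argmax channel; ties break toward the
    first channel in map order (deterministic; measure-zero after blurring).
    """
    stack = _check_stack(filtered_stack)
    n_cycles, n_channels = stack.shape[:2]
    if len(channel_map) != n_channels:
        raise ValueError(
            f"channel map {channel_map!r} does not cover {n_channels} channels"
        )
    H, W = stack.shape[2:]
    dots = []
    for loc in np.atleast_2d(np.asarray(locations, dtype=np.float64)):
        x, y = loc[0], loc[1]
        radius = loc[2] if loc.shape[0] > 2 else 0.0
        px, py = int(round(x)), int(round(y))
        if not (0 <= px < W and 0 <= py < H):
            raise ValueError(f"dot location ({x}, {y}) outside image {H}x{W}")
        inten = stack[:, :, py, px]
        calls = inten.argmax(axis=1)
        read = "".join(channel_map[c] for c in calls)
        ordered = np.sort(inten, axis=1)
        margins = ordered[:, -1] - ordered[:, -2]
        dots.append(
            DotRecord(
                x=float(x),
                y=float(y),
                radius=float(radius),
                intensities=inten.copy(),
                read=read,
                margins=margins,
            )
        )
    return dots


def assign_dots_to_cells(
    dots: Sequence[DotRecord],
    label_mask: np.ndarray,
    image_shape: Optional[tuple[int, int]] = None,
) -> list[DotRecord]:
    """Assign each dot the cell label at its (rounded) pixel.

    Label 0 is background: such dots stay unassigned and are excluded from
    genotyping. ``image_shape`` (when given) must equal the mask shape —
    guards against passing a mask from a different frame.
    """
    mask = np.asarray(label_mask)
    if mask.ndim != 2:
        raise ValueError("label mask must be 2-D")
    if image_shape is not None and tuple(image_shape) != mask.shape:
        raise ValueError(
            f"label mask shape {mask.shape} does not match image shape {tuple(image_shape)}"
        )
    H, W = mask.shape
    for d in dots:
        px, py = int(round(d.x)), int(round(d.y))
        if not (0 <= px < W and 0 <= py < H):
            raise ValueError(f"dot ({d.x}, {d.y}) outside mask frame {H}x{W}")
        d.cell_label = int(mask[py, px])
    return list(dots)


class BarcodeLibrary:
    """The lookup table of expected barcode sequences.

    Entries are single barcodes or ordered (barcode1, barcode2) pairs for
    double-barcode designs; each entry has an identifier (variant or guide
    name). Barcode length must be uniform and entries unique.
    """

    def __init__(self, entries: Sequence[tuple[str, ...]], identifiers: Sequence[str]):
        entries = [tuple(e) for e in entries]
        if not entries:
            raise ValueError("empty barcode library")
        if len(entries) != len(identifiers):
            raise ValueError("entries and identifiers differ in length")
        lengths = {len(bc) for e in entries for bc in e}
        if len(lengths) != 1:
            raise ValueError(f"non-uniform barcode lengths: {sorted(lengths)}")
        if len(set(entries)) != len(entries):
            raise ValueError("duplicate library entries")
        arity = {len(e) for e in entries}
        if len(arity) != 1:
            raise ValueError("mixed single/double entries")
        self.entries = entries
        self.identifiers = list(identifiers)
        self.barcode_length = lengths.pop()
        self.double = arity.pop() == 2

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BarcodeLibrary":
        """Build from a table with columns barcode[, barcode2], identifier."""
        if "barcode" not in frame.columns:
            raise ValueError("library table needs a 'barcode' column")
        ids = (
            frame["identifier"].astype(str).tolist()
            if "identifier" in frame.columns
            else [f"entry{k}" for k in range(len(frame))]
        )
        if "barcode2" in frame.columns:
            entries = list(zip(frame["barcode"].astype(str), frame["barcode2"].astype(str)))
        else:
            entries = [(bc,) for bc in frame["barcode"].astype(str)]
        return cls(entries, ids)

    def to_frame(self) -> pd.DataFrame:
        data = {"barcode": [e[0] for e in self.entries]}
        if self.double:
            data["barcode2"] = [e[1] for e in self.entries]
        data["identifier"] = self.identifiers
        return pd.DataFrame(data)


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


STATUS_MATCHED = "matched"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_UNMATCHED = "unmatched"


@dataclass
class CellGenotype:
    """Per-cell consensus reads and their library match."""

    cell_label: int
    reads: list[tuple[str, int]]  # retained (read, count), most frequent first
    barcodes: tuple[str, ...] = ()
    identifier: Optional[str] = None
    status: str = STATUS_UNMATCHED
    distance: Optional[int] = None


def _retain_top(reads: Counter, n_keep: int) -> list[tuple[str, int]]:
    # most frequent first; count ties at the boundary break lexicographically
    return sorted(reads.items(), key=lambda kv: (-kv[1], kv[0]))[:n_keep]


def _match_single(retained: list[str], library: BarcodeLibrary):
    best = None
    best_entries: set[int] = set()
    for read in retained:
        for k, entry in enumerate(library.entries):
            d = _edit_distance(read, entry[0])
            if best is None or d < best:
                best = d
                best_entries = {k}
            elif d == best:
                best_entries.add(k)
    return best, best_entries


def _match_double(retained: list[str], library: BarcodeLibrary, ordered: bool):
    if len(retained) >= 2:
        pairs = [
            (a, b) for a in retained for b in retained if a != b
        ]
    else:
        pairs = [(retained[0], retained[0])]
    best = None
    best_entries: set[int] = set()
    for k, entry in enumerate(library.entries):
        for a, b in pairs:
            d = _edit_distance(a, entry[0]) + _edit_distance(b, entry[1])
            if not ordered:
                d = min(d, _edit_distance(a, entry[1]) + _edit_distance(b, entry[0]))
            if best is None or d < best:
                best = d
                best_entries = {k}
            elif d == best:
                best_entries.add(k)
    return best, best_entries


def consensus_and_match(
    dots: Sequence[DotRecord],
    library: BarcodeLibrary,
    n_keep: int = 2,
    double_barcode: Optional[bool] = None,
    ordered_pairs: bool = True,
) -> list[CellGenotype]:
    """Form per-cell consensus reads and match them to the library.

    Reads from dots assigned to the same cell are counted; the ``n_keep``
    most frequent unique reads are retained, the rest discarded. In single
    mode each retained read is compared to every library barcode by
    Levenshtein distance and the cell is matched to the unique
    minimal-distance entry (a perfect match is distance 0 and wins
    trivially). In double mode, ordered pairs of retained reads are scored
    against library barcode pairs by summed distance (``ordered_pairs=False``
    also tries the swapped assignment). If two or more entries tie at the
    minimal distance the cell is ambiguous. Cells with zero reads are
    omitted.
    """
    if double_barcode is None:
        double_barcode = library.double
    if double_barcode and not library.double:
        raise ValueError("double-barcode matching requires a paired library")
    if library.double and not double_barcode:
        raise ValueError("paired library requires double-barcode matching")

    per_cell: dict[int, Counter] = {}
    for d in dots:
        if d.cell_label > 0 and d.read:
            per_cell.setdefault(d.cell_label, Counter())[d.read] += 1

    out = []
    for label in sorted(per_cell):
        retained = _retain_top(per_cell[label], n_keep)
        reads = [r for r, _ in retained]
        if double_barcode:
            best, entries = _match_double(reads, library, ordered_pairs)
        else:
            best, entries = _match_single(reads, library)
        geno = CellGenotype(cell_label=label, reads=retained)
        if best is not None and len(entries) == 1:
            k = entries.pop()
            geno.barcodes = library.entries[k]
            geno.identifier = library.identifiers[k]
            geno.status = STATUS_MATCHED
            geno.distance = best
        elif best is not None:
            geno.status = STATUS_AMBIGUOUS
            geno.distance = best
        out.append(geno)
    return out


def genotypes_to_frame(genotypes: Sequence[CellGenotype]) -> pd.DataFrame:
    """cells.csv layout: one row per cell with reads, match and status."""
    rows = []
    for g in genotypes:
        rows.append(
            {
                "cell_label": g.cell_label,
                "reads": ";".join(f"{r}:{n}" for r, n in g.reads),
                "barcode": "|".join(g.barcodes),
                "identifier": g.identifier if g.identifier is not None else "",
                "distance": g.distance if g.distance is not None else "",
                "status": g.status,
            }
        )
    return pd.DataFrame(rows)


def dots_to_frame(dots: Sequence[DotRecord]) -> pd.DataFrame:
    """dots.csv layout: location, size, cell, read and per-cycle margin."""
    rows = []
    for d in dots:
        rows.append(
            {
                "x": d.x,
                "y": d.y,
                "radius": d.radius,
                "cell_label": d.cell_label,
                "read": d.read,
                "min_margin": float(d.margins.min()) if d.margins is not None else "",
            }
        )
    return pd.DataFrame(rows)
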