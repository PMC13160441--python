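# Methods

## Problem setting and assumptions

A multi-cycle *in situ* sequencing acquisition of one well consists of
N_cycles × N_tiles fields of view, each annotated with a stage position
(x, y), a size (w, h), a cycle index, and a pixel-scale factor relative to
the common (largest-pixel) coordinate frame. We assume transformations
between tiles are purely translational (no rotation or nonlinear
deformation), channels within a tile are mutually aligned, and one channel
— the fiducial — images the same content in every cycle. Positions are in
pixel units, origin top-left, x rightward, y downward, 0-based, denoting
the tile's top-left corner; stage tables in microns or grid indices are
converted with a user-supplied pixel size.

## Constraint graph

Tiles are nodes; edges ("constraints") connect overlapping pairs and carry
the offset dx = x_j − x_i, dy = y_j − y_i. The overlap fraction is

    p_ij = max(0, ox)·max(0, oy) / min(w_i h_i, w_j h_j),
    ox = min(x_i+w_i, x_j+w_j) − max(x_i, x_j)   (likewise oy),

the standard intersection extent, positive exactly when the tiles
intersect. Intra-cycle edges require p_ij > 0 (diagonal neighbors with
tiny overlap are included and left to score filtering); inter-cycle edges
require p_ij ≥ 0.5, i.e. tiles at (essentially) the same stage position.
Inter-cycle edges are built between *all* cycle pairs so stitching and
cross-cycle alignment are optimized jointly; an option restricts them to
adjacent cycles when the quadratic cost in cycle count matters.

## Pairwise registration

Each constraint is refined by phase cross-correlation: both fiducial
images are mean-subtracted, zero-padded to a common shape, and the
phase-normalized circular cross-correlation is computed with forward and
inverse FFTs. Because circular correlation folds the plane, each
correlation peak (px, py) is ambiguous among (px, py), (px−W, py),
(px, py−H), (px−W, py−H); the top 2 peaks give 8 candidate offsets, each
scored with the ZNCC (cosine similarity of the mean-subtracted,
unit-normalized overlap the candidate implies; a zero-variance or
zero-area overlap scores 0 rather than raising, so blank fields are
silently filtered later). The best-scoring candidate wins; near-ties
(within 1e-9, e.g. exact circular shifts where a 3-row sliver also scores
1.0) resolve toward the larger overlap area. No window function is applied
before the FFT (a Hann window is available behind a flag); no sub-pixel
peak interpolation is performed — final positions are integers by design.
When the pair mixes objectives, the coarser image is upscaled bilinearly
onto the finer pixel grid of the pair and the recovered offset is
converted back to common-frame pixels.

The initial stage offset is deliberately **not** added as a ninth scored
candidate. For low-texture overlaps it would score high (smooth content
correlates well near the right answer) while being a few pixels wrong,
defeating the null-score filter that is supposed to reject exactly those
pairs; it serves only as the fallback value when registration finds no
usable overlap.

## Score threshold and imputation

The null distribution of ZNCC scores is estimated by registering 100
uniformly sampled far-apart tile pairs (separated by at least two tile
extents along x or y, hence sharing no content); the threshold is the 95th
percentile of their scores. Sampling is seeded. Constraints scoring below
the threshold (strict <) are removed.

A linear stage model then maps each removed constraint to a replacement
offset. Features are the initial offset (dx, dy) — capturing travel
between tiles and camera angle — plus **signed per-cycle indicator
columns**: the plate shift introduced by removing and re-inserting the
well between cycles is exactly one translation per cycle, i.e. an
intercept on the indicator difference. Without these terms every
inter-cycle constraint would be an outlier by construction (its stage
offset is ~0 regardless of the plate shift). The model is fitted with
RANSAC; gross registration failures are then flagged by a per-axis cut at

    max(residual_threshold, 6 × 1.4826 × MAD(residuals)),

with `residual_threshold` = 3 px. The adaptive component matters: honest
residuals are stage-jitter scatter whose extremes over a few hundred
constraints reach 3–4 robust sigmas, while wrong-peak registrations are
off by tens to hundreds of pixels; a fixed 3 px cut would discard correct
measurements and replace them with model predictions, which is precisely
how exact recovery fails. The final imputation model is an ordinary
least-squares refit on the inlier set (RANSAC's own consensus-subset
coefficients are too noisy over ~300 px lever arms). Imputed constraints
receive the weakest surviving inlier's score — enough weight to anchor
tiles that lost all edges, never enough to outvote measurements.

## Global solve

Each constraint contributes s_ij(x'_j − x'_i) = s_ij dx'_ij and the y
analogue, weighted by its ZNCC score (floored at 1e-3 so anti-correlated
survivors cannot destabilize the problem). The default solver minimizes
the weighted sum of absolute residuals via the slack-variable LP (two
equations, four slacks per constraint), solved per axis with HiGHS; the
problem is translation-invariant, so one anchor tile is pinned at (0, 0).
Integer positions come from rounding the continuous optimum (`round`,
default — with integer offsets the constraint matrix is totally
unimodular, so the LP vertex is already integral) or from declaring the
position variables integer (`ilp`; exact but with variable cost).
Alternatives: `mse` solves the score-weighted normal equations with the
anchor column removed; `spanning_tree` accumulates refined offsets along
the maximum-score spanning tree (scores select the tree; accumulation is
unweighted); `per_cycle` runs the MAE solver per cycle and aligns cycles
with one translation each, the median of their inter-cycle offsets. A
disconnected graph is an error listing the components. The reported
objective is the weighted MAE recomputed at the final integer positions.

Merging embeds tiles at integer positions on the bounding-box canvas:
`mean` averages all covering tiles per pixel, `nearest_center` takes the
tile whose center is closest (ties keep the earlier tile). Accumulation is
float64; integer inputs are written back in their dtype with
round-half-even. Fractional resampling during merging is a non-goal:
interpolation attenuates the ~2 px colonies (measured below). The stitch
result records a coverage mask — canvas pixels imaged in *every* cycle —
because cross-cycle comparisons are only meaningful there.

## Alignment evaluation

Stitched cycles are divided into 200×200 px blocks (edge remainders
skipped); every unordered cycle pair is phase-correlated per block, the
error is the L2 norm of the recovered offset, and each block's summary is
the maximum over pairs. Blocks with zero variance in any cycle, or not
fully inside the coverage mask when one is supplied, are missing. The
alignment percentage is 100 × (blocks with error < 1 px) / (non-missing
blocks). Registration is integer-resolution, so sub-pixel misalignment
registers as 0 and the "< 1 px" criterion effectively means "0 px at block
scale". The metric measures self-consistency, not error against ground
truth.

## Read calling

Input is a (cycles × 4 × H × W) stack. The filter chain:

1. **Background subtraction** — subtract a σ=3 Gaussian blur per (cycle,
   channel) plane. Features larger than the blur (cells, smooth
   background) vanish; the cell background beneath each colony is removed
   before intensities are extracted. Output may be negative.
2. **Z-scoring** — each plane to mean 0, sd 1, normalizing intensity
   swings across cycles (signal decay) and channels (background buildup).
   Zero-variance planes are set to 0 with a warning.
3. **Channel isolation** — subtract each pixel's second-highest channel
   value (leaving at most one positive channel), blur σ=1, clip at 0.
   Single-channel-bright colonies pass; cells and debris, bright in all
   channels, are suppressed.
4. **Cycle projection** — per-pixel population standard deviation (ddof 0)
   across cycles, summed over channels. Colonies switch channels every
   cycle and light up; static features vanish.

Colonies are LoG blobs (min_sigma 1, max_sigma 3, num_sigma 7) in the
projection. The detection threshold is a free parameter with default 0.05,
suitable for clean stacks; for synthetic stacks with realistic fluctuation
levels the experiments use 0.5, chosen between the measured blob response
of the generator's correlated background (≤ ~0.3 on z-scored planes) and
that of the dimmest colonies under the default signal model (≥ 1.5), and
fixed thereafter.

Base intensities are read from the **background-subtracted, z-scored**
stack (stages 1–2) at the nearest integer pixel — not from the raw stack
(the σ=3 subtraction exists precisely so extracted values exclude cell
background) and not from the channel-isolated stack (isolation distorts
relative channel values). The base per cycle is the argmax channel under
the map violet→G, blue→T, green→A, red→C (configurable); argmax ties break
toward the first channel in map order. Dots take the cell label at their
rounded pixel; label 0 is background and excluded from genotyping.

Per cell, unique reads are counted and the top `n_keep` = 2 retained
(count ties at the boundary break lexicographically). Single mode: the
cell is matched to the unique library entry at minimal Levenshtein
distance from any retained read (exact matches are distance 0); a tie
between entries makes the cell ambiguous. Double mode: ordered pairs of
retained reads are scored against entry pairs by summed distance (an
unordered option also tries the swap). Each detected dot contributes one
read; no deduplication across detections is attempted.

## Synthetic wells

The generator emulates one well end to end and retains full ground truth
(tile positions per cycle, dot locations, per-dot barcodes). Defaults, all
overridable:

- well 1200×1200 px; 80 non-overlapping cell disks of radius 18–28 px;
  300 colonies placed well inside cells (≥ 6 px apart, so colonies are
  resolvable);
- a 32-entry random barcode library, length = cycle count (12 default);
  double-barcode designs pair entries and give each colony one of its
  cell's two codes;
- colonies are σ=1.5 px Gaussian spots of peak amplitude 150·0.85^c in
  the channel of the barcode's base at cycle c — brightness decays over
  cycles as in real chemistry;
- optional linear background buildup (rate per base letter, conventionally
  C and A) with plane fluctuations of sd = 2 + 0.2 × level, 60% of the
  fluctuation variance spatially structured at σ=2 px (granular debris and
  local fluorophore variation). The structure matters: real sequencing
  planes are structure-dominated, which governs how resampling changes
  dot-to-background contrast;
- the fiducial channel is constant across cycles: cell disks (+60) on a
  smooth texture (σ=1.2, amplitude 25) plus pixel-scale structural detail
  (amplitude 10). The fine component keeps the fiducial spectrum
  broadband the way real nuclear stains are — with only smoothed texture,
  phase correlation at 15% overlap is unreliable (the true peak can rank
  ~20th);
- tile cutting: serpentine (or row-major) grid at 15% overlap; true crop
  origin = nominal + per-tile integer jitter (σ=2 px) + per-cycle global
  offset (uniform ±10 px, cycle 0 zero). The grid is inset from the well
  border by offset range + 4 jitter sigmas so the additive error model
  holds without clamping (a crop that would still leave the well is
  clamped with a warning).

Not emulated: optical PSF realism, vignetting/uneven illumination,
nonlinear deformation, phasing/pre-phasing chemistry errors, and real
segmentation error (the mask is exact). Passing tests therefore establish
algorithmic correctness under the stated error model, not performance on
arbitrary real acquisitions.

## Directional experiments

**Background robustness.** On a 12-cycle stack with decay 0.85 and C/A
buildup reaching the clean stack's 99.9th-percentile intensity (a proxy
for colony signal level) by the last cycle: with the full chain, per-cycle
called-base frequencies stay within ~3–4 percentage points of the
generating barcodes' frequencies; with z-scoring disabled (thresholds
rescaled by the median plane sd for comparability), detection floods with
background structure and the last cycle shows a > 10 pp excess of C calls
— the classic failure signature of channel-specific buildup.

**Shift sensitivity.** Sub-pixel stitching resamples every image by its
fractional offset; integer stitching leaves values untouched but can
misplace a cycle by 1 px. Emulated respectively as a 0.5 px cubic-spline
shift of the whole stack and a 1 px integer shift of one cycle, each
compared against the unperturbed pipeline's reads at the same colonies.
On the background stack, resampling changes ~12–18% of reads and retains
only ~94% of dot-pixel intensity, while the 1 px integer shift changes
~1–3% — the quantitative case for integer-position merging.

## Problem sizes and numerical choices

Tests and the acceptance script use desk-scale problems: a 4×4 grid × 3
cycles (48 tiles of ~312², ~170 constraints) for stitching, 1200² wells
with 300 colonies over 12 cycles for read calling, 200 random graphs of
3–5 tiles for the LP-vs-exhaustive oracle (the exhaustive search box,
radius 3(n−1) around the consistent solution, provably contains every LAD
optimum when perturbations are ≤ 3 px). The LP uses HiGHS through scipy;
LAD weights are floored at 1e-3; ZNCC guards denominators at 1e-12; the
suite derandomizes hypothesis and seeds every generator explicitly.

## Known limitations

Z-scoring assumes roughly equal base frequencies per cycle; heavily skewed
libraries would bias calls (a frequency-aware normalization would be the
extension). The pairwise registration cost grows quadratically in cycle
count. Sub-pixel accuracy is deliberately out of scope end to end. The
block metric cannot see misalignment smaller than a pixel or distinguish
a globally consistent but wrong gauge.
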