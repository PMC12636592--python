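# Methods

This note describes the models and procedures implemented in `issq`, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open.

## Problem setting

An in situ sequencing experiment images a well as a grid of overlapping
microscope tiles, re-acquired once per sequencing cycle.  Two sources of
positional error must be corrected before any per-pixel analysis: within a
cycle, the stage lands a few pixels away from its nominal position at each
tile ("jitter"); between cycles, removing and replacing the well plate adds
a rigid offset to the whole grid.  Because the features of interest —
rolling-circle-amplification colonies — are only 1–3 px across, a single
cycle misaligned by a couple of pixels corrupts every base called from it.
All transformations are assumed purely translational (no rotation, no
nonrigid distortion); a per-cycle scalar magnification can be supplied and
is removed by resampling before correlation.

## Pairwise registration

**Constraint graph.**  Every tile is a node.  For each unordered pair
`(i, j)` with nominal offset `(dx, dy) = pos_j − pos_i`, an edge
("constraint") is created when `−w_j ≤ dx ≤ w_i` and `−h_j ≤ dy ≤ h_i`,
i.e. when the nominal footprints touch.  Intra-cycle and inter-cycle pairs
are treated identically, so every cycle is aligned against every other —
the cost grows quadratically in the cycle count, which is the price of not
privileging any reference cycle.

**Refinement.**  Each constraint is refined by circular cross-correlation
of the two fiducial rasters, computed via FFT.  By default the plain
cross-correlation of mean-removed rasters is used; the classic
phase-normalized variant (`normalization="phase"`) is available but
whitens the spectrum, which makes it unreliable on smooth content whose
high frequencies carry no signal.  Circularity makes each correlation
maximum ambiguous among four true offsets (wrap in x, in y, both, or
neither).  The top two maxima are expanded into their eight candidate
offsets, each candidate is scored by the zero-normalized cross-correlation
(ZNCC) of the overlap it implies, and the best-scoring candidate becomes
the refined offset with its ZNCC stored as the constraint score.
Candidates whose implied overlap is empty, or smaller than 1% of the
smaller tile (`min_overlap_frac=0.01`), are discarded: minuscule overlaps
produce spuriously perfect ZNCC values.  No sub-pixel upsampling is
performed by default — constraints are refined at integer resolution.

**ZNCC.**  Both overlap vectors are mean-centred and scaled to unit norm;
the score is their dot product, in [−1, 1].  A zero-variance overlap is
uninformative and scores 0 (flagged with a warning); an overlap under two
pixels scores −∞ so the candidate is dropped.

**Filtering against a null.**  Tile pairs sharing no content still produce
a best-of-eight ZNCC well above zero, so the pass threshold is estimated
empirically: 100 tile pairs whose nominal separation exceeds twice the
larger tile dimension in both axes are aligned exactly as real pairs are,
and the 95th percentile of their scores (nearest-rank, no interpolation)
becomes `s_thresh`.  Constraints scoring below it are demoted to
`filtered`.  Small collections may not contain 100 such distant pairs; the
sample is then topped up from merely non-overlapping pairs, and — for
collections where every pair genuinely overlaps — from overlapping pairs
evaluated at deliberately wrong offsets (at least half a tile of
displacement), since their aligned score would be no null at all.  Both
relaxations warn.

**Stage model and imputation.**  A linear map from nominal to refined
offsets (2×2 matrix plus intercept, fitted jointly on x and y) is
estimated by RANSAC over the measured, score-passing constraints.  It
captures systematic stage behaviour: actual travel per grid step and any
axis scaling/shear.  The RANSAC residual threshold is 10 px — above
legitimate stage jitter (a few px contributed by each tile of a pair),
well below gross misregistrations (tens to hundreds of px).  Residual
outliers are demoted to `filtered`.  Every filtered constraint then
receives the model-predicted offset with status `imputed`; the edge set
never changes, only offsets, weights and status.  One global model is
fitted across all cycle pairs; per-cycle rigid offsets therefore sit in
the model's residual rather than its intercept.  This only affects imputed
edges, which carry the floor weight (`max(s_thresh, 0.05)`) and cannot
override measured ones; a config switch for per-cycle-pair models exists.

## Global layout

Each active constraint contributes two score-weighted equations,
`s_ij (x'_j − x'_i) = s_ij dx'_ij` and the y analogue.  The system is
overdetermined; the default solver minimizes the weighted sum of absolute
residuals by linear programming, introducing nonnegative slack pairs
`t − u` (x) and `v − w` (y) per constraint and minimizing the slack sum.
The x and y systems are independent and solved separately with HiGHS; the
reported objective is their sum and is re-derivable from the returned
positions (asserted in tests).  Alternatives: `mse` (weighted least
squares on the same rows, solved sparsely) and `spanning_tree` (offsets
accumulated along the maximum-score spanning tree, Kruskal with ties
broken by the smaller tile-id pair).  Positions are gauge-free under
common translation, so the first tile of the first cycle is anchored at
exactly (0, 0); a disconnected graph is solved per component (with a
warning), secondary components anchored at their smallest tile id.

**Integerization.**  `round` snaps each coordinate to the nearest integer
after re-anchoring (at most ~1 px of error); `ilp` re-solves the same
program with integrality on the positions, so its objective is never worse
than rounding's.  The integer solve falls back to rounding, with a
warning, if it exceeds its time limit (default 300 s) — integer solves on
large wells are known to be erratic in cost.

**Merging.**  Tiles are rendered into one frame shared by all cycles.
`mean` averages contributing tiles per pixel; `nearest_center` keeps the
value from the tile whose centre is closest.  Pixels with no contributor
are empty, not zero: a per-cycle coverage count is stored (and written as
a sidecar TIFF, since integer TIFF has no NaN).

## Alignment evaluation

The stitched fiducial rasters are divided into 200×200 px blocks (partial
edge blocks are dropped; FFTs on slivers are unstable).  For every block
and cycle pair, phase cross-correlation (scikit-image, integer resolution
to match the <1 px binning; 10× upsampling behind a flag) measures the
residual offset; the block error is the maximum L2 norm over cycle pairs.
Blocks that are featureless (near-zero variance) or not fully covered in
some cycle yield random offsets and are excluded and counted.  Summaries:
the median block error (robust to residual featureless blocks) and the
alignment percentage — the share of blocks with error < 1 px — reported
with both the evaluated-blocks denominator and the all-blocks denominator,
since either convention is defensible.

## Read calling

The aligned stack `f(t, c, y, x)` (cycles × the four sequencing channels
G, T, A, C × space) passes through four filters, in order, each tagged on
the stack so misordering raises:

1. **Background subtraction** (σ = 3): subtract a Gaussian blur of each
   (cycle, channel) plane from itself, removing structures larger than a
   colony — cell bodies and the in-cell fluorescent background.  Negative
   values are kept.
2. **Z-scoring**: each plane to mean 0, sd 1, flattening the large
   intensity differences between channels and across cycles (colony
   brightness decays; dye background builds up unevenly, mostly in A and
   C).  This assumes roughly equal base frequencies per cycle across the
   library.  Zero-variance planes are zeroed with a warning.  The step can
   be toggled off.
3. **Second-max suppression**: per pixel, subtract the second-largest
   channel value from all channels and clip at zero — only
   single-channel-bright structures survive, with at most one nonzero
   channel per pixel.  A σ = 1 blur follows, because the subtraction
   amplifies pixel noise.
4. **Temporal std projection**: standard deviation across cycles
   (population convention, ÷N) per channel and pixel, summed over
   channels.  Colonies switch channels every cycle and light up; static
   debris vanishes.

Colonies are detected on the projection by multi-scale
Laplacian-of-Gaussian blob detection (`min_sigma=1, max_sigma=3,
num_sigma=7`, scikit-image).  The response threshold has no canonical
value; the default 0.3 (z-score units) was fixed on the synthetic
fixtures, where recovery is insensitive to it over at least 0.2–0.5, and
it is exposed as a documented parameter everywhere.

Colony values are read at the rounded centre pixel (a 3×3-max footprint is
available) from the **normalized** stack by default — extraction from the
background-filtered or raw stack is a config switch, as either convention
is used in practice.  The base per cycle is the argmax channel; exact ties
take the fixed priority order G, T, A, C and set a flag.  Reads are
assigned to the cell whose label sits under the exact centre pixel (no
dilation; label 0 = background is kept in the colony table but excluded
from cell consensus).  Per cell, the top `k = 2` reads by count are
retained (count ties broken lexicographically, flagged), then matched to
the library by minimal Levenshtein distance over (retained read × entry):
a unique minimizer matches the cell, tied minimizers leave it ambiguous,
and a minimum above `max_distance` (default ∞) leaves it unmatched.  In
double-barcode mode entries are ordered pairs; the two retained reads are
assigned to the two slots in whichever order minimizes the combined
distance, with the same uniqueness rule.

## Synthetic data

The generator exists to give every stage an exact oracle, and its defaults
are the conditions the tests run under.

*Geometry.*  Tiles are crops of one latent field per cycle, so noiseless
overlaps are pixel-identical — the fixed point registration tests need.
True position = nominal grid position + integer jitter
(`round(N(0, jitter_sd))`, default 2 px) + per-cycle rigid offset; the
grid stride is `floor(size · (1 − overlap))`.  Scenes where jitter could
destroy overlaps (`overlap · min(w, h) ≤ 2 · jitter_sd`) are refused.  The
default fiducial texture is unit-σ-smoothed Gaussian noise (mean 100,
sd 30): dense fine-grained features everywhere, so any overlap is
registrable.  Readout noise is added per tile after cropping, so
overlapping tiles carry independent noise realisations.

*Photometry.*  Cells are non-overlapping disks (radius 10–16 px) placed by
rejection sampling; each carries one library barcode and (default) four
colonies placed uniformly inside it.  A colony adds a Gaussian dot
(σ = 1.5 px) of peak `amplitude · decay^t` (default amplitude 100) to the
channel of base `t` of its barcode.  Background builds up linearly over
cycles in the A and C channels only (configurable), and i.i.d. Gaussian
noise is added last.

*What is not emulated.*  Optics (PSF, vignetting, chromatic shift),
rotation or nonrigid distortion, non-Gaussian camera noise, colony size
variation, overlapping cells, and segmentation errors (the mask is exact).
Passing tests therefore demonstrate the correctness of the algorithms
under their stated assumptions, not robustness to every artefact of real
microscopes.

## Numerical choices

- Correlation candidates are ranked by ZNCC with strict `>` comparison, so
  ties keep the earliest candidate in the deterministic scan order.
- Nearest-rank percentile (no interpolation) for the null score threshold.
- All weights in the global solve are floored at `max(s_thresh, 0.05)` so
  the LP never sees a nonpositive weight, even if a degenerate null sample
  drives `s_thresh` below zero.
- Population (÷N) convention for the temporal standard deviation.
- Gaussian filtering of large planes can run in chunks with a halo of
  `4σ + 1` px of real data — the full support of the truncated kernel — so
  chunked and unchunked results agree to machine precision while peak
  memory stays bounded by one padded chunk.
- All randomness (textures, jitter, barcode draws, null-pair sampling,
  RANSAC) flows from explicit seeds; identical configs reproduce
  byte-identical output tables.

## Problem sizes used in the checks

The packaged verification runs use a 4×4 grid of 512² tiles over 3 cycles
(15% overlap, 2 px jitter) for stitching and alignment; 50 random 4–6-node
graphs against exhaustive solver oracles; and 200 cells with 12-cycle
barcodes from a 256-entry library on a 1024² frame for read calling.
These sizes exercise every code path while keeping a full verification run
in the low minutes on one CPU; all of them scale up linearly in pixels and
constraints.

## Known limitations

- Aligning every cycle against every other makes registration cost
  quadratic in cycle count.
- The z-score normalization assumes near-uniform base frequencies per
  cycle; libraries with skewed composition would need frequency-aware
  normalization, which is not implemented.
- No sub-pixel stitching: positions are integerized by design, so up to
  ~0.5 px of true sub-pixel offset is unrecoverable.
- The stage model is translational-linear; rotation between cycles is out
  of scope.
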