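"""Synthetic in situ sequencing data with exact ground truth.

Every downstream stage of the package (registration, global layout,
alignment evaluation, read calling) is testable against the generators in
this module: they emulate the geometry and photometry of a multi-cycle
in situ sequencing experiment while recording the exact truth — true tile
positions, colony coordinates, per-colony barcodes and per-cell barcodes.

Geometry
--------
Tiles are *crops of one latent full-field raster per cycle*, not
independently rendered images.  This guarantees that the overlap regions of
adjacent noiseless tiles are pixel-identical, which is the fixed point that
registration-correctness tests rely on.  A tile's true position is::

    true = nominal grid position + per-tile stage jitter + per-cycle offset

where the nominal grid position is what the "microscope" reports (jitter is
deliberately withheld, as a real stage withholds its own error), the jitter
emulates stage inaccuracy within a cycle and the per-cycle rigid offset
emulates removal and replacement of the well plate between cycles.

Photometry
----------
Amplicon colonies are small Gaussian dots bright in exactly one of the four
sequencing channels per cycle, the channel encoding the base of the colony's
barcode at that cycle.  Colony brightness decays geometrically over cycles,
a uniform background builds up over cycles (by default linearly, in the A
and C channels only, matching the phenomenology of real dye sets), and
additive Gaussian noise is applied last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .tiles import Tile, TileCollection

__all__ = [
    "SyntheticScene",
    "SyntheticGroundTruth",
    "make_barcode_library",
    "smooth_noise_texture",
    "generate_tile_set",
    "generate_cell_mask",
    "generate_sequencing_stack",
    "linear_background_ramp",
    "simulate_experiment",
]

#: Channel order of the four sequencing channels.
CHANNEL_BASES = "GTAC"


@dataclass
class SyntheticScene:
    """Geometry of a synthetic multi-cycle tile acquisition.

    Parameters
    ----------
    grid_shape : (rows, cols)
        Tile grid dimensions.
    tile_size : (w, h)
        Tile size in pixels.
    overlap_fraction : float
        Fraction of each tile shared with its neighbour, in (0, 1).
    n_cycles : int
        Number of imaging cycles.
    jitter_sd : float
        Standard deviation (px) of the per-tile stage-position error.
        Jitter is rounded to integers so that truth lives on the pixel grid.
    cycle_offsets : sequence of (dx, dy) or None
        Rigid offset of each cycle relative to cycle 0.  ``None`` means all
        zeros.
    rng_seed : int
        Seed for every random draw of the scene.
    """

    grid_shape: tuple[int, int]
    tile_size: tuple[int, int] = (512, 512)
    overlap_fraction: float = 0.15
    n_cycles: int = 1
    jitter_sd: float = 0.0
    cycle_offsets: list[tuple[int, int]] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        w, h = self.tile_size
        if rows < 1 or cols < 1 or w < 1 or h < 1:
            raise ValueError("grid and tile dimensions must be positive")
        if not 0 < self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in (0, 1)")
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")
        # True overlaps must survive jitter, otherwise the scene can render
        # tiles that no longer share any pixels with their neighbours.
        if (rows > 1 or cols > 1) and not (
            self.overlap_fraction * min(w, h) > 2 * self.jitter_sd
        ):
            raise ValueError(
                "overlap_fraction * min(tile size) must exceed 2 * jitter_sd"
            )
        if self.cycle_offsets is None:
            self.cycle_offsets = [(0, 0)] * self.n_cycles
        if len(self.cycle_offsets) != self.n_cycles:
            raise ValueError("need one cycle offset per cycle")

    @property
    def stride(self) -> tuple[int, int]:
        """Nominal grid stride ``(sx, sy)`` = floor(size * (1 - overlap))."""
        w, h = self.tile_size
        return int(w * (1 - self.overlap_fraction)), int(h * (1 - self.overlap_fraction))

    @property
    def n_tiles_per_cycle(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]


@dataclass
class SyntheticGroundTruth:
    """Exact truth recorded by the generators.

    ``true_positions`` maps tile id to the true ``(x, y)`` position in the
    world frame whose origin is the nominal position of tile (0, 0).
    ``colonies`` is a table with columns ``x, y, barcode_index, cell``
    (``cell`` 0 flags a background colony).  ``cell_barcodes`` maps cell
    label to the barcode string carried by that cell's colonies.
    """

    true_positions: dict[int, np.ndarray] = field(default_factory=dict)
    colonies: pd.DataFrame | None = None
    cell_labels: np.ndarray | None = None
    cell_barcodes: dict[int, str] = field(default_factory=dict)
    library: list[str] = field(default_factory=list)
    margin: int = 0


def make_barcode_library(n: int, length: int, rng_seed: int = 0) -> list[str]:
    """Draw ``n`` unique random barcodes of the given length over {G,T,A,C}."""
    if n > 4**length:
        raise ValueError("library larger than the barcode space")
    rng = np.random.default_rng(rng_seed)
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(CHANNEL_BASES[i] for i in rng.integers(0, 4, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def smooth_noise_texture(
    shape: tuple[int, int], rng: np.random.Generator, sigma: float = 1.0,
    mean: float = 100.0, sd: float = 30.0,
) -> np.ndarray:
    """Spatially varying speckle texture (smoothed white noise).

    Provides dense fine-grained features everywhere so that registration of
    any two overlapping crops is well posed; the mild blur (sigma 1) keeps
    per-pixel noise from dominating while preserving high-frequency
    content, which correlation peak localisation depends on.
    """
    field_ = gaussian_filter(rng.standard_normal(shape), sigma)
    field_ = (field_ - field_.mean()) / field_.std()
    return mean + sd * field_


def generate_tile_set(
    scene: SyntheticScene,
    texture=smooth_noise_texture,
    noise_sd: float = 0.0,
) -> tuple[TileCollection, SyntheticGroundTruth]:
    """Render a multi-cycle tile set as crops of a latent fiducial field.

    Parameters
    ----------
    scene : SyntheticScene
    texture : callable ``(shape, rng) -> 2-D array``
        Generator of the latent fiducial content.  Must produce a
        non-constant image; registration of constant images is
        underdetermined and is refused.
    noise_sd : float
        Per-tile additive Gaussian readout noise, applied after cropping so
        that the noise realisations of overlapping tiles differ.

    Returns
    -------
    (TileCollection, SyntheticGroundTruth)
        Tiles carry *nominal* positions (jitter withheld); ground truth
        records the true integer positions.
    """
    rng = np.random.default_rng(scene.rng_seed)
    rows, cols = scene.grid_shape
    w, h = scene.tile_size
    sx, sy = scene.stride

    max_off = max(
        (abs(dx) + abs(dy) for dx, dy in scene.cycle_offsets), default=0
    )
    margin = int(np.ceil(4 * scene.jitter_sd + max_off)) + 8
    field_shape = (
        (rows - 1) * sy + h + 2 * margin,
        (cols - 1) * sx + w + 2 * margin,
    )
    latent = np.asarray(texture(field_shape, rng), dtype=float)
    if latent.shape != field_shape:
        raise ValueError("texture returned the wrong shape")
    if latent.std() == 0:
        raise ValueError("texture is constant; registration would be underdetermined")

    tiles: list[Tile] = []
    truth = SyntheticGroundTruth(margin=margin)
    n_per_cycle = scene.n_tiles_per_cycle
    for t in range(scene.n_cycles):
        cdx, cdy = scene.cycle_offsets[t]
        for r in range(rows):
            for c in range(cols):
                tile_id = t * n_per_cycle + r * cols + c
                nominal = np.array([c * sx, r * sy], dtype=float)
                if scene.jitter_sd > 0:
                    jitter = np.round(rng.normal(0, scene.jitter_sd, size=2))
                else:
                    jitter = np.zeros(2)
                true = nominal + jitter + np.array([cdx, cdy], dtype=float)
                tx, ty = int(true[0]) + margin, int(true[1]) + margin
                raster = latent[ty : ty + h, tx : tx + w].copy()
                if noise_sd > 0:
                    raster = raster + rng.normal(0, noise_sd, raster.shape)
                tiles.append(Tile(tile_id, t, raster, nominal))
                truth.true_positions[tile_id] = true
    return TileCollection(tiles), truth


def generate_cell_mask(
    n_cells: int,
    shape: tuple[int, int],
    rng_seed: int = 0,
    radius_range: tuple[float, float] = (10.0, 16.0),
    max_tries: int = 20000,
) -> np.ndarray:
    """Place ``n_cells`` non-overlapping disk-shaped cells in an H x W frame.

    Returns an integer label mask: 0 is background, labels 1..n_cells are
    cells.  Raises if the cells cannot be placed without overlap after a
    bounded number of rejection-sampling retries.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    mask = np.zeros(shape, dtype=np.int32)
    if n_cells == 0:
        return mask
    rng = np.random.default_rng(rng_seed)
    H, W = shape
    centers: list[tuple[float, float, float]] = []  # (y, x, r)
    tries = 0
    while len(centers) < n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping cells in {shape}"
            )
        r = rng.uniform(*radius_range)
        y = rng.uniform(r + 1, H - r - 1)
        x = rng.uniform(r + 1, W - r - 1)
        if all((y - yy) ** 2 + (x - xx) ** 2 > (r + rr + 2) ** 2 for yy, xx, rr in centers):
            centers.append((y, x, r))
    for label, (y, x, r) in enumerate(centers, start=1):
        y0, y1 = int(y - r) - 1, int(y + r) + 2
        x0, x1 = int(x - r) - 1, int(x + r) + 2
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disk = (yy - y) ** 2 + (xx - x) ** 2 <= r**2
        mask[y0:y1, x0:x1][disk] = label
    return mask


def linear_background_ramp(
    n_cycles: int,
    peak: float,
    channels: tuple[int, ...] = (CHANNEL_BASES.index("A"), CHANNEL_BASES.index("C")),
) -> np.ndarray:
    """Per-(cycle, channel) additive background rising linearly to ``peak``.

    By default only the A and C channels ramp, emulating dye sets whose
    background builds up primarily in those two channels.
    """
    ramp = np.zeros((n_cycles, 4))
    t = np.arange(n_cycles) / max(n_cycles - 1, 1)
    for c in channels:
        ramp[:, c] = peak * t
    return ramp


def _render_colony(plane: np.ndarray, x: float, y: float, amp: float, sigma: float) -> None:
    """Add a Gaussian dot of peak ``amp`` at (x, y) to a 2-D plane, in place."""
    H, W = plane.shape
    r = int(np.ceil(4 * sigma))
    y0, y1 = max(0, int(round(y)) - r), min(H, int(round(y)) + r + 1)
    x0, x1 = max(0, int(round(x)) - r), min(W, int(round(x)) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    plane[y0:y1, x0:x1] += amp * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2)
    )


def generate_sequencing_stack(
    n_cells: int,
    library: list[str],
    n_cycles: int,
    *,
    shape: tuple[int, int] = (512, 512),
    colony_sigma: float = 1.5,
    colonies_per_cell: int = 4,
    n_background_colonies: int = 0,
    amplitude: float = 100.0,
    decay: float = 1.0,
    background_buildup: np.ndarray | None = None,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    mask: np.ndarray | None = None,
):
    """Render a 4-D sequencing stack ``f(t, c, y, x)`` with known truth.

    Each cell receives one barcode drawn from ``library`` and
    ``colonies_per_cell`` amplicon colonies placed inside it.  At cycle
    ``t`` a colony adds a Gaussian dot of peak ``amplitude * decay**t`` to
    the channel encoding base ``t`` of its barcode.  ``background_buildup``
    (shape ``(n_cycles, 4)``) is added uniformly per plane, then Gaussian
    noise of ``noise_sd``.

    Returns ``(SequencingStack, SyntheticGroundTruth)``; the ground truth
    carries the label mask, colony table and per-cell barcodes.
    """
    from .readcall import SequencingStack

    if any(len(b) != n_cycles for b in library):
        raise ValueError("barcode length must equal n_cycles")
    if not library:
        raise ValueError("library is empty")
    rng = np.random.default_rng(rng_seed)
    if mask is None:
        mask = generate_cell_mask(n_cells, shape, rng_seed=rng_seed + 1)
    H, W = mask.shape

    data = np.zeros((n_cycles, 4, H, W))
    if background_buildup is not None:
        bg = np.asarray(background_buildup, dtype=float)
        if bg.shape != (n_cycles, 4):
            raise ValueError("background_buildup must have shape (n_cycles, 4)")
        data += bg[:, :, None, None]

    cell_barcodes: dict[int, str] = {}
    records: list[dict] = []
    labels = [int(v) for v in np.unique(mask) if v != 0]
    for label in labels:
        bc_idx = int(rng.integers(0, len(library)))
        cell_barcodes[label] = library[bc_idx]
        ys, xs = np.nonzero(mask == label)
        picks = rng.integers(0, len(ys), size=colonies_per_cell)
        for p in picks:
            records.append(
                {"x": float(xs[p]), "y": float(ys[p]), "barcode_index": bc_idx,
                 "cell": label}
            )
    for _ in range(n_background_colonies):
        bc_idx = int(rng.integers(0, len(library)))
        ys, xs = np.nonzero(mask == 0)
        p = int(rng.integers(0, len(ys)))
        records.append(
            {"x": float(xs[p]), "y": float(ys[p]), "barcode_index": bc_idx, "cell": 0}
        )

    for rec in records:
        barcode = library[rec["barcode_index"]]
        for t, base in enumerate(barcode):
            c = CHANNEL_BASES.index(base)
            _render_colony(data[t, c], rec["x"], rec["y"], amplitude * decay**t, colony_sigma)

    if noise_sd > 0:
        data = data + rng.normal(0, noise_sd, data.shape)

    colonies = pd.DataFrame(records, columns=["x", "y", "barcode_index", "cell"])
    truth = SyntheticGroundTruth(
        colonies=colonies, cell_labels=mask, cell_barcodes=cell_barcodes,
        library=list(library),
    )
    return SequencingStack(data, channel_bases=CHANNEL_BASES), truth


def simulate_experiment(
    scene: SyntheticScene,
    library: list[str],
    *,
    n_cells_per_kpx2: float = 40.0,
    amplitude: float = 100.0,
    decay: float = 0.95,
    background_peak: float = 0.0,
    noise_sd: float = 0.0,
    colony_sigma: float = 1.5,
    colonies_per_cell: int = 4,
):
    """Full synthetic experiment: multi-channel tiles over a sequencing field.

    Builds one latent 5-channel field per cycle — channel 0 a constant
    fiducial texture, channels 1..4 the G/T/A/C sequencing channels rendered
    from cells and colonies — and crops tiles from it exactly as
    :func:`generate_tile_set` does.  Used by the end-to-end pipeline:
    stitch on the fiducial, then call reads from the stitched sequencing
    channels.

    Returns ``(TileCollection, SyntheticGroundTruth)``; the ground-truth
    label mask lives in the latent frame, whose origin relative to the
    nominal grid origin is ``-margin`` (recorded in ``truth.margin``).
    """
    n_cycles = scene.n_cycles
    if any(len(b) != n_cycles for b in library):
        raise ValueError("barcode length must equal the number of cycles")
    rng = np.random.default_rng(scene.rng_seed)
    rows, cols = scene.grid_shape
    w, h = scene.tile_size
    sx, sy = scene.stride
    max_off = max((abs(dx) + abs(dy) for dx, dy in scene.cycle_offsets), default=0)
    margin = int(np.ceil(4 * scene.jitter_sd + max_off)) + 8
    field_shape = ((rows - 1) * sy + h + 2 * margin, (cols - 1) * sx + w + 2 * margin)

    fiducial = smooth_noise_texture(field_shape, rng)
    n_cells = max(1, int(n_cells_per_kpx2 * field_shape[0] * field_shape[1] / 1e6))
    mask = generate_cell_mask(n_cells, field_shape, rng_seed=scene.rng_seed + 1)
    bg = (
        linear_background_ramp(n_cycles, background_peak)
        if background_peak > 0
        else None
    )
    stack, truth = generate_sequencing_stack(
        n_cells, library, n_cycles, mask=mask, colony_sigma=colony_sigma,
        colonies_per_cell=colonies_per_cell, amplitude=amplitude, decay=decay,
        background_buildup=bg, noise_sd=0.0, rng_seed=scene.rng_seed + 2,
    )

    tiles: list[Tile] = []
    truth.margin = margin
    n_per_cycle = scene.n_tiles_per_cycle
    for t in range(n_cycles):
        cdx, cdy = scene.cycle_offsets[t]
        latent = np.concatenate([fiducial[None], stack.data[t]], axis=0)
        for r in range(rows):
            for c in range(cols):
                tile_id = t * n_per_cycle + r * cols + c
                nominal = np.array([c * sx, r * sy], dtype=float)
                if scene.jitter_sd > 0:
                    jitter = np.round(rng.normal(0, scene.jitter_sd, size=2))
                else:
                    jitter = np.zeros(2)
                true = nominal + jitter + np.array([cdx, cdy], dtype=float)
                tx, ty = int(true[0]) + margin, int(true[1]) + margin
                data = latent[:, ty : ty + h, tx : tx + w].copy()
                if noise_sd > 0:
                    data = data + rng.normal(0, noise_sd, data.shape)
                tiles.append(Tile(tile_id, t, data, nominal))
                truth.true_positions[tile_id] = true
    return TileCollection(tiles, fiducial_channel=0), truth
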