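"""End-to-end orchestration: simulate → stitch → evaluate → call-reads.

Each stage reads and writes the on-disk formats in :mod:`issq.io`, logs its
parameters into the artifact headers/manifests, and is runnable on its own
(the CLI exposes one subcommand per stage plus ``run`` for the whole
chain).  All randomness flows from the seeds in :class:`RunConfig`, so two
runs with an identical config produce byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as iio
from .evaluation import evaluate_alignment
from .layout import integerize_positions, merge_tiles, solve_positions
from .readcall import DEFAULT_LOG_THRESHOLD, SequencingStack, call_reads
from .registration import register_tiles
from .simulate import SyntheticScene, make_barcode_library, simulate_experiment
from .tiles import TileCollection

__all__ = ["RunConfig", "simulate_stage", "stitch_stage", "evaluate_stage",
           "call_reads_stage", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Defaults follow the method's stated operating points: background blur
    sigma 3, post-suppression blur sigma 1, LoG scales 1–3 over 7 steps,
    200 px evaluation blocks, 100 null pairs at the 95th percentile, top-2
    consensus reads per cell.
    """

    out_dir: str = "issq_out"
    seed: int = 0
    # synthetic scene
    grid: tuple[int, int] = (3, 3)
    tile_size: tuple[int, int] = (256, 256)
    overlap: float = 0.15
    cycles: int = 4
    jitter_sd: float = 2.0
    library_size: int = 64
    noise_sd: float = 0.0
    # stitching
    solver: str = "mae"
    int_method: str = "round"
    merge_mode: str = "mean"
    n_null_pairs: int = 100
    percentile: float = 95.0
    # evaluation
    block: int = 200
    # read calling
    bg_sigma: float = 3.0
    blur_sigma: float = 1.0
    log_threshold: float = DEFAULT_LOG_THRESHOLD
    min_sigma: float = 1.0
    max_sigma: float = 3.0
    num_sigma: int = 7
    k: int = 2
    max_distance: float = float("inf")
    extraction_stage: str = "normalized"
    chunk_size: int = 0  # 0 = no chunking

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.grid = tuple(cfg.grid)
        cfg.tile_size = tuple(cfg.tile_size)
        return cfg


def _cycle_offsets(n_cycles: int, seed: int) -> list[tuple[int, int]]:
    """Rigid per-cycle offsets emulating plate removal/replacement."""
    rng = np.random.default_rng(seed)
    offsets = [(0, 0)]
    for _ in range(n_cycles - 1):
        offsets.append(tuple(int(v) for v in rng.integers(-4, 5, size=2)))
    return offsets


def simulate_stage(config: RunConfig) -> Path:
    """Generate a multi-channel synthetic scene and write all inputs.

    Writes the tile directory (fiducial + 4 sequencing channels per tile),
    the cell label mask, the barcode library and a ground-truth sidecar
    (``truth.json`` + ``truth_colonies.tsv``) used for frame mapping and
    for validation."""
    out = Path(config.out_dir)
    scene = SyntheticScene(
        grid_shape=config.grid,
        tile_size=config.tile_size,
        overlap_fraction=config.overlap,
        n_cycles=config.cycles,
        jitter_sd=config.jitter_sd,
        cycle_offsets=_cycle_offsets(config.cycles, config.seed + 10),
        rng_seed=config.seed,
    )
    library = make_barcode_library(config.library_size, config.cycles, rng_seed=config.seed + 20)
    tiles, truth = simulate_experiment(scene, library, noise_sd=config.noise_sd)
    iio.write_tiles(out / "tiles", tiles, params={"seed": config.seed})
    iio.write_mask(out / "mask.tif", truth.cell_labels)
    iio.write_library(out / "library.tsv", library)
    iio.write_tsv(truth.colonies, out / "truth_colonies.tsv", {"frame": "latent"})
    meta = {
        "margin": truth.margin,
        "anchor_true_position": [float(v) for v in truth.true_positions[min(truth.true_positions)]],
        "true_positions": {str(k): [float(x) for x in v] for k, v in truth.true_positions.items()},
        "cell_barcodes": {str(k): v for k, v in truth.cell_barcodes.items()},
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return out


def stitch_stage(config: RunConfig, tiles: TileCollection | None = None) -> Path:
    out = Path(config.out_dir)
    if tiles is None:
        tiles = iio.read_tiles(out / "tiles")
    graph = register_tiles(
        tiles, n_null_pairs=config.n_null_pairs, percentile=config.percentile,
        rng_seed=config.seed,
    )
    layout = solve_positions(graph, method=config.solver)
    layout = integerize_positions(layout, method=config.int_method)
    stitched = merge_tiles(tiles, layout, mode=config.merge_mode)
    iio.write_constraint_table(graph, out / "constraints.tsv", {"seed": config.seed})
    iio.write_stitched(out / "stitched", stitched, layout,
                       params={"solver": config.solver, "int_method": config.int_method,
                               "merge": config.merge_mode})
    return out / "stitched"


def evaluate_stage(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    stitched = iio.read_stitched(out / "stitched")
    report = evaluate_alignment(stitched, block=config.block)
    iio.write_tsv(report.to_dataframe(), out / "alignment_blocks.tsv",
                  {"block": config.block})
    summary = report.summary()
    with open(out / "alignment_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _mask_to_stitched_frame(mask: np.ndarray, offset: tuple[int, int],
                            shape: tuple[int, int]) -> np.ndarray:
    """Resample a label mask into the stitched frame by integer shift.

    ``offset`` is the position of stitched pixel (0, 0) in mask
    coordinates; out-of-mask regions become background (0).
    """
    H, W = shape
    out = np.zeros((H, W), dtype=mask.dtype)
    x0, y0 = offset
    sy0, sy1 = max(0, -y0), min(H, mask.shape[0] - y0)
    sx0, sx1 = max(0, -x0), min(W, mask.shape[1] - x0)
    if sy1 > sy0 and sx1 > sx0:
        out[sy0:sy1, sx0:sx1] = mask[y0 + sy0 : y0 + sy1, x0 + sx0 : x0 + sx1]
    return out


def call_reads_stage(config: RunConfig) -> Path:
    """Call reads from the stitched sequencing channels.

    The stitched frame is anchored at the first tile; the mask produced by
    ``simulate`` lives in the generator's latent frame, whose mapping to
    the stitched frame is recorded in ``truth.json`` (on real data the mask
    is segmented from the stitched image itself, so the frames coincide and
    no mapping is needed)."""
    out = Path(config.out_dir)
    stitched = iio.read_stitched(out / "stitched")
    mask = iio.read_mask(out / "mask.tif")
    library = iio.read_library(out / "library.tsv")

    seq_channels = [c for c in range(stitched.data.shape[1])
                    if c != stitched.fiducial_channel]
    if len(seq_channels) != 4:
        raise ValueError("need exactly 4 sequencing channels besides the fiducial")
    stack = SequencingStack(stitched.data[:, seq_channels])

    truth_path = out / "truth.json"
    if truth_path.exists() and mask.shape != stack.frame_shape:
        with open(truth_path) as fh:
            meta = json.load(fh)
        ax, ay = meta["anchor_true_position"]
        margin = meta["margin"]
        ox, oy = stitched.origin
        offset = (int(round(ox + ax + margin)), int(round(oy + ay + margin)))
        mask = _mask_to_stitched_frame(mask, offset, stack.frame_shape)
    elif mask.shape != stack.frame_shape:
        raise ValueError("label mask frame does not match the stitched frame")

    colonies, cells = call_reads(
        stack, mask, library,
        bg_sigma=config.bg_sigma, blur_sigma=config.blur_sigma,
        log_threshold=config.log_threshold, min_sigma=config.min_sigma,
        max_sigma=config.max_sigma, num_sigma=config.num_sigma,
        k=config.k, max_distance=config.max_distance,
        extraction_stage=config.extraction_stage,
        chunk_size=config.chunk_size or None,
    )
    params = {"k": config.k, "log_threshold": config.log_threshold,
              "extraction_stage": config.extraction_stage}
    iio.write_tsv(colonies.table, out / "colonies.tsv", params)
    cell_df = cells.table.copy()
    if len(cell_df):
        cell_df["reads"] = cell_df["reads"].map(",".join)
        cell_df["counts"] = cell_df["counts"].map(lambda cs: ",".join(map(str, cs)))
        if "match" in cell_df.columns:
            cell_df["match"] = cell_df["match"].map(
                lambda m: "" if m is None else (m if isinstance(m, str) else ",".join(m))
            )
    iio.write_tsv(cell_df, out / "cells.tsv", params)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and return the alignment summary."""
    simulate_stage(config)
    stitch_stage(config)
    summary = evaluate_stage(config)
    call_reads_stage(config)
    return summary
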