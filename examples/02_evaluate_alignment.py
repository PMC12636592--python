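"""Stitch a noisy scene and quantify residual inter-cycle alignment error.

Adds readout noise to the tiles (20% of the texture's standard deviation),
stitches, then measures per-block inter-cycle offsets by phase
cross-correlation: the summary is the median block error and the share of
blocks aligned to better than one pixel.
"""

import warnings

from issq import (
    SyntheticScene,
    evaluate_alignment,
    generate_tile_set,
    integerize_positions,
    merge_tiles,
    register_tiles,
    solve_positions,
)

scene = SyntheticScene(
    grid_shape=(3, 3),
    tile_size=(256, 256),
    overlap_fraction=0.15,
    n_cycles=3,
    jitter_sd=2.0,
    cycle_offsets=[(0, 0), (4, -3), (-2, 5)],
    rng_seed=1,
)
tiles, _ = generate_tile_set(scene, noise_sd=6.0)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    graph = register_tiles(tiles, rng_seed=0)
layout = integerize_positions(solve_positions(graph), "round")
stitched = merge_tiles(tiles, layout, mode="mean")

report = evaluate_alignment(stitched, block=100)
print(f"{report.n_blocks} evaluation blocks "
      f"({report.n_excluded} excluded as featureless/uncovered)")
print(f"median inter-cycle error: {report.median_error:.2f} px")
print(f"alignment percentage (<1 px): {report.alignment_percentage:.1f}%")
# A median of 0 px and ~100% alignment mean the mosaics of all three
# cycles sit on top of each other to sub-pixel accuracy despite the noise.
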