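"""Shared fixtures: small synthetic scenes and toy constraint graphs."""

from __future__ import annotations

import numpy as np
import pytest

from issq import (
    Constraint,
    ConstraintGraph,
    SyntheticScene,
    Tile,
    TileCollection,
    generate_tile_set,
    register_tiles,
)


@pytest.fixture(scope="session")
def small_scene():
    return SyntheticScene(
        grid_shape=(3, 3),
        tile_size=(128, 128),
        overlap_fraction=0.15,
        n_cycles=2,
        jitter_sd=2.0,
        cycle_offsets=[(0, 0), (3, -2)],
        rng_seed=1,
    )


@pytest.fixture(scope="session")
def small_tiles(small_scene):
    """Noiseless 3x3 x 2-cycle tile set with ground truth."""
    return generate_tile_set(small_scene)


@pytest.fixture(scope="session")
def registered_graph(small_tiles):
    """Fully registered constraint graph of the small scene."""
    tiles, _ = small_tiles
    with pytest.warns(UserWarning):  # small scene: relaxed null-pair sampling
        return register_tiles(tiles, rng_seed=0)


def make_toy_graph(n_tiles: int, edges: list[tuple]) -> ConstraintGraph:
    """Constraint graph over dummy 1-px tiles for solver unit tests.

    ``edges`` entries are ``(i, j, dx, dy, weight)``; every constraint is
    marked measured with score = weight.
    """
    tiles = TileCollection(
        [Tile(i, 0, np.zeros((1, 1, 1)), (0.0, 0.0)) for i in range(n_tiles)]
    )
    graph = ConstraintGraph(tiles, s_thresh=0.05)
    for i, j, dx, dy, w in edges:
        graph.constraints.append(
            Constraint(i, j, dx, dy, dx_refined=float(dx), dy_refined=float(dy),
                       score=float(w), status="measured")
        )
    return graph
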