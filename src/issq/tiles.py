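"""Core containers for multi-cycle microscope tile sets.

Coordinate convention used throughout the package: a position is an
``(x, y)`` pair where ``x`` indexes columns and ``y`` indexes rows, both
0-based.  Rasters are numpy arrays indexed ``[row, col]`` (i.e. ``[y, x]``),
and multi-channel tile data is stored channel-first as ``(C, H, W)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Tile", "TileCollection"]


@dataclass
class Tile:
    """One microscope field of view from one imaging cycle.

    Parameters
    ----------
    id : int
        Identifier unique across *all* cycles of the collection.
    cycle : int
        0-based imaging-cycle index.
    data : ndarray, shape (C, H, W)
        All channels of the tile.
    position : ndarray, shape (2,)
        Nominal stage position ``(x, y)`` in pixels.  Nominal positions come
        from the microscope stage (or a scan-pattern description) and are
        only approximate; registration refines them.
    scale : float
        Per-cycle magnification factor relative to the reference cycle.
        Tiles are resampled to the reference scale before correlation.
    """

    id: int
    cycle: int
    data: np.ndarray
    position: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("tile data must be (C, H, W) or (H, W)")
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (2,):
            raise ValueError("position must be an (x, y) pair")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def size(self) -> tuple[int, int]:
        """Tile size ``(w, h)`` in pixels."""
        return self.data.shape[2], self.data.shape[1]

    def channel(self, c: int) -> np.ndarray:
        return self.data[c]


@dataclass
class TileCollection:
    """All tiles of a well across every imaging cycle.

    One channel (``fiducial_channel``) shows structures that are physically
    constant across cycles (e.g. DAPI); only that channel is used for
    registration.
    """

    tiles: list[Tile] = field(default_factory=list)
    fiducial_channel: int = 0

    def __post_init__(self) -> None:
        ids = [t.id for t in self.tiles]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate tile ids")
        for t in self.tiles:
            if self.fiducial_channel >= t.n_channels:
                raise ValueError(
                    f"tile {t.id} lacks fiducial channel {self.fiducial_channel}"
                )

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)

    def __getitem__(self, tile_id: int) -> Tile:
        for t in self.tiles:
            if t.id == tile_id:
                return t
        raise KeyError(tile_id)

    @property
    def n_cycles(self) -> int:
        return len({t.cycle for t in self.tiles})

    @property
    def cycles(self) -> list[int]:
        return sorted({t.cycle for t in self.tiles})

    def by_cycle(self, cycle: int) -> list[Tile]:
        return [t for t in self.tiles if t.cycle == cycle]

    def fiducial(self, tile: Tile | int) -> np.ndarray:
        """Fiducial-channel raster of a tile, resampled to reference scale."""
        if isinstance(tile, int):
            tile = self[tile]
        raster = tile.data[self.fiducial_channel]
        if tile.scale != 1.0:
            from scipy.ndimage import zoom

            raster = zoom(raster, tile.scale, order=1)
        return raster
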