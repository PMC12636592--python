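"""Readers and writers for the on-disk formats every stage touches.

Tiles travel as one TIFF per tile (pages = channels) with a TSV sidecar of
nominal positions; stitched output is one multi-page TIFF per cycle plus a
JSON manifest; tables (constraints, colonies, cells, barcode libraries)
are TSV.  Every table written here carries a ``#`` comment block recording
the package version and the parameters that produced it, so a run can be
audited from its artifacts alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .layout import GlobalLayout, StitchedImage
from .registration import ConstraintGraph
from .tiles import Tile, TileCollection

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_tiles",
    "read_tiles",
    "write_constraint_table",
    "write_stitched",
    "read_stitched",
    "write_mask",
    "read_mask",
    "write_library",
    "read_library",
]


def write_tsv(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a TSV with a ``#`` comment block (version + parameters)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# issq {__version__}\n")
        for key, val in (params or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# tiles


def write_tiles(out_dir, tiles: TileCollection, params: dict | None = None) -> None:
    """Write one TIFF per tile plus the nominal-position sidecar TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in sorted(tiles, key=lambda t: t.id):
        tifffile.imwrite(out_dir / f"tile_{t.id:05d}.tif", t.data.astype(np.float32))
        rows.append({"tile_id": t.id, "cycle": t.cycle, "x": t.position[0], "y": t.position[1]})
    meta = {"fiducial_channel": tiles.fiducial_channel, "units": "px"}
    meta.update(params or {})
    write_tsv(pd.DataFrame(rows), out_dir / "positions.tsv", meta)


def _sidecar_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
    return meta


def read_tiles(
    tile_dir,
    positions: str | Path = "positions.tsv",
    pixel_scale: float | None = None,
    fiducial_channel: int | None = None,
) -> TileCollection:
    """Load a tile directory and its position sidecar.

    Positions are converted to pixels: if the sidecar declares
    ``units: um`` (or ``pixel_scale`` is given), positions are divided by
    the pixel scale in microns per pixel.  Missing tile files, duplicate
    ids, raster/size mismatches and missing cycles raise explicit errors.
    """
    tile_dir = Path(tile_dir)
    sidecar = tile_dir / positions if not Path(positions).is_absolute() else Path(positions)
    meta = _sidecar_meta(sidecar)
    table = read_tsv(sidecar)
    required = {"tile_id", "cycle", "x", "y"}
    if not required <= set(table.columns):
        raise ValueError(f"position sidecar lacks columns {required - set(table.columns)}")
    if table["tile_id"].duplicated().any():
        dupes = table.loc[table["tile_id"].duplicated(), "tile_id"].tolist()
        raise ValueError(f"duplicate tile ids in sidecar: {dupes}")

    units = meta.get("units", "px")
    scale = pixel_scale if pixel_scale is not None else float(meta.get("pixel_scale", 0) or 0)
    if units == "um":
        if not scale:
            raise ValueError("positions in microns but no pixel scale (um/px) given")
        table = table.assign(x=table["x"] / scale, y=table["y"] / scale)

    tiles = []
    for row in table.itertuples(index=False):
        path = tile_dir / f"tile_{int(row.tile_id):05d}.tif"
        if not path.exists():
            raise FileNotFoundError(f"missing tile file {path.name}")
        data = tifffile.imread(path)
        tiles.append(Tile(int(row.tile_id), int(row.cycle), data, (row.x, row.y)))

    cycles = sorted({t.cycle for t in tiles})
    expected = list(range(cycles[-1] + 1)) if cycles else []
    missing = sorted(set(expected) - set(cycles))
    if missing:
        raise ValueError(f"missing cycle(s): {missing}")
    if len({t.n_channels for t in tiles}) > 1:
        raise ValueError("tiles disagree on channel count")
    fc = fiducial_channel if fiducial_channel is not None else int(meta.get("fiducial_channel", 0))
    return TileCollection(tiles, fiducial_channel=fc)


# ---------------------------------------------------------------------------
# constraint graph / layout


def write_constraint_table(graph: ConstraintGraph, path, params: dict | None = None) -> None:
    cycle_of = {t.id: t.cycle for t in graph.tiles}
    rows = [
        {
            "tile_i": c.i,
            "cycle_i": cycle_of[c.i],
            "tile_j": c.j,
            "cycle_j": cycle_of[c.j],
            "dx": c.dx,
            "dy": c.dy,
            "dx_refined": c.dx_refined,
            "dy_refined": c.dy_refined,
            "score": c.score,
            "status": c.status,
        }
        for c in graph.constraints
    ]
    meta = {"s_thresh": graph.s_thresh}
    meta.update(params or {})
    write_tsv(pd.DataFrame(rows), path, meta)


def write_stitched(out_dir, stitched: StitchedImage, layout: GlobalLayout | None = None,
                   params: dict | None = None) -> None:
    """One multi-page TIFF per cycle (pages = channels), coverage masks and
    a JSON manifest (frame origin, per-tile integer positions, solver
    metadata).  Empty pixels are written as zeros; consult the coverage
    TIFFs to distinguish them from true zero intensity."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for t in range(stitched.n_cycles):
        tifffile.imwrite(out_dir / f"cycle_{t:03d}.tif", stitched.data[t].astype(np.float32))
        tifffile.imwrite(out_dir / f"coverage_{t:03d}.tif", stitched.coverage[t].astype(np.uint16))
    manifest = {
        "version": __version__,
        "origin": [int(v) for v in stitched.origin],
        "n_cycles": int(stitched.n_cycles),
        "fiducial_channel": int(stitched.fiducial_channel),
        "params": params or {},
    }
    if layout is not None:
        manifest["solver"] = {
            "method": layout.method,
            "int_method": layout.int_method,
            "anchor": int(layout.anchor),
            "objective": float(layout.objective),
            "objective_int": None if layout.objective_int is None else float(layout.objective_int),
        }
        manifest["positions"] = {
            str(i): [int(p[0]), int(p[1])] for i, p in sorted(layout.positions_int.items())
        }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_stitched(stitch_dir) -> StitchedImage:
    stitch_dir = Path(stitch_dir)
    with open(stitch_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    data, coverage = [], []
    for t in range(manifest["n_cycles"]):
        d = tifffile.imread(stitch_dir / f"cycle_{t:03d}.tif")
        data.append(d[None] if d.ndim == 2 else d)
        coverage.append(tifffile.imread(stitch_dir / f"coverage_{t:03d}.tif"))
    data = np.stack(data)
    return StitchedImage(
        data=data.astype(float),
        origin=tuple(manifest["origin"]),
        coverage=np.stack(coverage).astype(np.int32),
        fiducial_channel=manifest.get("fiducial_channel", 0),
    )


# ---------------------------------------------------------------------------
# masks and libraries


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(mask).astype(np.int32))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_library(path, entries: list, mode: str = "single") -> None:
    """Barcode library as plain TSV: one barcode (or tab-separated pair)
    per line."""
    with open(path, "w") as fh:
        for e in entries:
            fh.write((e if mode == "single" else "\t".join(e)) + "\n")


def read_library(path):
    """Read a barcode library TSV; auto-detects single vs double mode."""
    from .readcall import BarcodeLibrary

    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            entries.append(parts[0] if len(parts) == 1 else (parts[0], parts[1]))
    if not entries:
        raise ValueError("empty barcode library file")
    mode = "double" if isinstance(entries[0], tuple) else "single"
    return BarcodeLibrary(entries, mode=mode)
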