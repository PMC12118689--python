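"""Domain types and container I/O for hyperspectral EDX cubes.

The central object is the :class:`HyperspectralCube`: a ``[row, col, channel]``
array of X-ray counts together with the energy-axis calibration and the
acquisition metadata (pixel size, accumulated frame count, dwell time).
Mosaics of tiles are described by :class:`MosaicLayout`; sparse hand
annotations by :class:`AnnotationSet`; flattened pixel-by-feature matrices by
:class:`FlatPixelTable`.

Conventions: coordinates are 0-based, row-major ``(row, col)``; bounding boxes
are half-open ``[r0, r1) x [c0, c1)``; energy channels are 0-based.  Raw
(pre-denoising) counts are stored as unsigned integers; every derived array is
floating point.

Cubes are stored one per tile in an HDF5 container (``counts`` dataset plus
metadata attributes); mosaic grids are described by a plain-text key-value
manifest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np

__all__ = [
    "EnergyAxis",
    "HyperspectralCube",
    "MosaicLayout",
    "AnnotationSet",
    "AnnotationClass",
    "FlatPixelTable",
    "read_cube",
    "write_cube",
    "read_manifest",
    "write_manifest",
    "flatten",
    "unflatten",
    "tiles_for_extent",
]


# ---------------------------------------------------------------------------
# Energy axis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyAxis:
    """Linear energy calibration of the spectral axis.

    Parameters
    ----------
    offset_ev : float
        Energy of the *center* of channel 0, in eV.
    bin_width_ev : float
        Width of one channel, in eV.  Must be positive.
    n_channels : int
        Number of channels.
    """

    offset_ev: float
    bin_width_ev: float
    n_channels: int

    def __post_init__(self) -> None:
        if self.bin_width_ev <= 0:
            raise ValueError(f"bin_width_ev must be > 0, got {self.bin_width_ev}")
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")

    def centers(self) -> np.ndarray:
        """Channel-center energies in eV (strictly increasing)."""
        return self.offset_ev + self.bin_width_ev * np.arange(self.n_channels)

    def edges(self) -> np.ndarray:
        """Channel-edge energies in eV, length ``n_channels + 1``."""
        return (
            self.offset_ev
            - 0.5 * self.bin_width_ev
            + self.bin_width_ev * np.arange(self.n_channels + 1)
        )


# ---------------------------------------------------------------------------
# Hyperspectral cube
# ---------------------------------------------------------------------------

@dataclass
class HyperspectralCube:
    """A spectrum image: per-pixel X-ray energy histograms plus metadata.

    ``counts`` has shape ``(rows, cols, n_channels)`` and is nonnegative
    everywhere.  Raw counts (before any denoising) are integer-typed; derived
    cubes (binned with a mean reducer, mean-filtered, ...) are float.
    """

    counts: np.ndarray
    energy: EnergyAxis
    pixel_size_nm: float
    n_frames: int = 1
    dwell_us: float | None = None
    tile_id: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    # shape accessors -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape  # type: ignore[return-value]

    @property
    def rows(self) -> int:
        return self.counts.shape[0]

    @property
    def cols(self) -> int:
        return self.counts.shape[1]

    @property
    def n_channels(self) -> int:
        return self.counts.shape[2]

    def validate(self) -> None:
        if self.counts.ndim != 3:
            raise ValueError(
                f"counts must be 3-D [row, col, channel], got ndim={self.counts.ndim}"
            )
        if self.counts.shape[2] != self.energy.n_channels:
            raise ValueError(
                f"channel dimension {self.counts.shape[2]} does not match "
                f"energy axis n_channels={self.energy.n_channels}"
            )
        if self.counts.size and float(self.counts.min()) < 0:
            raise ValueError("counts must be nonnegative everywhere")
        if self.pixel_size_nm <= 0:
            raise ValueError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")

    def total_counts(self) -> float:
        return float(self.counts.sum())

    def with_counts(
        self, counts: np.ndarray, energy: EnergyAxis | None = None
    ) -> "HyperspectralCube":
        """A copy of this cube with new data (metadata carried over)."""
        return HyperspectralCube(
            counts=counts,
            energy=energy if energy is not None else self.energy,
            pixel_size_nm=self.pixel_size_nm,
            n_frames=self.n_frames,
            dwell_us=self.dwell_us,
            tile_id=self.tile_id,
        )


# ---------------------------------------------------------------------------
# Mosaic layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MosaicLayout:
    """Regular tile grid with a fixed per-edge overlap.

    The stitched extent along an axis with ``n`` tiles is
    ``tile_px * n - overlap_px * (n - 1)`` pixels.
    """

    grid_rows: int
    grid_cols: int
    tile_px: int
    overlap_px: int = 0
    pixel_size_nm: float = 1.0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must have at least one tile per axis")
        if not (0 <= self.overlap_px < self.tile_px):
            raise ValueError(
                f"overlap_px must satisfy 0 <= overlap < tile_px, "
                f"got overlap={self.overlap_px}, tile_px={self.tile_px}"
            )

    @property
    def n_tiles(self) -> int:
        return self.grid_rows * self.grid_cols

    def stitched_shape(self) -> tuple[int, int]:
        """(rows, cols) of the stitched mosaic in pixels."""
        step = self.tile_px - self.overlap_px
        return (
            self.tile_px + step * (self.grid_rows - 1),
            self.tile_px + step * (self.grid_cols - 1),
        )

    def extent_nm(self) -> tuple[float, float]:
        r, c = self.stitched_shape()
        return (r * self.pixel_size_nm, c * self.pixel_size_nm)

    def tile_origin(self, grid_r: int, grid_c: int) -> tuple[int, int]:
        """Top-left stitched-pixel coordinate of tile (grid_r, grid_c)."""
        step = self.tile_px - self.overlap_px
        return (grid_r * step, grid_c * step)


def tiles_for_extent(
    extent_um: tuple[float, float], tile_px: int, pixel_size_nm: float
) -> tuple[int, int]:
    """Minimum non-overlapping tile grid covering a physical extent.

    Parameters
    ----------
    extent_um : (height_um, width_um)
        Physical field of view in micrometers.
    tile_px : int
        Tile side length in pixels.
    pixel_size_nm : float
        Spatial sampling in nm per pixel.

    Returns
    -------
    (n_rows, n_cols) tile counts, each ``ceil(extent / tile_extent)``.
    """
    tile_um = tile_px * pixel_size_nm / 1000.0
    return (
        math.ceil(extent_um[0] / tile_um),
        math.ceil(extent_um[1] / tile_um),
    )


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationClass:
    label: str
    color: str
    pixels: list[tuple[int, int]]


@dataclass
class AnnotationSet:
    """Sparse hand annotations: named pixel sets, one class per pixel."""

    classes: list[AnnotationClass]

    def validate(self, shape: tuple[int, int]) -> None:
        seen: set[tuple[int, int]] = set()
        for cls in self.classes:
            if not cls.pixels:
                raise ValueError(f"annotation class {cls.label!r} has no pixels")
            for (r, c) in cls.pixels:
                if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                    raise ValueError(
                        f"pixel ({r}, {c}) of class {cls.label!r} outside bounds {shape}"
                    )
                if (r, c) in seen:
                    raise ValueError(
                        f"pixel ({r}, {c}) assigned to more than one class"
                    )
                seen.add((r, c))


# ---------------------------------------------------------------------------
# Flat pixel table
# ---------------------------------------------------------------------------

@dataclass
class FlatPixelTable:
    """Pixel-by-feature matrix with provenance back to cube coordinates.

    ``values`` is ``(n_pixels, n_features)``; ``origin`` is ``(n_pixels, 2)``
    holding ``(row, col)`` per table row, a bijection onto the selected
    pixels.  ``tile_ids`` optionally records the source tile per row.
    """

    values: np.ndarray
    origin: np.ndarray
    tile_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.origin = np.asarray(self.origin)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D [pixel, feature]")
        if self.origin.shape != (self.values.shape[0], 2):
            raise ValueError(
                f"origin shape {self.origin.shape} does not match "
                f"{self.values.shape[0]} rows"
            )
        uniq = {tuple(rc) for rc in self.origin}
        if len(uniq) != self.origin.shape[0]:
            raise ValueError("origin must be a bijection (duplicate pixels found)")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def take(self, idx: np.ndarray) -> "FlatPixelTable":
        return FlatPixelTable(
            values=self.values[idx],
            origin=self.origin[idx],
            tile_ids=None if self.tile_ids is None else self.tile_ids[idx],
        )


def flatten(
    cube: HyperspectralCube,
    selection: np.ndarray | None = None,
) -> FlatPixelTable:
    """Flatten a cube to a ``(n_pixels, n_channels)`` table.

    ``selection`` is an optional boolean mask over ``(rows, cols)``; pixels
    where it is False are dropped.  Row order is row-major over the selected
    pixels, so flatten/unflatten is a lossless bijection.
    """
    rows, cols, nch = cube.shape
    if selection is None:
        selection = np.ones((rows, cols), dtype=bool)
    selection = np.asarray(selection, dtype=bool)
    if selection.shape != (rows, cols):
        raise ValueError(
            f"selection shape {selection.shape} does not match cube {(rows, cols)}"
        )
    rr, cc = np.nonzero(selection)
    if rr.size == 0:
        raise ValueError("empty selection: no pixels to flatten")
    values = cube.counts[rr, cc, :].astype(np.float64, copy=True)
    origin = np.stack([rr, cc], axis=1)
    tid = None
    if cube.tile_id is not None:
        tid = np.full(rr.size, cube.tile_id, dtype=object)
    return FlatPixelTable(values=values, origin=origin, tile_ids=tid)


def unflatten(
    table: FlatPixelTable, shape: tuple[int, int], fill: float = 0.0
) -> np.ndarray:
    """Scatter a table back onto a ``(rows, cols, n_features)`` array."""
    out = np.full(shape + (table.n_features,), fill, dtype=np.float64)
    out[table.origin[:, 0], table.origin[:, 1], :] = table.values
    return out


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------

_REQUIRED_ATTRS = ("offset_ev", "bin_width_ev", "pixel_size_nm", "n_frames")


def write_cube(cube: HyperspectralCube, path: str | Path) -> None:
    """Write a cube to the HDF5 container layout.

    Layout: a chunked ``counts`` dataset plus root attributes ``offset_ev``,
    ``bin_width_ev``, ``pixel_size_nm``, ``n_frames``, and optional
    ``dwell_us`` / ``tile_id``.
    """
    cube.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        chunk = (
            min(256, cube.rows),
            min(256, cube.cols),
            min(64, cube.n_channels),
        )
        f.create_dataset("counts", data=cube.counts, chunks=chunk, compression="gzip")
        f.attrs["offset_ev"] = float(cube.energy.offset_ev)
        f.attrs["bin_width_ev"] = float(cube.energy.bin_width_ev)
        f.attrs["pixel_size_nm"] = float(cube.pixel_size_nm)
        f.attrs["n_frames"] = int(cube.n_frames)
        if cube.dwell_us is not None:
            f.attrs["dwell_us"] = float(cube.dwell_us)
        if cube.tile_id is not None:
            f.attrs["tile_id"] = str(cube.tile_id)


def read_cube(path: str | Path) -> HyperspectralCube:
    """Read a cube written by :func:`write_cube`; validates all invariants."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "counts" not in f:
            raise ValueError(f"{path}: container lacks the 'counts' dataset")
        for name in _REQUIRED_ATTRS:
            if name not in f.attrs:
                raise ValueError(f"{path}: missing required metadata field {name!r}")
        counts = f["counts"][...]
        energy = EnergyAxis(
            offset_ev=float(f.attrs["offset_ev"]),
            bin_width_ev=float(f.attrs["bin_width_ev"]),
            n_channels=counts.shape[2],
        )
        return HyperspectralCube(
            counts=counts,
            energy=energy,
            pixel_size_nm=float(f.attrs["pixel_size_nm"]),
            n_frames=int(f.attrs["n_frames"]),
            dwell_us=float(f.attrs["dwell_us"]) if "dwell_us" in f.attrs else None,
            tile_id=str(f.attrs["tile_id"]) if "tile_id" in f.attrs else None,
        )


def write_manifest(layout: MosaicLayout, tile_paths: Sequence[str], path: str | Path) -> None:
    """Write a plain-text key-value mosaic manifest (row-major tile order)."""
    if len(tile_paths) != layout.n_tiles:
        raise ValueError(
            f"manifest needs {layout.n_tiles} tile paths, got {len(tile_paths)}"
        )
    lines = [
        f"grid_rows = {layout.grid_rows}",
        f"grid_cols = {layout.grid_cols}",
        f"tile_px = {layout.tile_px}",
        f"overlap_px = {layout.overlap_px}",
        f"pixel_size_nm = {layout.pixel_size_nm}",
    ]
    lines += [f"tile = {p}" for p in tile_paths]
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> tuple[MosaicLayout, list[str]]:
    """Read a mosaic manifest written by :func:`write_manifest`."""
    kv: dict[str, str] = {}
    tiles: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key == "tile":
            tiles.append(val)
        else:
            kv[key] = val
    for name in ("grid_rows", "grid_cols", "tile_px", "overlap_px", "pixel_size_nm"):
        if name not in kv:
            raise ValueError(f"{path}: missing required manifest field {name!r}")
    layout = MosaicLayout(
        grid_rows=int(kv["grid_rows"]),
        grid_cols=int(kv["grid_cols"]),
        tile_px=int(kv["tile_px"]),
        overlap_px=int(kv["overlap_px"]),
        pixel_size_nm=float(kv["pixel_size_nm"]),
    )
    return layout, tiles
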