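"""Chunked on-disk video stores and raw-file ingest.

A recording is a 3D stack ordered (T frames, H pixels, W pixels); all
coordinates are 0-based and all ranges half-open.  :func:`convert_input`
turns a raw TIFF / AVI / HDF5 file into one HDF5 dataset per channel
(de-interleaving alternating frames), optionally subtracting a static
background at ingest.  :class:`VideoStore` provides lazy window reads so that
detection never needs the full video in memory.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import tifffile

from . import _avi
from .errors import BoundsError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: cap for automatically chosen chunk sizes
_AUTO_CHUNK_BYTES = 8 * 2**20


@dataclass
class VideoStore:
    """Handle to one chunked 3D dataset inside an HDF5 file.

    When ``lazy`` is true (default) every read opens the file, slices the
    requested window and closes it again; eager mode keeps a cached full copy.
    Both modes are value-identical by contract (property-tested).
    """

    path: Union[str, Path]
    loc: str = "data/ch0"
    lazy: bool = True
    _cache: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        with h5py.File(self.path, "r") as fh:
            return tuple(fh[self.loc].shape)

    @property
    def dtype(self) -> np.dtype:
        with h5py.File(self.path, "r") as fh:
            return fh[self.loc].dtype

    @property
    def chunks(self) -> Optional[tuple[int, int, int]]:
        with h5py.File(self.path, "r") as fh:
            return fh[self.loc].chunks

    def read_full(self) -> np.ndarray:
        if not self.lazy:
            if self._cache is None:
                with h5py.File(self.path, "r") as fh:
                    self._cache = fh[self.loc][()]
            return self._cache
        with h5py.File(self.path, "r") as fh:
            return fh[self.loc][()]

    def read_window(
        self,
        t_range: tuple[int, int],
        y_range: Optional[tuple[int, int]] = None,
        x_range: Optional[tuple[int, int]] = None,
    ) -> np.ndarray:
        """Read the half-open window ``[t0,t1) x [y0,y1) x [x0,x1)``."""
        T, H, W = self.shape
        y_range = (0, H) if y_range is None else y_range
        x_range = (0, W) if x_range is None else x_range
        for (lo, hi), n, name in (
            (t_range, T, "t"),
            (y_range, H, "y"),
            (x_range, W, "x"),
        ):
            if not (0 <= lo < hi <= n):
                raise BoundsError(
                    f"{name}_range [{lo}, {hi}) outside [0, {n}) or empty"
                )
        if not self.lazy:
            full = self.read_full()
            return full[slice(*t_range), slice(*y_range), slice(*x_range)].copy()
        with h5py.File(self.path, "r") as fh:
            return fh[self.loc][
                slice(*t_range), slice(*y_range), slice(*x_range)
            ]


@dataclass
class ConversionConfig:
    channels: int = 1
    subtract_background: Union[None, float, np.ndarray] = None
    output_path: Union[str, Path] = "converted.h5"
    loc: str = "data"
    compression: Optional[str] = None
    dtype: Union[str, np.dtype] = "infer"
    chunks: Union[str, tuple[int, int, int]] = "auto"
    input_loc: Optional[str] = None  # dataset path for HDF5 sources

    def __post_init__(self) -> None:
        if self.channels < 1:
            raise ValidationError("channels must be >= 1")
        if self.compression not in (None, "none", "gzip", "lzf"):
            raise ValidationError(f"unsupported compression {self.compression!r}")


def auto_chunks(shape: tuple[int, int, int], itemsize: int) -> tuple[int, int, int]:
    """Time-chunked whole frames: (min(64, T), H, W), capped at ~8 MiB."""
    T, H, W = shape
    t = min(64, T)
    while t > 1 and t * H * W * itemsize > _AUTO_CHUNK_BYTES:
        t = math.ceil(t / 2)
    return (t, H, W)


def write_store(
    data: np.ndarray,
    path: Union[str, Path],
    loc: str = "data/ch0",
    chunks: Union[str, tuple[int, int, int]] = "auto",
    compression: Optional[str] = None,
    dtype: Union[None, str, np.dtype] = None,
) -> VideoStore:
    """Write a 3D block to an HDF5 dataset and return its store handle."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValidationError(f"expected a 3D stack, got shape {data.shape}")
    if dtype is not None and dtype != "infer":
        data = data.astype(dtype)
    if chunks == "auto" or chunks is None:
        chunk_shape = auto_chunks(data.shape, data.dtype.itemsize)
    else:
        chunk_shape = tuple(int(c) for c in chunks)
        if len(chunk_shape) != 3 or any(
            c < 1 or c > s for c, s in zip(chunk_shape, data.shape)
        ):
            raise ValidationError(
                f"chunk shape {chunk_shape} invalid for data shape {data.shape}"
            )
    if compression == "none":
        compression = None
    with h5py.File(path, "a") as fh:
        if loc in fh:
            del fh[loc]
        fh.create_dataset(
            loc, data=data, chunks=chunk_shape, compression=compression
        )
    return VideoStore(path=path, loc=loc)


def read_source(source: Union[str, Path], input_loc: Optional[str] = None) -> np.ndarray:
    """Decode a TIFF / AVI / HDF5 file into a (T, H, W) array."""
    source = Path(source)
    if not source.exists():
        raise FormatError(f"{source}: no such file")
    suffix = source.suffix.lower()
    if suffix in (".tif", ".tiff"):
        data = tifffile.imread(source)
    elif suffix == ".avi":
        data = _avi.read_avi(source)
    elif suffix in (".h5", ".hdf5"):
        if input_loc is None:
            raise ValidationError("HDF5 input requires an input dataset location")
        with h5py.File(source, "r") as fh:
            if input_loc not in fh:
                raise FormatError(f"{source}: no dataset at {input_loc!r}")
            data = fh[input_loc][()]
    else:
        raise FormatError(f"{source}: unsupported format {suffix!r}")
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 4 and data.shape[-1] in (3, 4):
        # colour frames: convert to luminance
        data = (
            0.299 * data[..., 0] + 0.587 * data[..., 1] + 0.114 * data[..., 2]
        ).astype(data.dtype)
    if data.ndim != 3:
        raise FormatError(f"{source}: expected a 3D stack, got shape {data.shape}")
    return data


def deinterleave(data: np.ndarray, channels: int) -> list[np.ndarray]:
    """Split alternating frames into per-channel stacks; remainder dropped."""
    T = data.shape[0]
    remainder = T % channels
    if remainder:
        logger.warning(
            "dropping %d trailing frame(s): %d frames not divisible by %d channels",
            remainder, T, channels,
        )
        data = data[: T - remainder]
    return [data[c::channels] for c in range(channels)]


def _subtract_static(data: np.ndarray, background) -> np.ndarray:
    bg = np.asarray(background)
    if bg.ndim == 2 and bg.shape != data.shape[1:]:
        raise ValidationError(
            f"background shape {bg.shape} does not match frame shape {data.shape[1:]}"
        )
    if np.issubdtype(data.dtype, np.unsignedinteger):
        # clamp at the dtype floor instead of wrapping around
        wide = data.astype(np.int64) - bg.astype(np.int64)
        return np.clip(wide, 0, np.iinfo(data.dtype).max).astype(data.dtype)
    return data - bg.astype(data.dtype, copy=False)


def convert_input(
    source: Union[str, Path], cfg: ConversionConfig
) -> list[VideoStore]:
    """Ingest a raw video file into one chunked HDF5 dataset per channel."""
    data = read_source(source, cfg.input_loc)
    stores = []
    for c, channel in enumerate(deinterleave(data, cfg.channels)):
        if cfg.subtract_background is not None:
            channel = _subtract_static(channel, cfg.subtract_background)
        stores.append(
            write_store(
                channel,
                cfg.output_path,
                loc=f"{cfg.loc}/ch{c}",
                chunks=cfg.chunks,
                compression=cfg.compression,
                dtype=None if cfg.dtype == "infer" else cfg.dtype,
            )
        )
    return stores


def export_video(
    store: VideoStore, path: Union[str, Path], fps: int = 25
) -> None:
    """Export a store to TIFF or AVI (AVI is scaled to uint8)."""
    path = Path(path)
    data = store.read_full()
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".avi":
        if data.dtype != np.uint8:
            lo, hi = float(data.min()), float(data.max())
            scale = 255.0 / (hi - lo) if hi > lo else 0.0
            data = ((data - lo) * scale).astype(np.uint8)
        _avi.write_avi(path, data, fps=fps)
    else:
        raise FormatError(f"unsupported export format {path.suffix!r}")
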