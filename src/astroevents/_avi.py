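"""Minimal uncompressed 8-bit grayscale AVI (RIFF) reader/writer.

Covers exactly the subset this package exports: a RIFF/AVI container with a
single video stream of uncompressed 8-bit palettised DIB frames (grayscale
palette, bottom-up rows, rows padded to 4 bytes).  Colour frames written by
other tools are converted to luminance on read when the palette is not gray.
"""

from __future__ import annotations

import struct

import numpy as np

from .errors import FormatError


def write_avi(path, frames: np.ndarray, fps: int = 25) -> None:
    """Write a (T, H, W) uint8 stack as an uncompressed grayscale AVI."""
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise FormatError("AVI writer expects a (T, H, W) stack")
    if frames.dtype != np.uint8:
        raise FormatError("AVI writer expects uint8 data")
    T, H, W = frames.shape
    pad = (-W) % 4
    row_bytes = W + pad
    frame_bytes = row_bytes * H

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        data = payload + (b"\x00" if len(payload) % 2 else b"")
        return fourcc + struct.pack("<I", len(payload)) + data

    def lst(fourcc: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", fourcc + payload)

    avih = struct.pack(
        "<14I",
        1000000 // fps,  # microseconds per frame
        frame_bytes * fps,  # max bytes per second
        0, 0x10,  # padding, flags (AVIF_HASINDEX)
        T, 0, 1, frame_bytes, W, H, 0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sIHHIIIIIIIIhhhh",
        b"vids", b"DIB ", 0, 0, 0, 0, 1, fps, 0, T, frame_bytes, 0xFFFFFFFF, 0,
        0, 0, W, H,
    )
    bmih = struct.pack("<IiiHHIIiiII", 40, W, H, 1, 8, 0, frame_bytes, 0, 0, 256, 256)
    palette = b"".join(struct.pack("<BBBB", i, i, i, 0) for i in range(256))
    strf = bmih + palette
    hdrl = lst(
        b"hdrl",
        chunk(b"avih", avih) + lst(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf)),
    )

    movi_payload = b"movi"
    index_entries = []
    offset = 4  # relative to start of 'movi' fourcc
    for frame in frames:
        rows = frame[::-1]  # bottom-up
        if pad:
            rows = np.pad(rows, ((0, 0), (0, pad)))
        data = rows.tobytes()
        movi_payload += chunk(b"00db", data)
        index_entries.append((offset, len(data)))
        offset += 8 + len(data) + (len(data) % 2)
    movi = chunk(b"LIST", movi_payload)
    idx1 = b"".join(
        b"00db" + struct.pack("<III", 0x10, off, size) for off, size in index_entries
    )
    riff_payload = b"AVI " + hdrl + movi + chunk(b"idx1", idx1)
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos : pos + 4]
        (size,) = struct.unpack("<I", buf[pos + 4 : pos + 8])
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path) -> np.ndarray:
    """Read an uncompressed 8-bit DIB AVI into a (T, H, W) uint8 stack."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise FormatError(f"{path}: not an AVI file")

    width = height = bitcount = None
    palette = None
    frames: list[np.ndarray] = []

    def walk(start: int, end: int) -> None:
        nonlocal width, height, bitcount, palette
        for fourcc, data_pos, size in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(data_pos + 4, data_pos + size)
            elif fourcc == b"strf" and width is None:
                (_, width, height, _, bitcount) = struct.unpack(
                    "<IiiHH", buf[data_pos : data_pos + 16]
                )
                (clr_used,) = struct.unpack("<I", buf[data_pos + 32 : data_pos + 36])
                if bitcount == 8:
                    n = clr_used or 256
                    pal = np.frombuffer(
                        buf[data_pos + 40 : data_pos + 40 + 4 * n], dtype=np.uint8
                    ).reshape(-1, 4)
                    palette = pal
            elif fourcc in (b"00db", b"00dc") and size > 0:
                frames.append(np.frombuffer(buf[data_pos : data_pos + size], np.uint8))

    walk(12, len(buf))
    if width is None or not frames:
        raise FormatError(f"{path}: no decodable video stream found")
    if bitcount != 8:
        raise FormatError(f"{path}: only uncompressed 8-bit AVI is supported")
    H, W = abs(height), width
    row_bytes = W + ((-W) % 4)
    out = np.empty((len(frames), H, W), dtype=np.uint8)
    for i, raw in enumerate(frames):
        rows = raw[: row_bytes * H].reshape(H, row_bytes)[:, :W]
        out[i] = rows[::-1] if height > 0 else rows
    if palette is not None and not np.all(palette[:, 0][:, None] == palette[:, :3]):
        # non-gray palette: convert via luminance of the palette entries
        lum = (
            0.114 * palette[:, 0] + 0.587 * palette[:, 1] + 0.299 * palette[:, 2]
        ).astype(np.uint8)
        out = lum[out]
    return out
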