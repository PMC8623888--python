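"""Reading and writing binary mask stacks and the pipeline's tables.

Mask sequences are stored either as one multi-page TIFF per particle or as a
directory of PNG frames; tables are plain CSV throughout so every
intermediate is inspectable.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from granmorph.errors import MeasurementError

__all__ = ["read_mask_stack", "write_mask_stack"]


def write_mask_stack(path, frames: np.ndarray) -> Path:
    """Write a (n, H, W) boolean stack as multi-page TIFF or a single PNG.

    A ``.png`` path is only valid for single-frame stacks; for multi-frame
    PNG output pass a directory path (frames become ``frame_000.png``...).
    """
    path = Path(path)
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise MeasurementError(f"expected (n, H, W) stack, got shape {frames.shape}")
    data = (frames.astype(np.uint8)) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data, photometric="minisblack")
    elif path.suffix.lower() == ".png":
        if len(data) != 1:
            raise MeasurementError("a .png path can hold only a single frame")
        iio.imwrite(path, data[0])
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(data):
            iio.imwrite(path / f"frame_{i:03d}.png", frame)
    return path


def read_mask_stack(path) -> np.ndarray:
    """Read a mask stack written by :func:`write_mask_stack` back as bool (n, H, W)."""
    path = Path(path)
    if path.is_dir():
        frames = [iio.imread(p) for p in sorted(path.glob("frame_*.png"))]
        if not frames:
            raise MeasurementError(f"no frame_*.png files under {path}")
        data = np.stack(frames)
    elif path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        data = iio.imread(path)
    else:
        raise MeasurementError(f"unsupported mask format: {path}")
    if data.ndim == 2:
        data = data[None, :, :]
    return data > 0
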