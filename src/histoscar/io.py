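"""Raster I/O, ROI cropping, and mask-area measurement.

Images are plain ``numpy`` arrays: RGB images are ``(H, W, 3) uint8`` in sRGB,
binary masks are ``(H, W) bool``.  Coordinates are 0-based and row-major;
ROI boxes are half-open ``[row0, row1) x [col0, col1)``.

PNG and TIFF are the supported formats.  JPEG is rejected by default because
its chroma subsampling and quantization corrupt the stain colors that the
downstream segmentation clusters on; pass ``allow_jpeg=True`` to override.
16-bit inputs are linearly rescaled to 8 bits with the exact full-range
integer mapping ``v8 = v16 * 255 // 65535`` (no gamma change).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile
from PIL import Image, UnidentifiedImageError

from .errors import BoundsError, DimensionError, InputFormatError

__all__ = [
    "RoiBox",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "crop_roi",
    "measure_area",
]

_TIFF_EXT = {".tif", ".tiff"}
_JPEG_EXT = {".jpg", ".jpeg"}


@dataclass(frozen=True)
class RoiBox:
    """Half-open rectangular region ``[row0, row1) x [col0, col1)``, 0-based."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if not (0 <= self.row0 < self.row1 and 0 <= self.col0 < self.col1):
            raise BoundsError(
                f"degenerate box rows [{self.row0},{self.row1}) cols [{self.col0},{self.col1})"
            )

    @property
    def height(self) -> int:
        return self.row1 - self.row0

    @property
    def width(self) -> int:
        return self.col1 - self.col0

    def compose(self, inner: "RoiBox") -> "RoiBox":
        """Box equivalent to cropping ``self`` first, then ``inner`` in the cropped frame."""
        if inner.row1 > self.height or inner.col1 > self.width:
            raise BoundsError(f"inner box {inner} exceeds outer box {self}")
        return RoiBox(
            self.row0 + inner.row0,
            self.col0 + inner.col0,
            self.row0 + inner.row1,
            self.col0 + inner.col1,
        )


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return (arr.astype(np.uint32) * 255 // 65535).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return (arr.astype(np.int64) * 255 // info.max).astype(np.uint8)
    raise InputFormatError(f"unsupported pixel dtype {arr.dtype}")


def _normalize_channels(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:  # grayscale -> replicate
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    elif arr.ndim == 3 and arr.shape[2] == 2:  # gray+alpha
        arr = np.stack([arr[:, :, 0]] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InputFormatError(f"cannot interpret array of shape {arr.shape} as RGB")
    return arr


def read_image(path: str | os.PathLike, allow_jpeg: bool = False) -> np.ndarray:
    """Read a PNG or TIFF as an 8-bit ``(H, W, 3)`` sRGB array.

    Grayscale inputs are replicated across channels; an alpha channel is
    dropped; 16-bit samples are rescaled to 8-bit by integer division of the
    full ranges.  JPEG raises :class:`InputFormatError` unless ``allow_jpeg``.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in _JPEG_EXT and not allow_jpeg:
        raise InputFormatError(
            f"{path}: JPEG is rejected (lossy compression corrupts stain colors); "
            "pass allow_jpeg=True to override"
        )
    try:
        if ext in _TIFF_EXT:
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                if im.format == "JPEG" and not allow_jpeg:
                    raise InputFormatError(f"{path}: JPEG content is rejected by default")
                arr = np.asarray(im)
    except InputFormatError:
        raise
    except (OSError, ValueError, UnidentifiedImageError) as exc:
        raise InputFormatError(f"{path}: cannot read image ({exc})") from exc
    arr = np.atleast_2d(np.asarray(arr))
    return _to_uint8(_normalize_channels(arr))


def write_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write an ``(H, W, 3) uint8`` image as PNG or TIFF, chosen by extension."""
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise InputFormatError(f"expected uint8 image, got {image.dtype}")
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in _TIFF_EXT:
        tifffile.imwrite(path, image)
    else:
        Image.fromarray(image).save(path)


def read_mask(path: str | os.PathLike, frame: tuple[int, int] | None = None) -> np.ndarray:
    """Read a single-channel mask image; nonzero pixels are positive.

    RGB-encoded masks are accepted when all channels agree.  If ``frame`` is
    given, the mask shape must match it.
    """
    path = os.fspath(path)
    try:
        if os.path.splitext(path)[1].lower() in _TIFF_EXT:
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except (OSError, ValueError, UnidentifiedImageError) as exc:
        raise InputFormatError(f"{path}: cannot read mask ({exc})") from exc
    if arr.ndim == 3:
        if not (arr[..., :1] == arr[..., : min(3, arr.shape[2])]).all():
            raise InputFormatError(f"{path}: multi-channel mask with disagreeing channels")
        arr = arr[:, :, 0]
    mask = arr != 0
    if frame is not None and mask.shape != tuple(frame):
        raise DimensionError(f"{path}: mask shape {mask.shape} does not match frame {tuple(frame)}")
    return mask


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a boolean mask as single-channel PNG (0 = background, 255 = positive)."""
    out = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    Image.fromarray(out, mode="L").save(os.fspath(path))


def crop_roi(image: np.ndarray, box: RoiBox) -> np.ndarray:
    """Copy the ROI ``box`` out of ``image`` (2-D mask or 3-D RGB)."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    if box.row1 > h or box.col1 > w:
        raise BoundsError(f"box {box} exceeds image frame {h}x{w}")
    return image[box.row0 : box.row1, box.col0 : box.col1].copy()


def measure_area(mask: np.ndarray) -> int:
    """Number of positive pixels in a binary mask (the scar-area measurement)."""
    return int(np.count_nonzero(np.asarray(mask, dtype=bool)))
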