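"""Image readers/writers for the fusion pipeline.

Accepted formats: PNG, TIFF (via imageio/tifffile) and NIfTI 2-D slices
(via nibabel). Everything is normalized to float [0, 1] on read; color
inputs are collapsed to luminance (ITU-R BT.601) and the conversion logged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

logger = logging.getLogger("cpfuse")

__all__ = ["read_image", "write_image", "ImageIOError"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_RASTER_SUFFIXES = (".png", ".tif", ".tiff")


class ImageIOError(IOError):
    """Unreadable file or unsupported format."""


def _normalize(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    arr = arr.astype(float)
    if not np.all(np.isfinite(arr)):
        raise ImageIOError("image contains non-finite values")
    # float inputs: assume [0,1]; rescale only if clearly out of range
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        lo, hi = arr.min(), arr.max()
        arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
        logger.info("float image rescaled from [%g, %g] to [0, 1]", lo, hi)
    return arr


def _to_gray(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        logger.info("%s: color image converted to luminance (BT.601)", path.name)
        rgb = arr[..., :3]
        return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    raise ImageIOError(f"{path}: expected a 2-D grayscale or RGB image, got shape {arr.shape}")


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image as float [0, 1]. PNG/TIFF/NIfTI (2-D slice)."""
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"{path}: no such file")
    name = path.name.lower()
    try:
        if name.endswith(_NIFTI_SUFFIXES):
            import nibabel as nib

            data = np.asanyarray(nib.load(path).dataobj)
            data = np.squeeze(data)
            if data.ndim != 2:
                raise ImageIOError(
                    f"{path}: expected a 2-D NIfTI slice, got shape {data.shape}"
                )
            return _normalize(np.asarray(data))
        if name.endswith(_RASTER_SUFFIXES):
            import imageio.v3 as iio

            arr = iio.imread(path)
            return _normalize(_to_gray(np.asarray(arr), path))
    except ImageIOError:
        raise
    except Exception as exc:  # unreadable/corrupt file
        raise ImageIOError(f"{path}: failed to read ({exc})") from exc
    raise ImageIOError(
        f"{path}: unsupported format (expected .png, .tif/.tiff, .nii/.nii.gz)"
    )


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float image: PNG as 8-bit, TIFF as 16-bit, NIfTI as
    float32."""
    path = Path(path)
    img = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        import nibabel as nib

        nib.save(nib.Nifti1Image(img.astype(np.float32), affine=np.eye(4)), path)
        return
    import imageio.v3 as iio

    if name.endswith((".tif", ".tiff")):
        iio.imwrite(path, np.round(img * 65535.0).astype(np.uint16))
    elif name.endswith(".png"):
        iio.imwrite(path, np.round(img * 255.0).astype(np.uint8))
    else:
        raise ImageIOError(f"{path}: unsupported output format")
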