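"""Image readers/writers: PNG/TIFF for 2D, NIfTI for 3D volumes.

NIfTI keeps voxel spacing in its header (affine = diag(spacing)); 2D raster
formats default to unit spacing.  Float data round-trips exactly through
float32 NIfTI and integer data through 16-bit PNG/TIFF.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile

from .grid import ImageGrid, as_image

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_RASTER_SUFFIXES = (".png", ".tif", ".tiff")


def _kind(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz") or name.endswith(".nii"):
        return "nifti"
    if name.endswith(".png"):
        return "png"
    if name.endswith(".tif") or name.endswith(".tiff"):
        return "tiff"
    raise ValueError(
        f"unsupported image format for {path}: expected .nii/.nii.gz, .png or .tif(f)"
    )


def read_image(path) -> ImageGrid:
    """Load a 2D raster or 3D NIfTI file into an ImageGrid (float data)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input image not found: {path}")
    kind = _kind(path)
    try:
        if kind == "nifti":
            img = nib.load(str(path))
            data = np.asarray(img.dataobj, dtype=float)
            spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
            return ImageGrid(data, spacing)
        if kind == "png":
            data = iio.imread(path)
        else:
            data = tifffile.imread(str(path))
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise ValueError(f"failed to read image {path}: {exc}") from exc
    if data.ndim == 3 and data.shape[-1] in (3, 4):
        data = data[..., 0]  # grayscale stored as RGB(A)
    return ImageGrid(np.asarray(data, dtype=float))


def write_image(image, path, dtype=None) -> Path:
    """Write an ImageGrid/array; format chosen from the file suffix.

    PNG output requires integer-valued data in [0, 65535] (written as
    uint16), or pass ``dtype=np.uint8`` for {0,1} masks.  NIfTI writes
    float32 by default with the spacing on the affine diagonal.
    """
    img = as_image(image)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    kind = _kind(path)
    if kind == "nifti":
        dt = np.float32 if dtype is None else dtype
        affine = np.diag(list(img.spacing) + [1.0] * (4 - img.ndim))
        nib.save(nib.Nifti1Image(img.data.astype(dt), affine), str(path))
        return path
    if img.ndim != 2:
        raise ValueError(f"{kind} output is 2D only; use NIfTI for volumes")
    if dtype is None:
        dtype = np.uint16
    arr = img.data
    info = np.iinfo(dtype)
    if (arr < info.min).any() or (arr > info.max).any() or not np.allclose(arr, np.rint(arr)):
        raise ValueError(
            f"{kind} stores integers in [{info.min}, {info.max}]; rescale the "
            "image first or write NIfTI"
        )
    arr = arr.astype(dtype)
    if kind == "png":
        iio.imwrite(path, arr)
    else:
        tifffile.imwrite(str(path), arr)
    return path


def read_mask(path) -> np.ndarray:
    """Load a binary mask (any nonzero voxel counts as foreground)."""
    return read_image(path).data > 0.5


def write_mask(mask: np.ndarray, path, spacing=None) -> Path:
    """Write a {0,1} mask as 8-bit raster or uint8 NIfTI."""
    img = ImageGrid(np.asarray(mask).astype(float), spacing)
    return write_image(img, path, dtype=np.uint8)
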