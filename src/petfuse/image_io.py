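"""Reading, writing and gray-level quantization of 2D medical images.

The registration pipeline works on single-slice grayscale rasters: a
floating PET image that is transformed, and a fixed CT reference (or its
edge map).  Intensities are kept in their stored units; mutual information
is computed on quantized gray levels, so no rescaling is ever applied on
input.

Supported formats are NIfTI (via nibabel), 8/16-bit grayscale PNG (via
imageio) and raw float32 with a JSON sidecar declaring the shape.  NIfTI
and raw are lossless for arbitrary float data; PNG is lossless only for
non-negative integer-valued images.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class Modality(enum.Enum):
    """What a raster represents: functional PET, anatomical CT, a binary
    edge map derived from CT, or anything else."""

    PET = "PET"
    CT = "CT"
    EDGE = "EDGE"
    OTHER = "OTHER"


#: Minimum image side length accepted by the registration pipeline.
MIN_REGISTRATION_SIZE = 8


@dataclass(frozen=True)
class Image2D:
    """A 2D grayscale raster with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray
        Finite real intensities, shape (height, width), row-major.
    spacing : tuple of float
        Physical size of a pixel in millimetres, (row, col).
    modality : Modality
        Tag describing the image content; purely informational.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    modality: Modality = Modality.OTHER

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"Image2D requires a 2D array, got ndim={px.ndim}")
        if not np.all(np.isfinite(px)):
            raise ValueError("Image2D intensities must be finite (no NaN/Inf)")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def check_registration_size(self) -> None:
        """Raise if the image is too small to register (side < 8 px)."""
        if min(self.shape) < MIN_REGISTRATION_SIZE:
            raise ValueError(
                f"registration inputs must be at least "
                f"{MIN_REGISTRATION_SIZE}x{MIN_REGISTRATION_SIZE}, got {self.shape}"
            )


@dataclass(frozen=True)
class QuantizedImage:
    """Integer gray-level labels in [0, levels-1] plus the intensity range
    they were binned from."""

    labels: np.ndarray
    levels: int
    source_range: tuple[float, float]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.min(initial=0) < 0 or lab.max(initial=0) > self.levels - 1:
            raise ValueError("labels outside [0, levels-1]")
        object.__setattr__(self, "labels", lab.astype(np.int64))


def quantize(img: Image2D, levels: int, mask: np.ndarray | None = None) -> QuantizedImage:
    """Bin intensities into ``levels`` equal-width gray levels.

    The observed [min, max] range (over ``mask`` if given) is split into
    ``levels`` equal-width bins; the maximum maps to bin ``levels - 1`` and
    a constant image maps wholly to bin 0.  Equal-width binning over the
    observed range makes mutual information invariant to affine intensity
    rescaling of either image.

    Parameters
    ----------
    img : Image2D
    levels : int
        Number of gray levels, >= 2.
    mask : ndarray of bool, optional
        If given, the bin edges are computed from the masked pixels only;
        labels are still produced for every pixel (values outside the
        masked range are clipped into [0, levels-1]).
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    px = img.pixels
    sel = px if mask is None else px[np.asarray(mask, dtype=bool)]
    if sel.size == 0:
        raise ValueError("empty mask: no pixels to quantize")
    lo, hi = float(sel.min()), float(sel.max())
    if hi == lo:
        labels = np.zeros(px.shape, dtype=np.int64)
    else:
        labels = np.floor((px - lo) / (hi - lo) * levels).astype(np.int64)
        np.clip(labels, 0, levels - 1, out=labels)
    return QuantizedImage(labels=labels, levels=levels, source_range=(lo, hi))


# ---------------------------------------------------------------------------
# File I/O


def _read_nifti(path: Path, slice_index: int | None) -> np.ndarray:
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj)
    vol = np.squeeze(vol)
    if vol.ndim == 2:
        return vol
    if vol.ndim == 3:
        if slice_index is None:
            raise ValueError(
                f"{path}: 3D NIfTI volume requires a slice index"
            )
        return vol[:, :, slice_index]
    raise ValueError(f"{path}: unsupported NIfTI dimensionality {vol.ndim}")


def read_image(
    path: str | Path,
    format: str = "nifti",
    modality: Modality = Modality.OTHER,
    slice_index: int | None = None,
    spacing: tuple[float, float] = (1.0, 1.0),
) -> Image2D:
    """Read a 2D grayscale image; intensities are returned as stored.

    ``format`` is one of ``nifti``, ``png``, ``raw``.  Raw files are
    float32 row-major with a ``<path>.json`` sidecar holding the shape.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read image: {path} does not exist")
    if format == "nifti":
        arr = _read_nifti(path, slice_index)
    elif format == "png":
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:  # collapse grayscale stored with channels
            arr = arr[..., 0]
    elif format == "raw":
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise IOError(f"raw image {path} is missing sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        shape = tuple(meta["shape"])
        arr = np.fromfile(path, dtype=np.float32).reshape(shape)
    else:
        raise ValueError(f"unknown image format {format!r}")
    return Image2D(pixels=np.asarray(arr, dtype=np.float64), spacing=spacing, modality=modality)


def write_image(img: Image2D, path: str | Path, format: str = "nifti") -> None:
    """Write an image; NIfTI and raw round-trip arbitrary floats exactly,
    PNG requires non-negative integer intensities (<= 65535) and stores
    them as 16-bit."""
    path = Path(path)
    if format == "nifti":
        import nibabel as nib

        nii = nib.Nifti1Image(img.pixels.astype(np.float64), affine=np.eye(4))
        nii.header.set_zooms((img.spacing[0], img.spacing[1]))
        nib.save(nii, str(path))
    elif format == "png":
        import imageio.v3 as iio

        px = img.pixels
        if np.any(px < 0) or np.any(px > 65535) or not np.allclose(px, np.round(px)):
            raise ValueError(
                "PNG output requires integer intensities in [0, 65535]; "
                "use nifti or raw for float data"
            )
        iio.imwrite(path, px.astype(np.uint16))
    elif format == "raw":
        px = img.pixels.astype(np.float32)
        px.tofile(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"shape": list(px.shape), "dtype": "float32"}))
    else:
        raise ValueError(f"unknown image format {format!r}")
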