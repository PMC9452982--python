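"""Rigid 2D transforms (rotation about the image center + translation)
and backward-warp resampling.

A transform T = (beta, tx, ty) maps a center-relative point p = (r, c) to

    [r']   [cos b  -sin b] [r]   [tx]
    [c'] = [sin b   cos b] [c] + [ty]

with beta in radians and translations in pixels; tx shifts rows, ty shifts
columns.  Rotation is about the image center ((H-1)/2, (W-1)/2), which
keeps the angle and translation identifiable.  Resampling is backward
(pull) warping: the output pixel at q takes the interpolated input value
at T^{-1}(q), so no holes appear.  Pixels whose back-mapped source falls
outside the input raster are filled with a constant and flagged in an
overlap mask; the mutual-information estimator only ever counts pixels
inside that mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .image_io import Image2D


@dataclass(frozen=True)
class RigidTransform:
    """Rotation ``beta`` (radians, about the image center) followed by
    translation (``tx`` rows, ``ty`` columns, pixels)."""

    beta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    @property
    def params(self) -> np.ndarray:
        return np.array([self.beta, self.tx, self.ty])

    @property
    def rotation_matrix(self) -> np.ndarray:
        cb, sb = np.cos(self.beta), np.sin(self.beta)
        return np.array([[cb, -sb], [sb, cb]])


IDENTITY = RigidTransform(0.0, 0.0, 0.0)


def map_point(
    T: RigidTransform,
    p: tuple[float, float] | np.ndarray,
    center: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Apply T to a (row, col) point; rotation is about ``center``."""
    p = np.asarray(p, dtype=np.float64)
    c = np.asarray(center, dtype=np.float64)
    rel = p - c
    out = T.rotation_matrix @ rel + np.array([T.tx, T.ty])
    return out + c


def compose(T1: RigidTransform, T2: RigidTransform) -> RigidTransform:
    """Transform applying T2 first, then T1 (about the same center)."""
    t2 = np.array([T2.tx, T2.ty])
    t = T1.rotation_matrix @ t2 + np.array([T1.tx, T1.ty])
    return RigidTransform(beta=T1.beta + T2.beta, tx=float(t[0]), ty=float(t[1]))


def invert(T: RigidTransform) -> RigidTransform:
    """Inverse transform: map_point(invert(T), map_point(T, p)) == p."""
    Rinv = RigidTransform(beta=-T.beta).rotation_matrix
    t = -Rinv @ np.array([T.tx, T.ty])
    return RigidTransform(beta=-T.beta, tx=float(t[0]), ty=float(t[1]))


_INTERP_ORDER = {"nearest": 0, "bilinear": 1}


def resample(
    img: Image2D,
    T: RigidTransform,
    interpolation: str = "bilinear",
    fill: float = 0.0,
) -> tuple[Image2D, np.ndarray]:
    """Backward-warp ``img`` by T on the same output grid.

    Returns the warped image and the boolean overlap mask marking output
    pixels whose back-mapped source lies inside the input support, taken
    as [-0.5, N-0.5) per axis: a source within half a pixel of the border
    still has a well-defined (border-clamped) value, anything further out
    is extrapolation.  Pixels outside the overlap take ``fill``; they
    must be excluded (via the mask) from any histogram so the fill
    intensity never biases MI.  Without the half-pixel convention, any
    sub-pixel rotation would shave near-constant background corners off
    the mask and spuriously inflate the masked entropies — a known
    overlap artifact of MI registration.
    """
    if interpolation not in _INTERP_ORDER:
        raise ValueError(
            f"unknown interpolation {interpolation!r}; expected one of {sorted(_INTERP_ORDER)}"
        )
    H, W = img.shape
    center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    Tinv = invert(T)

    rows, cols = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    rel = np.stack([rows.ravel() - center[0], cols.ravel() - center[1]])
    src = Tinv.rotation_matrix @ rel
    src[0] += Tinv.tx + center[0]
    src[1] += Tinv.ty + center[1]
    # snap source coordinates that are within one part in 1e9 of a pixel
    # center; rotation by multiples of pi/2 would otherwise land a hair
    # outside the raster and read the fill value
    near = np.abs(src - np.rint(src)) < 1e-9
    src[near] = np.rint(src[near])

    overlap = (
        (src[0] >= -0.5) & (src[0] < H - 0.5) & (src[1] >= -0.5) & (src[1] < W - 0.5)
    ).reshape(H, W)
    src[0] = np.clip(src[0], 0.0, H - 1.0)
    src[1] = np.clip(src[1], 0.0, W - 1.0)
    warped = map_coordinates(
        img.pixels, src, order=_INTERP_ORDER[interpolation], mode="nearest"
    ).reshape(H, W)
    warped[~overlap] = fill
    out = Image2D(pixels=warped, spacing=img.spacing, modality=img.modality)
    return out, overlap


def save_transform(T: RigidTransform, path: str | Path) -> None:
    """Serialize as one plain-text line: ``beta tx ty`` (radians, pixels)."""
    Path(path).write_text(f"{T.beta!r} {T.tx!r} {T.ty!r}\n")


def load_transform(path: str | Path) -> RigidTransform:
    parts = Path(path).read_text().split()
    if len(parts) != 3:
        raise ValueError(f"transform file {path} must hold exactly 'beta tx ty'")
    b, tx, ty = (float(p) for p in parts)
    return RigidTransform(beta=b, tx=tx, ty=ty)
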