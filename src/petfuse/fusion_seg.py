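"""PET/CT fusion overlay, high-uptake segmentation and accuracy scoring.

Fusion renders the CT as a grayscale base and blends the registered PET
on top through a "hot" colormap with opacity alpha, the standard clinical
display for localizing high-metabolism (high FDG uptake) regions against
anatomy.  Segmentation thresholds the registered PET, either at a
fraction of its maximum (the usual relative-SUV-style rule) or at a fixed
intensity.  Accuracy against a ground-truth mask is reported as pixel
accuracy, Dice and Jaccard; Dice is the field's standard overlap score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import Image2D


@dataclass(frozen=True)
class SegmentationResult:
    mask: np.ndarray  # binary, 1 = high uptake
    threshold_used: float
    n_foreground: int


def _normalize01(px: np.ndarray) -> np.ndarray:
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        return np.zeros_like(px)
    return (px - lo) / (hi - lo)


def fuse(pet_reg: Image2D, ct: Image2D, alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend colormapped PET over grayscale CT.

    Returns an (H, W, 3) float array in [0, 1].  alpha = 0 reproduces the
    normalized CT; alpha = 1 shows pure colormapped PET.
    """
    if pet_reg.shape != ct.shape:
        raise ValueError(f"shape mismatch: PET {pet_reg.shape} vs CT {ct.shape}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    from matplotlib import colormaps

    ct_n = _normalize01(ct.pixels)
    pet_n = _normalize01(pet_reg.pixels)
    base = np.repeat(ct_n[..., None], 3, axis=-1)
    hot = colormaps["hot"](pet_n)[..., :3]
    return np.clip((1.0 - alpha) * base + alpha * hot, 0.0, 1.0)


def segment_high_uptake(
    pet_reg: Image2D, method: str = "fraction_of_max", value: float = 0.4
) -> SegmentationResult:
    """Threshold the registered PET to locate high-uptake regions.

    ``fraction_of_max`` keeps pixels >= value * max (value in (0, 1));
    ``fixed`` keeps pixels >= value.
    """
    px = pet_reg.pixels
    if method == "fraction_of_max":
        if not 0.0 < value < 1.0:
            raise ValueError(f"fraction_of_max value must be in (0, 1), got {value}")
        threshold = value * float(px.max())
    elif method == "fixed":
        threshold = float(value)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    mask = (px >= threshold).astype(np.uint8)
    return SegmentationResult(mask=mask, threshold_used=threshold, n_foreground=int(mask.sum()))


def accuracy_metrics(mask: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Pixel accuracy, Dice and Jaccard between two binary masks.

    Both empty => perfect agreement (Dice and Jaccard defined as 1).
    """
    a = np.asarray(mask).astype(bool)
    b = np.asarray(truth).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    total = a.size
    pixel_accuracy = float((a == b).sum() / total)
    denom = a.sum() + b.sum()
    dice = 1.0 if denom == 0 else float(2.0 * inter / denom)
    jaccard = 1.0 if union == 0 else float(inter / union)
    return {"pixel_accuracy": pixel_accuracy, "dice": dice, "jaccard": jaccard}


def relative_error(
    estimate: np.ndarray, truth: np.ndarray, scales: np.ndarray | None = None
) -> float:
    """Mean relative error in percent, per-component normalized.

    error = mean_i |estimate_i - truth_i| / scales_i * 100.  ``scales``
    should be each parameter's search-range half-width so the error is
    comparable across heterogeneous units (radians vs pixels); if omitted
    it falls back to |truth| per component, which then must be nonzero.
    """
    est = np.asarray(estimate, dtype=np.float64).ravel()
    tru = np.asarray(truth, dtype=np.float64).ravel()
    if est.shape != tru.shape:
        raise ValueError("estimate and truth must have the same length")
    if scales is None:
        sc = np.abs(tru)
    else:
        sc = np.broadcast_to(np.asarray(scales, dtype=np.float64).ravel(), est.shape)
    if np.any(sc <= 0):
        raise ValueError("all error scales must be positive")
    return float(np.mean(np.abs(est - tru) / sc) * 100.0)
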