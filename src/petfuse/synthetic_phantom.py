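"""Co-registered CT-like / PET-like phantom pairs with known ground truth.

No patient scans ship with this package, so validation runs on synthetic
slices that reproduce the features the registration method relies on:

* CT: piecewise-constant soft-tissue body (an ellipse), a sharp
  high-intensity "bone" rim along the body outline plus a vertebra-like
  disc — the clear, high-contrast anatomy whose edges the cellular
  neural network extracts.
* PET: smooth body-wide tracer uptake with one or more Gaussian "hot"
  lesions inside the body, Gaussian-blurred to emulate PET's low spatial
  resolution and degraded by additive Gaussian noise, then resampled by
  a known rigid transform (the misalignment the registration must undo).

All stochastic choices (the transform when not given, lesion positions,
the noise field) come from one numpy Generator keyed by ``seed``, drawn
in that fixed order, so phantoms are bit-reproducible.

The module also hosts the end-to-end benchmark used for validation:
generate a batch of phantoms, register each PET to its CT edge image,
and score transform recovery and high-uptake segmentation against the
generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import RigidTransform, invert, resample
from .image_io import Image2D, Modality

#: Misalignment ranges the transform is drawn from when not specified:
#: |beta| <= 0.2 rad, |tx|, |ty| <= 8 px — typical slice misalignment at
#: this image scale, and comfortably inside the default search grid.
MAX_BETA = 0.2
MAX_SHIFT = 8.0

#: Full-width-half-maximum factor for a Gaussian: FWHM = 2 sqrt(2 ln 2) sigma.
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class Phantom:
    """A CT/PET pair with the ground truth needed to score the pipeline.

    ``pet`` is the misaligned floating image (already resampled by
    ``true_transform``); ``pet_aligned`` keeps the pre-transform PET for
    truth checks.  ``lesion_mask`` lives in the CT frame and marks pixels
    within one FWHM of each lesion center.
    """

    ct: Image2D
    pet: Image2D
    pet_aligned: Image2D
    true_transform: RigidTransform
    lesion_mask: np.ndarray
    lesion_centers: np.ndarray  # (n, 2) row/col, CT frame
    seed: int


def _ellipse_rho(shape: tuple[int, int]) -> np.ndarray:
    """Normalized elliptical radius of every pixel (1.0 = body outline)."""
    H, W = shape
    cr, cc = (H - 1) / 2.0, (W - 1) / 2.0
    ar, ac = 0.38 * H, 0.30 * W
    rows, cols = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    return np.sqrt(((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2)


def generate_phantom(
    seed: int,
    size: int = 128,
    n_lesions: int = 1,
    beta: float | None = None,
    tx: float | None = None,
    ty: float | None = None,
    noise_sd: float = 0.05,
    pet_blur_sigma: float = 2.0,
    lesion_sigma: float | None = None,
) -> Phantom:
    """Generate a reproducible CT/PET phantom pair.

    Parameters
    ----------
    seed : int
        Keys the phantom's private random stream.
    size : int
        Image side length in pixels (>= 64).
    n_lesions : int
        Number of hot lesions (>= 1), placed inside the body core.
    beta, tx, ty : float, optional
        The rigid misalignment applied to the PET.  Any component left as
        None is drawn uniformly from the module's default ranges.
    noise_sd : float
        Standard deviation of additive Gaussian PET noise (intensity
        units; the body uptake is 0.4 and lesion peaks ~1.4).
    pet_blur_sigma : float
        Gaussian blur, pixels, emulating PET's low spatial resolution.
    lesion_sigma : float, optional
        Gaussian lesion width in pixels; default 0.04 * size.
    """
    if size < 64:
        raise ValueError(f"size must be >= 64, got {size}")
    if n_lesions < 1:
        raise ValueError("n_lesions must be >= 1")
    if lesion_sigma is None:
        lesion_sigma = 0.04 * size
    rng = np.random.default_rng(seed)

    # Draw order is fixed: transform components, lesion centers, noise.
    b = rng.uniform(-MAX_BETA, MAX_BETA) if beta is None else float(beta)
    t_r = rng.uniform(-MAX_SHIFT, MAX_SHIFT) if tx is None else float(tx)
    t_c = rng.uniform(-MAX_SHIFT, MAX_SHIFT) if ty is None else float(ty)
    true_T = RigidTransform(beta=b, tx=t_r, ty=t_c)

    shape = (size, size)
    rho = _ellipse_rho(shape)
    H, W = shape
    cr, cc = (H - 1) / 2.0, (W - 1) / 2.0
    rows, cols = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")

    # --- CT: soft tissue 0.3, bone rim and vertebra 1.0, background 0.
    ct_px = np.zeros(shape)
    ct_px[rho <= 1.0] = 0.3
    ct_px[(rho >= 0.90) & (rho <= 1.0)] = 1.0
    vert = np.sqrt((rows - (cr + 0.22 * H)) ** 2 + (cols - cc) ** 2) <= 0.05 * size
    ct_px[vert] = 1.0

    # --- Lesion placement: integer pixels in the body core (rho <= 0.6).
    centers = []
    for _ in range(n_lesions):
        for _try in range(100):
            r = int(rng.integers(0, H))
            c = int(rng.integers(0, W))
            if rho[r, c] <= 0.6:
                centers.append((r, c))
                break
        else:
            raise RuntimeError("could not place a lesion inside the body in 100 tries")
    centers = np.array(centers, dtype=np.float64)

    # --- PET: smooth uptake + hot lesions, blur, noise, then misalign.
    pet_px = np.where(rho <= 1.0, 0.4, 0.0)
    for r, c in centers:
        d2 = (rows - r) ** 2 + (cols - c) ** 2
        pet_px = pet_px + np.exp(-d2 / (2.0 * lesion_sigma**2))
    if pet_blur_sigma > 0:
        pet_px = gaussian_filter(pet_px, pet_blur_sigma)
    if noise_sd > 0:
        pet_px = pet_px + rng.normal(0.0, noise_sd, shape)
    pet_aligned = Image2D(pixels=pet_px, modality=Modality.PET)
    pet_moved, _ = resample(pet_aligned, true_T, interpolation="bilinear", fill=0.0)
    pet_moved = Image2D(pixels=pet_moved.pixels, modality=Modality.PET)

    # --- Truth mask: within one FWHM of any lesion center, CT frame.
    radius = FWHM_FACTOR * lesion_sigma
    mask = np.zeros(shape, dtype=np.uint8)
    for r, c in centers:
        mask |= ((rows - r) ** 2 + (cols - c) ** 2 <= radius**2).astype(np.uint8)
    if not mask.any():
        raise RuntimeError("degenerate phantom: empty lesion mask")

    return Phantom(
        ct=Image2D(pixels=ct_px, modality=Modality.CT),
        pet=pet_moved,
        pet_aligned=pet_aligned,
        true_transform=true_T,
        lesion_mask=mask,
        lesion_centers=centers,
        seed=seed,
    )


def evaluate_registration_pipeline(
    seeds,
    size: int = 128,
    n_lesions: int = 1,
    noise_sd: float = 0.05,
    pet_blur_sigma: float = 2.0,
    config=None,
    threshold: float = 0.4,
):
    """Run the full phantom -> register -> segment benchmark.

    For each seed: generate a phantom (misalignment drawn from the
    phantom's stream), register its PET to the CT edge image, compare the
    recovered transform with the alignment-restoring truth
    ``invert(true_transform)`` (relative error normalized by the search
    half-widths 0.3 rad / 10 px / 10 px), resample the PET into the CT
    frame, segment high uptake at ``threshold`` fraction-of-max, and
    score the mask against the generator's lesion truth.

    Returns a pandas DataFrame with one row per seed and columns
    ``recovery_error_pct``, ``pixel_accuracy``, ``dice``, ``jaccard``,
    ``final_mi`` plus the recovered and true parameters.
    """
    import pandas as pd

    from .fusion_seg import accuracy_metrics, relative_error, segment_high_uptake
    from .registration import RegistrationConfig, register

    config = config or RegistrationConfig()
    half_widths = np.array(
        [
            (config.search["beta"][1] - config.search["beta"][0]) / 2.0,
            (config.search["tx"][1] - config.search["tx"][0]) / 2.0,
            (config.search["ty"][1] - config.search["ty"][0]) / 2.0,
        ]
    )
    records = []
    for seed in seeds:
        ph = generate_phantom(
            seed,
            size=size,
            n_lesions=n_lesions,
            noise_sd=noise_sd,
            pet_blur_sigma=pet_blur_sigma,
        )
        res = register(ph.pet, ph.ct, config)
        truth = invert(ph.true_transform)
        err = relative_error(res.u_star.params, truth.params, scales=half_widths)
        realigned, _ = resample(ph.pet, res.u_star, interpolation="bilinear", fill=0.0)
        seg = segment_high_uptake(realigned, method="fraction_of_max", value=threshold)
        acc = accuracy_metrics(seg.mask, ph.lesion_mask)
        records.append(
            {
                "seed": seed,
                "recovery_error_pct": err,
                "pixel_accuracy": acc["pixel_accuracy"],
                "dice": acc["dice"],
                "jaccard": acc["jaccard"],
                "final_mi": res.final_mi,
                "beta_hat": res.u_star.beta,
                "tx_hat": res.u_star.tx,
                "ty_hat": res.u_star.ty,
                "beta_true": truth.beta,
                "tx_true": truth.tx,
                "ty_true": truth.ty,
            }
        )
    return pd.DataFrame.from_records(records)
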