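"""Mutual-information-maximizing rigid registration of PET to CT.

The optimal transform is

    u* = argmax_T  I( PET o T , D )

where D is the reference: either the raw CT or, by default, the binary
edge image the cellular neural network extracts from it.  PET edges are
blurred and information-poor, so the PET stays a grayscale floating image
while the CT contributes its sharp anatomy through the edge map.

MI is estimated from the joint histogram of the warped PET and the
reference, restricted to the overlap mask, with the PET re-quantized over
the overlap at each evaluation.  The optimizer is fully deterministic:
an exhaustive coarse grid over (beta, tx, ty) followed by coordinate
descent with successively halved steps until every step drops below its
tolerance.  MI from a discrete histogram is piecewise smooth at best, so
a derivative-free search is the robust choice.  Ties in MI are broken
toward the smallest motion, lexicographically on (|beta|, |tx|, |ty|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cnn_core
from .geometry import RigidTransform, resample
from .image_io import Image2D, quantize
from .info_metrics import joint_histogram, mutual_information

#: Fraction of pixels below which the optimum's overlap is flagged degenerate.
MIN_OVERLAP_FRACTION = 0.10

#: MI differences below this (bits) are ties, broken toward smaller motion;
#: absorbs floating-point summation noise between equivalent transforms.
TIE_TOL = 1e-12


def _default_grid() -> dict:
    return {
        "beta": (-0.3, 0.3, 0.05),  # (lo, hi, step) radians
        "tx": (-10.0, 10.0, 2.0),  # pixels (rows)
        "ty": (-10.0, 10.0, 2.0),  # pixels (cols)
    }


def _default_tol() -> dict:
    return {"beta": 0.005, "tx": 0.25, "ty": 0.25}


@dataclass
class RegistrationConfig:
    """Search settings for :func:`register`.

    levels : gray levels for the floating (PET) histogram axis; the
        reference axis uses 2 levels in ``ct_edge`` mode (the edge image
        is binary by construction) and ``levels`` in ``ct_raw`` mode.
    reference_mode : "ct_edge" (register against the CNN edge image,
        default) or "ct_raw".
    search : coarse grid per parameter as (lo, hi, step).
    refine_tol : coordinate-descent stops once every step < its tolerance.
    seed : reserved for randomized multi-start strategies; the default
        grid + coordinate-descent optimizer is deterministic and ignores it.
    """

    levels: int = 64
    reference_mode: str = "ct_edge"
    search: dict = field(default_factory=_default_grid)
    refine_tol: dict = field(default_factory=_default_tol)
    cnn_step: float = cnn_core.DEFAULT_STEP
    cnn_duration: float = cnn_core.DEFAULT_DURATION
    seed: int = 0

    def grid_axis(self, name: str) -> np.ndarray:
        lo, hi, step = self.search[name]
        if hi < lo or step <= 0:
            raise ValueError(f"invalid search range for {name}: {self.search[name]}")
        n = int(np.floor((hi - lo) / step + 0.5)) + 1
        return lo + step * np.arange(n)


@dataclass
class RegistrationResult:
    """Best transform, its MI, and the full evaluation trace."""

    u_star: RigidTransform
    final_mi: float
    mi_trace: list  # [(RigidTransform, mi_bits), ...] in evaluation order
    n_evals: int
    low_overlap: bool = False


def _tie_key(T: RigidTransform) -> tuple:
    return (abs(T.beta), abs(T.tx), abs(T.ty))


def _is_better(mi: float, T: RigidTransform, best_mi: float, best_T: RigidTransform | None) -> bool:
    if best_T is None:
        return True
    if mi > best_mi + TIE_TOL:
        return True
    return abs(mi - best_mi) <= TIE_TOL and _tie_key(T) < _tie_key(best_T)


class _Objective:
    """MI of (PET warped by T) vs the fixed quantized reference."""

    def __init__(self, pet: Image2D, reference: Image2D, ref_levels: int, pet_levels: int):
        self.pet = pet
        self.q_ref = quantize(reference, ref_levels)
        self.pet_levels = pet_levels
        self.fill = float(pet.pixels.min())
        self.trace: list = []

    def __call__(self, T: RigidTransform) -> float:
        warped, overlap = resample(self.pet, T, interpolation="bilinear", fill=self.fill)
        if not overlap.any():
            mi = -np.inf
        else:
            q_mov = quantize(warped, self.pet_levels, mask=overlap)
            mi = mutual_information(joint_histogram(q_mov, self.q_ref, mask=overlap)).I
        self.trace.append((T, mi))
        return mi


def register(pet: Image2D, ct: Image2D, config: RegistrationConfig | None = None) -> RegistrationResult:
    """Recover the rigid transform aligning PET onto the CT reference.

    In ``ct_edge`` mode the CT is first passed through the CNN edge
    extractor and the (binary) edge image is the reference; in ``ct_raw``
    mode the CT intensities are used directly.  Runs an exhaustive coarse
    grid search followed by coordinate-descent refinement at halved steps.
    """
    config = config or RegistrationConfig()
    pet.check_registration_size()
    ct.check_registration_size()
    if pet.shape != ct.shape:
        raise ValueError(f"PET and CT shapes differ: {pet.shape} vs {ct.shape}")

    if config.reference_mode == "ct_edge":
        reference = cnn_core.edge_extract(ct, step=config.cnn_step, duration=config.cnn_duration)
        ref_levels = 2
    elif config.reference_mode == "ct_raw":
        reference = ct
        ref_levels = config.levels
    else:
        raise ValueError(f"unknown reference_mode {config.reference_mode!r}")

    objective = _Objective(pet, reference, ref_levels, config.levels)

    beta_ax = config.grid_axis("beta")
    tx_ax = config.grid_axis("tx")
    ty_ax = config.grid_axis("ty")
    if min(beta_ax.size, tx_ax.size, ty_ax.size) == 0:
        raise ValueError("empty search grid")

    best_T, best_mi = None, -np.inf
    for b in beta_ax:
        for tx in tx_ax:
            for ty in ty_ax:
                T = RigidTransform(float(b), float(tx), float(ty))
                mi = objective(T)
                if _is_better(mi, T, best_mi, best_T):
                    best_T, best_mi = T, mi

    # Coordinate descent: halve all steps, sweep each parameter with +/-
    # moves until no move improves, halve again, stop when every step is
    # below its tolerance.
    steps = {name: config.search[name][2] for name in ("beta", "tx", "ty")}
    tol = config.refine_tol
    while True:
        steps = {k: v / 2.0 for k, v in steps.items()}
        active = [k for k in steps if steps[k] >= tol[k]]
        if not active:
            break
        moved = True
        sweeps = 0
        while moved and sweeps < 50:
            moved = False
            sweeps += 1
            for name in active:
                for sign in (+1.0, -1.0):
                    p = dict(beta=best_T.beta, tx=best_T.tx, ty=best_T.ty)
                    p[name] += sign * steps[name]
                    T = RigidTransform(**p)
                    mi = objective(T)
                    if _is_better(mi, T, best_mi, best_T):
                        best_T, best_mi = T, mi
                        moved = True

    _, overlap = resample(pet, best_T, interpolation="bilinear", fill=objective.fill)
    low_overlap = overlap.mean() < MIN_OVERLAP_FRACTION
    return RegistrationResult(
        u_star=best_T,
        final_mi=float(best_mi),
        mi_trace=objective.trace,
        n_evals=len(objective.trace),
        low_overlap=low_overlap,
    )


def fuse_after_register(
    pet: Image2D, ct: Image2D, result: RegistrationResult, alpha: float = 0.5
) -> np.ndarray:
    """Resample PET by the recovered transform and overlay it on CT."""
    from .fusion_seg import fuse

    warped, _ = resample(pet, result.u_star, interpolation="bilinear", fill=float(pet.pixels.min()))
    return fuse(warped, ct, alpha=alpha)
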