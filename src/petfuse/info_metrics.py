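"""Joint histograms, entropies and mutual information (in bits).

For two quantized images U and D the joint histogram counts co-located
gray-level pairs: n_ud is the number of pixel positions x with
(U(x), D(x)) = (u, d), and N = sum n_ud.  The joint probability estimate
is j_UD(u, d) = n_ud / N with marginals j_U(u) = sum_d j_UD(u, d) and
j_D(d) = sum_u j_UD(u, d).

Entropies use log base 2 with the convention 0 log 0 = 0:

    G(U)   = -sum_u j_U(u) log2 j_U(u)
    G(U,D) = -sum_{u,d} j_UD(u,d) log2 j_UD(u,d)

Mutual information is computed directly from the joint law,

    I(U,D) = sum_{u,d} j_UD(u,d) log2 [ j_UD(u,d) / (j_U(u) j_D(d)) ]

and satisfies the identity I(U,D) = G(U) + G(D) - G(U,D).  I is maximal
when the two images are aligned, which is what the registration optimizer
exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import QuantizedImage

#: Numerical tolerance for the MI/entropy identity, in bits.
IDENTITY_TOL = 1e-9


@dataclass(frozen=True)
class JointHistogram:
    """Co-located gray-level pair counts and derived probabilities."""

    counts: np.ndarray  # (L_U, L_D) integer matrix n_ud

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be a 2D matrix")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if c.sum() <= 0:
            raise ValueError("joint histogram is empty")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def levels(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def joint_prob(self) -> np.ndarray:
        return self.counts / self.total

    @property
    def marginal_u(self) -> np.ndarray:
        return self.joint_prob.sum(axis=1)

    @property
    def marginal_d(self) -> np.ndarray:
        return self.joint_prob.sum(axis=0)


@dataclass(frozen=True)
class MIResult:
    """Marginal/joint entropies and mutual information, all in bits."""

    H_U: float
    H_D: float
    H_UD: float
    I: float


def joint_histogram(
    qU: QuantizedImage,
    qD: QuantizedImage,
    mask: np.ndarray | None = None,
) -> JointHistogram:
    """Count co-located gray-level pairs between two quantized images.

    ``mask`` (boolean, same shape) restricts counting to selected pixels;
    registration uses it to keep the histogram inside the transform
    overlap region so that fill values never bias the estimate.
    """
    lu, ld = qU.labels, qD.labels
    if lu.shape != ld.shape:
        raise ValueError(f"shape mismatch: {lu.shape} vs {ld.shape}")
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if m.shape != lu.shape:
            raise ValueError(f"mask shape {m.shape} does not match images {lu.shape}")
        if not m.any():
            raise ValueError("empty mask: joint histogram would be degenerate")
        lu, ld = lu[m], ld[m]
    Lu, Ld = qU.levels, qD.levels
    flat = lu.ravel() * Ld + ld.ravel()
    counts = np.bincount(flat, minlength=Lu * Ld).reshape(Lu, Ld)
    return JointHistogram(counts=counts)


def entropy(p: np.ndarray) -> float:
    """Shannon entropy -sum p log2 p in bits, with 0 log 0 = 0.

    ``p`` must be a probability vector (non-negative, summing to 1)."""
    p = np.asarray(p, dtype=np.float64).ravel()
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()}")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def mutual_information(h: JointHistogram) -> MIResult:
    """Entropies and mutual information of a joint histogram.

    I is computed directly from the joint/marginal probability ratio
    (zero-probability cells skipped); the entropies come from the
    marginal and joint laws, so the identity I = H_U + H_D - H_UD serves
    as an internal cross-check rather than the definition.
    """
    j = h.joint_prob
    pu = h.marginal_u
    pd_ = h.marginal_d
    H_U = entropy(pu)
    H_D = entropy(pd_)
    H_UD = entropy(j)
    nz = j > 0
    denom = np.outer(pu, pd_)
    I = float(np.sum(j[nz] * np.log2(j[nz] / denom[nz])))
    return MIResult(H_U=H_U, H_D=H_D, H_UD=H_UD, I=I)
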