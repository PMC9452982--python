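"""Chua-Yang cellular neural network simulation and CT edge extraction.

A cellular neural network (CNN, in the original cellular sense, not a
convolutional deep network) is a lattice of locally coupled analog cells.
Each cell (i, j) carries a state x_ij evolving by

    dx_ij/dt = -x_ij + (A * y)_ij + (B * u)_ij + z

where ``A`` is the 3x3 feedback template applied to the neighbouring cell
outputs y, ``B`` is the 3x3 control template applied to the (fixed) inputs
u in [-1, 1], ``z`` is a scalar bias, and the output nonlinearity is the
piecewise-linear saturation

    y = 0.5 * (|x + 1| - |x - 1|)

so that y = x for |x| <= 1 and y = sign(x) otherwise.  Cells outside the
grid contribute zero output and zero input (Dirichlet boundary).

With the classical edge-detection template (Laplacian-like control
template, unit self-feedback, bias -1) the steady-state output marks
intensity transitions: a cell saturates to +1 only where its input differs
from enough of its neighbours.  The CT image, normalized to [-1, 1], is
run through this network and the thresholded output is the binary edge
image used as the registration reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import correlate

from .image_io import Image2D, Modality


@dataclass(frozen=True)
class CNNTemplates:
    """Feedback template A, control template B (both 3x3) and bias z."""

    A: np.ndarray
    B: np.ndarray
    z: float

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=np.float64)
        B = np.asarray(self.B, dtype=np.float64)
        if A.shape != (3, 3) or B.shape != (3, 3):
            raise ValueError("CNN templates must be exactly 3x3")
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B)) and np.isfinite(self.z)):
            raise ValueError("CNN template entries and bias must be finite")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)


@dataclass(frozen=True)
class CNNState:
    """Cell states x, outputs y = 0.5(|x+1| - |x-1|) and inputs u."""

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray


#: Classical edge-detection template: unit self-feedback, Laplacian-style
#: control template and bias -1.  On inputs in [-1, 1] the steady state is
#: +1 on the bright side of intensity transitions and -1 elsewhere.
EDGE_DEFAULT = CNNTemplates(
    A=np.array([[0.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 0.0]]),
    B=np.array([[-1.0, -1.0, -1.0], [-1.0, 8.0, -1.0], [-1.0, -1.0, -1.0]]),
    z=-1.0,
)

DEFAULT_STEP = 0.1
DEFAULT_DURATION = 10.0


def output_nonlinearity(x: np.ndarray) -> np.ndarray:
    """Piecewise-linear saturation y = 0.5(|x+1| - |x-1|).

    Algebraically this equals clamping x to [-1, 1], which is how it is
    computed: the literal two-subtraction form drifts by an ulp in
    floating point, breaking the exact saturation bound."""
    return np.clip(x, -1.0, 1.0)


def normalize_to_cnn_range(img: Image2D) -> np.ndarray:
    """Map intensities linearly so min -> -1 and max -> +1.

    A constant image maps to all -1 (background convention)."""
    px = img.pixels
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        return np.full(px.shape, -1.0)
    return -1.0 + 2.0 * (px - lo) / (hi - lo)


def cnn_evolve(
    input: np.ndarray,
    templates: CNNTemplates,
    step: float = DEFAULT_STEP,
    duration: float = DEFAULT_DURATION,
    initial_state: np.ndarray | str = "copy-input",
) -> CNNState:
    """Integrate the Chua-Yang cell dynamics by forward Euler.

    Parameters
    ----------
    input : ndarray
        Cell inputs u in [-1, 1], shape at least 3x3; held fixed.
    templates : CNNTemplates
    step : float
        Euler step in network time units; must be > 0.
    duration : float
        Total integration time; must be >= step.
    initial_state : ndarray or "copy-input"
        Initial cell states x(0); "copy-input" starts from x(0) = u.

    Returns
    -------
    CNNState with the final states and outputs.
    """
    u = np.asarray(input, dtype=np.float64)
    if u.ndim != 2 or min(u.shape) < 3:
        raise ValueError("CNN input must be 2D and at least 3x3")
    if not np.isfinite(step) or step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if duration < step:
        raise ValueError("duration must be at least one step")

    if isinstance(initial_state, str):
        if initial_state != "copy-input":
            raise ValueError(f"unknown initial_state {initial_state!r}")
        x = u.copy()
    else:
        x = np.asarray(initial_state, dtype=np.float64).copy()
        if x.shape != u.shape:
            raise ValueError("initial_state shape must match input shape")

    # B * u never changes during integration; precompute it.
    bu = correlate(u, templates.B, mode="constant", cval=0.0)
    n_steps = int(round(duration / step))
    for _ in range(n_steps):
        y = output_nonlinearity(x)
        ay = correlate(y, templates.A, mode="constant", cval=0.0)
        x += step * (-x + ay + bu + templates.z)
    return CNNState(x=x, y=output_nonlinearity(x), u=u)


def edge_extract(
    ct: Image2D,
    templates: CNNTemplates = EDGE_DEFAULT,
    step: float = DEFAULT_STEP,
    duration: float = DEFAULT_DURATION,
) -> Image2D:
    """Extract a binary edge image from a CT slice with the CNN.

    The CT is normalized to [-1, 1], the network is run to (near) steady
    state from x(0) = u, and cells with positive output are marked edge
    (1); all others are 0.  A constant input yields an empty edge set.

    The input is edge-replicated by one pixel before the run and the
    output cropped back, so that cells on the raster border see their own
    intensity rather than the network's zero (mid-gray) padding; without
    this, any bright region touching the border would be flagged as an
    edge against the padding, not against the image.
    """
    u = normalize_to_cnn_range(ct)
    u_pad = np.pad(u, 1, mode="edge")
    state = cnn_evolve(u_pad, templates, step=step, duration=duration, initial_state="copy-input")
    edges = (state.y[1:-1, 1:-1] > 0.0).astype(np.float64)
    return Image2D(pixels=edges, spacing=ct.spacing, modality=Modality.EDGE)


def load_template_config(path: str | Path) -> tuple[CNNTemplates, float, float]:
    """Load templates plus integration settings from a plain-text file.

    The file holds 21 whitespace-separated numbers in order: nine A values
    (row-major), nine B values, bias z, step, duration.  Lines starting
    with ``#`` are comments.
    """
    tokens: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0]
        tokens.extend(float(t) for t in line.split())
    if len(tokens) != 21:
        raise ValueError(
            f"template config must hold 21 numbers (9 A, 9 B, z, step, duration), "
            f"got {len(tokens)}"
        )
    A = np.array(tokens[0:9]).reshape(3, 3)
    B = np.array(tokens[9:18]).reshape(3, 3)
    z, step, duration = tokens[18], tokens[19], tokens[20]
    return CNNTemplates(A=A, B=B, z=z), step, duration
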