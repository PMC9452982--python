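import numpy as np
import pytest

from petfuse import (
    CNNTemplates,
    EDGE_DEFAULT,
    Image2D,
    Modality,
    cnn_evolve,
    edge_extract,
    normalize_to_cnn_range,
)
from petfuse.cnn_core import load_template_config, output_nonlinearity

ZERO = np.zeros((3, 3))


def has_opposite_neighbour(binary, r, c):
    """Brute-force scan: does (r, c) have an 8-neighbour with the other value?"""
    H, W = binary.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and binary[rr, cc] != binary[r, c]:
                return True
    return False


class TestNormalize:
    def test_endpoints(self):
        arr = normalize_to_cnn_range(Image2D(pixels=np.array([[0.0, 255.0]] * 2)))
        assert set(arr.ravel()) == {-1.0, 1.0}

    def test_constant_maps_to_background(self):
        arr = normalize_to_cnn_range(Image2D(pixels=np.full((5, 5), 42.0)))
        assert np.all(arr == -1.0)

    def test_midpoint_maps_to_zero(self):
        img = Image2D(pixels=np.array([[10.0, 20.0, 30.0]] * 3))
        arr = normalize_to_cnn_range(img)
        assert arr[0, 1] == pytest.approx(0.0)


class TestDynamics:
    def test_zero_templates_decay(self, rng):
        """With A = B = z = 0 the state is pure exponential decay."""
        x0 = rng.uniform(-1, 1, (5, 5))
        prev = np.abs(x0).copy()
        for t in (1.0, 2.0, 4.0):
            st = cnn_evolve(np.zeros((5, 5)), CNNTemplates(ZERO, ZERO, 0.0),
                            step=0.1, duration=t, initial_state=x0)
            assert np.all(np.abs(st.x) <= prev + 1e-12)
            prev = np.abs(st.x)

    def test_center_feedback_matches_scalar_ode(self):
        """Center-only A with a_00 = 2 makes every cell follow the scalar
        recurrence x <- x + h(-x + 2 y(x)); all cells must track it exactly
        and saturate toward +1 output."""
        A = ZERO.copy()
        A[1, 1] = 2.0
        h, T = 0.1, 6.0
        st = cnn_evolve(np.zeros((6, 6)), CNNTemplates(A, ZERO, 0.0),
                        step=h, duration=T, initial_state=np.full((6, 6), 0.5))
        x = 0.5
        for _ in range(int(round(T / h))):
            y = 0.5 * (abs(x + 1) - abs(x - 1))
            x = x + h * (-x + 2 * y)
        np.testing.assert_allclose(st.x, x, rtol=0, atol=1e-12)
        assert np.all(st.y == 1.0)

    def test_output_saturation_bound(self, rng):
        """|y| <= 1 for all cells at all sampled times, any templates."""
        templates = CNNTemplates(rng.normal(size=(3, 3)), rng.normal(size=(3, 3)), 0.5)
        u = rng.uniform(-1, 1, (8, 8))
        for dur in (0.5, 2.0, 10.0):
            st = cnn_evolve(u, templates, step=0.1, duration=dur)
            assert np.max(np.abs(st.y)) <= 1.0

    def test_nonlinearity_regions(self, rng):
        x = rng.uniform(-3, 3, 100)
        y = output_nonlinearity(x)
        inner = np.abs(x) <= 1
        np.testing.assert_allclose(y[inner], x[inner])
        np.testing.assert_allclose(y[~inner], np.sign(x[~inner]))

    def test_parameter_errors(self):
        with pytest.raises(ValueError, match="positive"):
            cnn_evolve(np.zeros((4, 4)), EDGE_DEFAULT, step=-0.1)
        with pytest.raises(ValueError, match="finite"):
            CNNTemplates(np.full((3, 3), np.inf), ZERO, 0.0)
        with pytest.raises(ValueError, match="3x3"):
            CNNTemplates(np.zeros((5, 5)), ZERO, 0.0)


class TestEdgeExtract:
    def test_constant_input_no_edges(self):
        edge = edge_extract(Image2D(pixels=np.full((16, 16), 7.0)))
        assert edge.modality is Modality.EDGE
        assert edge.pixels.sum() == 0

    def test_halves_edges_hug_the_boundary(self, halves_image):
        edge = edge_extract(halves_image)
        marked = np.argwhere(edge.pixels > 0)
        assert len(marked) > 0
        # confined to the two columns adjacent to the step at col 7|8
        assert set(marked[:, 1]).issubset({7, 8})

    def test_single_bright_pixel(self):
        px = np.zeros((16, 16))
        px[8, 8] = 255.0
        edge = edge_extract(Image2D(pixels=px))
        assert edge.pixels[8, 8] == 1.0
        # all flagged pixels lie inside the bright pixel's 8-neighbourhood
        marked = np.argwhere(edge.pixels > 0)
        assert np.all(np.max(np.abs(marked - [8, 8]), axis=1) <= 1)

    def test_edge_soundness_on_random_binary(self, rng):
        """Every flagged pixel must touch an opposite-valued 8-neighbour."""
        for _ in range(10):
            binary = (rng.random((20, 20)) > rng.uniform(0.2, 0.8)).astype(float)
            edge = edge_extract(Image2D(pixels=binary))
            for r, c in np.argwhere(edge.pixels > 0):
                assert has_opposite_neighbour(binary, r, c)


def test_template_config_round_trip(tmp_path):
    cfg = tmp_path / "edge.txt"
    cfg.write_text(
        "# classical edge template\n"
        "0 0 0  0 1 0  0 0 0\n"
        "-1 -1 -1  -1 8 -1  -1 -1 -1\n"
        "-1\n0.1 10\n"
    )
    templates, step, duration = load_template_config(cfg)
    np.testing.assert_array_equal(templates.A, EDGE_DEFAULT.A)
    np.testing.assert_array_equal(templates.B, EDGE_DEFAULT.B)
    assert templates.z == -1.0 and step == 0.1 and duration == 10.0
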