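import numpy as np
import pytest

from petfuse import (
    Image2D,
    JointHistogram,
    entropy,
    joint_histogram,
    mutual_information,
    quantize,
)
from petfuse.image_io import QuantizedImage


def q(labels, levels):
    labels = np.asarray(labels)
    return QuantizedImage(labels=labels, levels=levels,
                          source_range=(0.0, float(levels - 1)))


def random_histogram(rng):
    Lu, Ld = rng.integers(2, 9, size=2)
    counts = rng.integers(0, 12, size=(Lu, Ld))
    if counts.sum() == 0:
        counts[0, 0] = 1
    return JointHistogram(counts=counts)


class TestJointHistogram:
    def test_hand_enumerated_diagonal(self):
        """qU = qD = [[0,0],[1,1]] -> counts [[2,0],[0,2]]."""
        labels = [[0, 0], [1, 1]]
        h = joint_histogram(q(labels, 2), q(labels, 2))
        np.testing.assert_array_equal(h.counts, [[2, 0], [0, 2]])
        assert h.total == 4
        np.testing.assert_allclose(np.diag(h.joint_prob), [0.5, 0.5])

    def test_single_cell(self):
        h = joint_histogram(q(np.zeros((3, 3), int), 2), q(np.zeros((3, 3), int), 2))
        assert h.counts[0, 0] == 9 and h.total == 9
        assert h.joint_prob[0, 0] == 1.0

    def test_normalization_and_marginals(self, rng):
        """Sum of joint_prob is 1 and marginals are its row/col sums."""
        for _ in range(20):
            h = random_histogram(rng)
            assert h.joint_prob.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(h.marginal_u, h.joint_prob.sum(axis=1))
            np.testing.assert_allclose(h.marginal_d, h.joint_prob.sum(axis=0))
            assert h.total == h.counts.sum()

    def test_mask_restricts_counts(self):
        labels = np.array([[0, 0], [1, 1]])
        mask = np.array([[True, True], [False, False]])
        h = joint_histogram(q(labels, 2), q(labels, 2), mask=mask)
        assert h.total == 2 and h.counts[0, 0] == 2

    def test_shape_mismatch_and_empty_mask(self):
        a, b = q(np.zeros((2, 2), int), 2), q(np.zeros((3, 3), int), 2)
        with pytest.raises(ValueError, match="shape"):
            joint_histogram(a, b)
        with pytest.raises(ValueError, match="mask"):
            joint_histogram(a, a, mask=np.zeros((2, 2), bool))


class TestEntropy:
    @pytest.mark.parametrize(
        "p,expected",
        [([1.0], 0.0), ([0.5, 0.5], 1.0), ([0.25] * 4, 2.0), ([0.5, 0.5, 0.0], 1.0)],
    )
    def test_closed_forms(self, p, expected):
        assert entropy(np.array(p)) == pytest.approx(expected, abs=1e-12)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            entropy(np.array([1.2, -0.2]))

    def test_not_normalized_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            entropy(np.array([0.5, 0.2]))


class TestMutualInformation:
    def test_identical_images_give_marginal_entropy(self):
        """I(U, U) = H(U): two levels with occupancy 2+2 -> 1 bit."""
        labels = [[0, 0], [1, 1]]
        r = mutual_information(joint_histogram(q(labels, 2), q(labels, 2)))
        assert r.I == pytest.approx(1.0, abs=1e-12)
        assert r.H_U == pytest.approx(1.0, abs=1e-12)

    def test_independent_pattern_zero_information(self):
        """Joint uniform over 4 cells with uniform marginals -> I = 0."""
        r = mutual_information(joint_histogram(q([[0, 0], [1, 1]], 2), q([[0, 1], [0, 1]], 2)))
        assert r.I == pytest.approx(0.0, abs=1e-12)
        assert r.H_UD == pytest.approx(2.0, abs=1e-12)

    def test_entropy_identity_on_random_histograms(self, rng):
        """Direct joint/marginal-ratio I equals H_U + H_D - H_UD."""
        for _ in range(100):
            r = mutual_information(random_histogram(rng))
            assert r.I == pytest.approx(r.H_U + r.H_D - r.H_UD, abs=1e-9)
            assert r.I >= -1e-12
            assert r.I <= min(r.H_U, r.H_D) + 1e-9
            assert r.H_UD <= r.H_U + r.H_D + 1e-12

    def test_symmetry_under_transpose(self, rng):
        for _ in range(30):
            h = random_histogram(rng)
            rt = mutual_information(JointHistogram(counts=h.counts.T))
            assert mutual_information(h).I == pytest.approx(rt.I, abs=1e-12)

    def test_merging_levels_never_increases_information(self, rng):
        """Data-processing sanity: pooling two gray levels of either image
        can only lose information."""
        for _ in range(30):
            h = random_histogram(rng)
            I0 = mutual_information(h).I
            c = h.counts
            if c.shape[0] > 2:
                merged = np.vstack([c[0] + c[1], c[2:]])
                assert mutual_information(JointHistogram(counts=merged)).I <= I0 + 1e-12
            if c.shape[1] > 2:
                merged = np.hstack([(c[:, 0] + c[:, 1])[:, None], c[:, 2:]])
                assert mutual_information(JointHistogram(counts=merged)).I <= I0 + 1e-12

    def test_quantized_image_path(self, rng):
        """MI through quantize + joint_histogram on a real-valued pair."""
        px = rng.normal(size=(16, 16))
        img = Image2D(pixels=px)
        h = joint_histogram(quantize(img, 8), quantize(img, 8))
        r = mutual_information(h)
        assert r.I == pytest.approx(r.H_U, abs=1e-9)  # image vs itself
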