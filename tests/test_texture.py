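"""GLCM / run-length feature tests against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neovessel import texture as tx

OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))  # the four averaged offsets


def brute_glcm(img, levels, distance, symmetric=True):
    """Direct double-loop co-occurrence counting."""
    q = tx.quantize(img, levels)
    h, w = q.shape
    counts = np.zeros((levels, levels))
    for dr, dc in OFFSETS:
        dr, dc = dr * distance, dc * distance
        m = np.zeros((levels, levels))
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    m[q[r, c], q[r2, c2]] += 1
        counts += m + m.T if symmetric else m
    counts /= len(OFFSETS)
    return counts


class TestGLCM:
    def test_hand_counted_two_by_two(self):
        # [[0,1],[0,1]]: two horizontal (0,1) pairs only
        img = np.array([[0.0, 0.6], [0.0, 0.6]])
        m = tx.compute_glcm(img, levels=2, distance=1, angles=(0.0,),
                            symmetric=False)
        assert m.counts[0, 1] == 2
        assert m.counts.sum() == 2
        assert m.probs[0, 1] == 1.0

    def test_constant_image_on_diagonal(self):
        m = tx.compute_glcm(np.full((8, 8), 0.4), levels=8)
        k = tx.quantize(np.array([[0.4]]), 8)[0, 0]
        assert m.probs[k, k] == 1.0

    def test_matches_bruteforce(self, rng):
        img = rng.random((8, 8))
        m = tx.compute_glcm(img, levels=8, distance=1)
        expected = brute_glcm(img, 8, 1)
        assert np.allclose(m.counts, expected, atol=1e-9)
        assert np.allclose(m.probs, expected / expected.sum(), atol=1e-12)

    def test_invariant_to_bin_preserving_rescale(self, rng):
        # quantized identically => identical matrix
        img = rng.integers(0, 8, (10, 10)) / 8.0 + 0.01
        a = tx.compute_glcm(img, levels=8).probs
        b = tx.compute_glcm(img + 0.05, levels=8).probs
        assert np.allclose(a, b)


class TestGLCMFeatures:
    def _point_mass(self, i, j, levels=8):
        p = np.zeros((levels, levels))
        p[i, j] = 1.0
        return tx.GLCMatrix(counts=p, probs=p, levels=levels, distance=1)

    def test_diagonal_point_mass(self):
        f = tx.glcm_features(self._point_mass(2, 2))
        assert f["energy"] == 1.0
        assert f["entropy"] == 0.0
        assert f["contrast"] == 0.0
        assert f["homogeneity"] == 1.0
        assert f["max_probability"] == 1.0

    def test_off_diagonal_point_mass(self):
        f = tx.glcm_features(self._point_mass(0, 3))
        assert f["contrast"] == 9.0
        assert f["dissimilarity"] == 3.0
        assert f["homogeneity"] == pytest.approx(0.1)

    def test_uniform_distribution(self):
        p = np.full((4, 4), 1 / 16)
        f = tx.glcm_features(tx.GLCMatrix(p, p, 4, 1))
        assert f["energy"] == pytest.approx(1 / 16)
        assert f["entropy"] == pytest.approx(4.0)

    def test_matches_double_sum_oracle(self, rng):
        p = rng.random((8, 8))
        p /= p.sum()
        f = tx.glcm_features(tx.GLCMatrix(p, p, 8, 1))
        L = 8
        acc = dict.fromkeys(f, 0.0)
        mu_i = sum(i * p[i, j] for i in range(L) for j in range(L))
        mu_j = sum(j * p[i, j] for i in range(L) for j in range(L))
        sd_i = np.sqrt(sum((i - mu_i) ** 2 * p[i, j]
                           for i in range(L) for j in range(L)))
        sd_j = np.sqrt(sum((j - mu_j) ** 2 * p[i, j]
                           for i in range(L) for j in range(L)))
        m1 = sum(abs(i - j) * p[i, j]
                 for i in range(L) for j in range(L))
        var = sum((abs(i - j) - m1) ** 2 * p[i, j]
                  for i in range(L) for j in range(L))
        for i in range(L):
            for j in range(L):
                v = p[i, j]
                acc["energy"] += v * v
                acc["entropy"] += -v * np.log2(v)
                acc["contrast"] += (i - j) ** 2 * v
                acc["homogeneity"] += v / (1 + (i - j) ** 2)
                acc["dissimilarity"] += abs(i - j) * v
                acc["inverse_difference_momentum"] += \
                    v / (1 + (i - j) ** 2 / L**2)
                acc["correlation"] += \
                    (i - mu_i) * (j - mu_j) * v / (sd_i * sd_j)
                acc["moment3"] += ((abs(i - j) - m1) / np.sqrt(var))**3 * v
                acc["moment4"] += ((abs(i - j) - m1) / np.sqrt(var))**4 * v
        acc["moment1"] = m1
        acc["moment2"] = np.sqrt(var)
        acc["max_probability"] = p.max()
        for key, val in acc.items():
            assert f[key] == pytest.approx(val, abs=1e-10), key

    def test_rejects_empty_matrix(self):
        z = np.zeros((4, 4))
        with pytest.raises(ValueError):
            tx.glcm_features(tx.GLCMatrix(z, z, 4, 1))


def brute_rlm(img, levels, direction):
    q = tx.quantize(np.asarray(img, float), levels)
    lines = list(tx._scan_lines(q, direction))
    counts = np.zeros((levels, max(img.shape)), dtype=int)
    for line in lines:
        line = list(line)
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            counts[line[i], j - i - 1] += 1
            i = j
    return counts


class TestRLM:
    def test_single_row_hand_count(self):
        img = np.array([[0.0, 0.0, 0.6, 0.6, 0.6]])
        m = tx.compute_rlm(img, levels=2, direction=0)
        assert m.counts[0, 1] == 1   # run of level 0, length 2
        assert m.counts[1, 2] == 1   # run of level 1, length 3
        assert m.counts.sum() == 2

    def test_constant_image_one_run_per_row(self):
        m = tx.compute_rlm(np.full((6, 6), 0.9), levels=4, direction=0)
        k = tx.quantize(np.array([[0.9]]), 4)[0, 0]
        assert m.counts[k, 5] == 6

    @pytest.mark.parametrize("direction", [0, 45, 90, 135])
    def test_pixel_conservation(self, rng, direction):
        img = rng.random((9, 13))
        m = tx.compute_rlm(img, levels=4, direction=direction)
        jj = np.arange(1, m.counts.shape[1] + 1)
        assert (m.counts * jj).sum() == img.size

    def test_checkerboard_all_runs_length_one(self):
        board = np.indices((8, 8)).sum(axis=0) % 2 * 0.9
        m = tx.compute_rlm(board, levels=2, direction=0)
        assert m.counts[:, 1:].sum() == 0
        assert m.counts.sum() == 64

    @pytest.mark.parametrize("direction", [0, 45, 90, 135])
    def test_matches_bruteforce(self, rng, direction):
        img = rng.random((12, 12))
        m = tx.compute_rlm(img, levels=8, direction=direction)
        assert np.array_equal(m.counts, brute_rlm(img, 8, direction))


class TestRLMFeatures:
    def test_all_runs_length_one(self):
        counts = np.zeros((2, 8), dtype=int)
        counts[0, 0] = 30
        counts[1, 0] = 34
        f = tx.rlm_features(tx.RLMatrix(counts, 0, 64))
        assert f["SRE"] == 1.0
        assert f["LRE"] == 1.0
        assert f["RP"] == 1.0

    def test_single_row_hand_values(self):
        m = tx.compute_rlm(np.array([[0.0, 0.0, 0.6, 0.6, 0.6]]),
                           levels=2, direction=0)
        f = tx.rlm_features(m)
        assert f["SRE"] == pytest.approx((1 / 4 + 1 / 9) / 2)
        assert f["LRE"] == pytest.approx(6.5)
        assert f["RP"] == pytest.approx(0.4)
        assert f["GLN"] == pytest.approx((1 + 1) / 2)
        assert f["RLN"] == pytest.approx((1 + 1) / 2)

    def test_matches_bruteforce_oracle(self, rng):
        img = rng.random((10, 10))
        m = tx.compute_rlm(img, levels=8, direction=45)
        f = tx.rlm_features(m)
        r = m.counts.astype(float)
        n = r.sum()
        sre = sum(r[i, j] / (j + 1) ** 2
                  for i in range(r.shape[0])
                  for j in range(r.shape[1])) / n
        assert f["SRE"] == pytest.approx(sre, abs=1e-10)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            tx.rlm_features(tx.RLMatrix(np.zeros((2, 2), int), 0, 4))


class TestSTAVector:
    def test_length_and_finiteness(self, rng):
        v = tx.sta_vector(rng.random((32, 32)))
        assert v.shape == (17,)
        assert np.isfinite(v).all()

    def test_constant_image_degenerate_values(self):
        v = tx.sta_vector(np.full((16, 16), 0.5))
        named = dict(zip(tx.STA_FEATURE_NAMES, v))
        assert named["energy"] == 1.0
        assert named["entropy"] == 0.0
        assert named["contrast"] == 0.0
        # one run per scan line; RP = total runs / (4 directions * n)
        assert named["RP"] == pytest.approx(
            np.mean([16 / 256, 16 / 256, 31 / 256, 31 / 256]))

    def test_rotation_symmetry_of_direction_average(self, rng):
        img = rng.random((16, 16))
        a = dict(zip(tx.STA_FEATURE_NAMES, tx.sta_vector(img)))
        b = dict(zip(tx.STA_FEATURE_NAMES, tx.sta_vector(np.rot90(img))))
        for key in ("SRE", "LRE", "GLN", "RLN", "RP"):
            assert a[key] == pytest.approx(b[key], abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_entropy_energy_bounds(seed):
    """entropy <= log2(#nonzero cells); energy * #nonzero >= 1."""
    img = np.random.default_rng(seed).random((8, 8))
    m = tx.compute_glcm(img, levels=8)
    f = tx.glcm_features(m)
    nnz = int((m.probs > 0).sum())
    assert f["entropy"] <= np.log2(nnz) + 1e-9
    assert f["energy"] * nnz >= 1.0 - 1e-9
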