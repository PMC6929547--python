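import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from psewave import (CoefficientPyramid, WaveletSpec, decompose2d,
                     default_threshold, denoise1d, denoise2d,
                     denoise_vector_via_2d, flatten_2d, hard_threshold,
                     reconstruct2d, soft_threshold, threshold_pyramid,
                     vector_as_2d)
from psewave.wavelet import SUPPORTED_FAMILIES

from .naive import (haar1d_level1, haar1d_level1_inverse, haar2d_level1,
                    haar2d_level1_inverse, soft)

ORTHOGONAL = tuple(f for f in SUPPORTED_FAMILIES if not f.startswith("bior"))


# --- scalar thresholding ----------------------------------------------------

@pytest.mark.parametrize("x,t,expected", [
    (2.0, 0.5, 1.5), (-0.3, 0.5, 0.0), (0.5, 0.5, 0.0), (-0.5, 0.5, 0.0),
    (1.25, 0.0, 1.25), (-3.0, 1.0, -2.0),
])
def test_soft_threshold_closed_form(x, t, expected):
    assert soft_threshold(x, t) == pytest.approx(expected, abs=1e-15)


@given(x=st.floats(-100, 100), t=st.floats(0, 50))
def test_soft_threshold_matches_piecewise_definition(x, t):
    assert soft_threshold(x, t) == pytest.approx(soft(x, t), abs=1e-12)


def test_threshold_rejects_negative_t():
    with pytest.raises(ValueError):
        soft_threshold(1.0, -0.1)
    with pytest.raises(ValueError):
        hard_threshold(1.0, -0.1)


def test_hard_threshold_keeps_or_kills():
    np.testing.assert_allclose(hard_threshold(np.array([2.0, -0.3, 0.5]), 0.5),
                               [2.0, 0.0, 0.0])


# --- default (universal) threshold ------------------------------------------

def _pyramid_from_blocks(h, v, d):
    return CoefficientPyramid(approx=np.zeros((2, 2)),
                              details=[(np.asarray(h), np.asarray(v), np.asarray(d))],
                              family="haar", shape=(4, 4))


def test_universal_threshold_hand_value():
    # diagonal details {1,-2,3,-4}; 12 detail coefficients in total
    pyr = _pyramid_from_blocks([1.0, -1.0, 2.0, -2.0], [0.5, 0.5, 0.5, 0.5],
                               [1.0, -2.0, 3.0, -4.0])
    expected = (2.5 / 0.6745) * np.sqrt(2 * np.log(12))
    assert default_threshold(pyr) == pytest.approx(expected, rel=1e-12)


def test_universal_threshold_zero_when_details_vanish():
    pyr = _pyramid_from_blocks(np.zeros(4), np.zeros(4), np.zeros(4))
    assert default_threshold(pyr) == 0.0


def test_universal_threshold_scales_homogeneously(rng):
    blocks = [rng.normal(size=4) for _ in range(3)]
    t1 = default_threshold(_pyramid_from_blocks(*blocks))
    t3 = default_threshold(_pyramid_from_blocks(*(3.0 * b for b in blocks)))
    assert t3 == pytest.approx(3.0 * t1, rel=1e-12)


# --- decomposition / reconstruction -----------------------------------------

@pytest.mark.parametrize("family", ["haar", "db4", "sym4", "bior2.2"])
def test_constant_input_has_no_detail_energy(family):
    pyr = decompose2d(np.full((8, 8), 3.7), WaveletSpec(family, 2, "given", 0.0))
    assert pyr.detail_energy() < 1e-18


def test_haar_level1_matches_block_transform_oracle(rng):
    a = rng.normal(size=(4, 4))
    pyr = decompose2d(a, WaveletSpec("haar", 1, "given", 0.0))
    A, H, V, D = haar2d_level1(a.tolist())
    np.testing.assert_allclose(pyr.approx, A, atol=1e-12)
    h, v, d = pyr.details[0]
    np.testing.assert_allclose(h, H, atol=1e-12)
    np.testing.assert_allclose(v, V, atol=1e-12)
    np.testing.assert_allclose(d, D, atol=1e-12)


def test_haar_full_denoise_matches_oracle_pipeline(rng):
    a = rng.normal(size=(4, 4))
    t = 0.3
    got = denoise2d(a, WaveletSpec("haar", 1, "given", t, "soft"))
    A, H, V, D = haar2d_level1(a.tolist())
    Hs = [[soft(x, t) for x in row] for row in H]
    Vs = [[soft(x, t) for x in row] for row in V]
    Ds = [[soft(x, t) for x in row] for row in D]
    expected = haar2d_level1_inverse(A, Hs, Vs, Ds)
    np.testing.assert_allclose(got, expected, atol=1e-12)


@pytest.mark.parametrize("family", SUPPORTED_FAMILIES)
@pytest.mark.parametrize("shape", [(4, 4), (7, 9), (16, 33)])
def test_perfect_reconstruction(rng, family, shape):
    a = rng.normal(size=shape)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pyr = decompose2d(a, WaveletSpec(family, 3, "given", 0.0))
        rec = reconstruct2d(pyr)
    assert rec.shape == a.shape
    np.testing.assert_allclose(rec, a, atol=1e-8)


def test_decompose_rejects_non_2d_input():
    with pytest.raises(ValueError, match="2-D"):
        decompose2d(np.arange(8.0), WaveletSpec("db4", 1, "given", 0.0))


def test_unsupported_family_rejected():
    with pytest.raises(ValueError, match="unsupported"):
        WaveletSpec("db42", 1)


# --- pyramid thresholding ---------------------------------------------------

def test_threshold_pyramid_elementwise_and_approx_untouched(rng):
    a = rng.normal(size=(8, 8))
    pyr = decompose2d(a, WaveletSpec("db2", 2, "given", 0.0))
    out = threshold_pyramid(pyr, 0.5, "soft")
    np.testing.assert_array_equal(out.approx, pyr.approx)
    for (h0, v0, d0), (h1, v1, d1) in zip(pyr.details, out.details):
        for before, after in ((h0, h1), (v0, v1), (d0, d1)):
            looped = np.vectorize(lambda x: soft(x, 0.5))(before)
            np.testing.assert_allclose(after, looped, atol=1e-12)
            assert np.all(np.abs(after) <= np.abs(before) + 1e-15)


def test_threshold_zero_is_identity_and_saturation_zeroes(rng):
    a = rng.normal(size=(8, 8))
    pyr = decompose2d(a, WaveletSpec("sym2", 1, "given", 0.0))
    same = threshold_pyramid(pyr, 0.0, "soft")
    np.testing.assert_array_equal(same.details[0][0], pyr.details[0][0])
    big = threshold_pyramid(pyr, 1e6, "soft")
    assert big.detail_energy() == 0.0


@pytest.mark.parametrize("family", ORTHOGONAL)
def test_soft_thresholding_never_increases_detail_energy(rng, family):
    a = rng.normal(size=(12, 10))
    pyr = decompose2d(a, WaveletSpec(family, 2, "given", 0.0))
    shrunk = threshold_pyramid(pyr, 0.4, "soft")
    assert shrunk.detail_energy() <= pyr.detail_energy()


# --- end-to-end denoising ---------------------------------------------------

@pytest.mark.parametrize("family", ["haar", "db4", "sym4", "coif1", "bior2.4"])
def test_denoise_with_zero_threshold_is_identity(rng, family):
    a = rng.normal(size=(10, 12))
    out = denoise2d(a, WaveletSpec(family, 2, "given", 0.0, "soft"))
    np.testing.assert_allclose(out, a, atol=1e-8)


def test_denoise_constant_matrix_is_fixed_point():
    a = np.full((9, 7), 2.5)
    out = denoise2d(a, WaveletSpec("db4", 2, "default", None, "soft"))
    np.testing.assert_allclose(out, a, atol=1e-10)


def test_denoise_shrinks_spike_and_detail_energy(rng):
    row = np.linspace(0, 1, 16)
    col = np.linspace(1, 2, 12)
    smooth = np.outer(col, row)
    noisy = smooth.copy()
    noisy[5, 7] += 4.0  # isolated spike
    spec = WaveletSpec("db4", 2, "default", None, "soft")
    out = denoise2d(noisy, spec)
    probe = WaveletSpec("db4", 2, "given", 0.0)
    e_in = decompose2d(noisy, probe).detail_energy()
    e_out = decompose2d(out, probe).detail_energy()
    assert e_out <= e_in
    assert abs(out[5, 7] - smooth[5, 7]) < abs(noisy[5, 7] - smooth[5, 7])


# --- 1-D path and vector reshaping ------------------------------------------

def test_denoise1d_identity_and_constant(rng):
    v = rng.normal(size=24)
    np.testing.assert_allclose(denoise1d(v, WaveletSpec("sym4", 2, "given", 0.0)), v, atol=1e-8)
    c = np.full(17, 1.3)
    np.testing.assert_allclose(denoise1d(c, WaveletSpec("db2", 2, "default")), c, atol=1e-10)


def test_denoise1d_haar_matches_hand_computation(rng):
    v = rng.normal(size=8)
    t = 0.4
    got = denoise1d(v, WaveletSpec("haar", 1, "given", t, "soft"))
    approx, detail = haar1d_level1(v.tolist())
    expected = haar1d_level1_inverse(approx, [soft(x, t) for x in detail])
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_vector_reshape_conventions():
    arr24, n24 = vector_as_2d(np.arange(24.0))
    assert arr24.shape == (4, 6) and n24 == 24
    np.testing.assert_array_equal(arr24[0], np.arange(6.0))  # row-major
    arr22, n22 = vector_as_2d(np.arange(22.0))
    assert arr22.shape == (4, 6) and n22 == 22
    # two symmetric-reflection pad cells at the tail
    assert arr22.ravel()[22] == 21.0 and arr22.ravel()[23] == 20.0
    np.testing.assert_array_equal(flatten_2d(arr22, n22), np.arange(22.0))


def test_vector_reshape_roundtrip_is_identity(rng):
    for n in (4, 6, 22, 24, 30, 37):
        v = rng.normal(size=n)
        arr, n0 = vector_as_2d(v)
        np.testing.assert_array_equal(flatten_2d(arr, n0), v)


def test_vector_reshape_rejects_short_input():
    with pytest.raises(ValueError):
        vector_as_2d(np.arange(3.0))


def test_single_vector_2d_denoise_preserves_length(rng):
    v = rng.normal(size=24)
    out = denoise_vector_via_2d(v, WaveletSpec("sym4", 2, "default", None, "soft"))
    assert out.shape == v.shape
    np.testing.assert_allclose(
        denoise_vector_via_2d(v, WaveletSpec("sym4", 2, "given", 0.0)), v, atol=1e-8)
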