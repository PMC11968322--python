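import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zernpatch.errors import DescriptorMismatchError
from zernpatch.projection import DiskImage
from zernpatch.zernike import (
    ZernikeDescriptor,
    decompose,
    radial_polynomial,
    reconstruct,
    zernike_basis,
    zernike_distance,
    zernike_indices,
)


def radial_factorial_sum(n, m, r):
    """Independent oracle: classical factorial-sum definition of R_nm."""
    total = 0.0
    for k in range((n - m) // 2 + 1):
        coeff = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)
            )
        )
        total += coeff * r ** (n - 2 * k)
    return total


def band_limited_image(coeffs, order, grid_size, alpha=0.0):
    """Evaluate sum_m w_m Re(c_nm e^{-im alpha} Z_nm) on the disk grid."""
    idx = zernike_indices(order)

    def f(r, th):
        v = np.zeros(r.shape)
        for (n, m), c in zip(idx, coeffs):
            w = 1.0 if m == 0 else 2.0
            v += w * np.real(c * np.exp(-1j * m * alpha) * zernike_basis(n, m, r, th))
        return v

    return DiskImage.from_function(f, grid_size)


def random_descriptor(rng, order=6):
    k = len(zernike_indices(order))
    coeffs = rng.normal(size=k) + 1j * rng.normal(size=k)
    return ZernikeDescriptor(order=order, coefficients=coeffs)


class TestRadialPolynomial:
    def test_base_cases(self):
        r = np.linspace(0, 1, 11)
        assert np.allclose(radial_polynomial(0, 0, r), 1.0)
        assert radial_polynomial(1, 1, 0.5) == pytest.approx(0.5)
        assert radial_polynomial(4, 0, 0.5) == pytest.approx(-0.125)

    @pytest.mark.parametrize("n", range(0, 21))
    def test_matches_factorial_sum_oracle(self, n):
        r = np.linspace(0.0, 1.0, 17)
        for m in range(n % 2, n + 1, 2):
            expected = [radial_factorial_sum(n, m, x) for x in r]
            assert np.allclose(radial_polynomial(n, m, r), expected, atol=1e-10)

    def test_invalid_indices(self):
        for n, m in [(2, 1), (1, 2), (3, -1)]:
            with pytest.raises(ValueError):
                radial_polynomial(n, m, 0.5)

    def test_stable_at_high_order(self):
        vals = radial_polynomial(40, 0, np.linspace(0, 1, 101))
        assert np.all(np.isfinite(vals))
        assert np.max(np.abs(vals)) <= 1.0 + 1e-9  # |R_n0| <= 1 on [0, 1]


def test_index_count_combinatorial():
    for order in range(0, 25):
        expected = (order // 2 + 1) * ((order + 1) // 2 + 1)
        assert len(zernike_indices(order)) == expected
        assert all(
            0 <= m <= n and (n - m) % 2 == 0 for n, m in zernike_indices(order)
        )


class TestDecompose:
    def test_constant_image(self):
        img = DiskImage.from_function(lambda r, th: np.ones_like(r), 64)
        d = decompose(img, 2)
        mods = dict(zip(d.indices, d.invariants_vector))
        assert mods[(0, 0)] == pytest.approx(1.0, abs=2 / 64)
        assert mods[(2, 0)] == pytest.approx(0.0, abs=2 / 64)
        assert mods[(2, 2)] == pytest.approx(0.0, abs=2 / 64)

    def test_linear_image_excites_only_11(self):
        img = DiskImage.from_function(lambda r, th: r * np.cos(th), 64)
        d = decompose(img, 4)
        mods = dict(zip(d.indices, d.invariants_vector))
        assert mods[(1, 1)] == pytest.approx(0.5, abs=1e-6)
        others = [v for k, v in mods.items() if k != (1, 1)]
        assert max(others) < 1e-6

    def test_zero_image_gives_zero_descriptor(self):
        img = DiskImage(
            grid_size=32, values=np.zeros((32, 32)),
            mask=np.zeros((32, 32), dtype=bool),
        )
        d = decompose(img, 8)
        assert np.all(d.coefficients == 0)

    def test_rotation_leaves_moduli_invariant(self):
        rng = np.random.default_rng(11)
        order = 20
        k = len(zernike_indices(order))
        coeffs = rng.uniform(0.5, 1.5, k) * np.exp(1j * rng.uniform(0, 2 * np.pi, k))
        base = decompose(band_limited_image(coeffs, order, 64), order)
        rot = decompose(
            band_limited_image(coeffs, order, 64, alpha=1.234), order
        )
        rel = np.abs(rot.invariants_vector - base.invariants_vector)
        rel /= base.invariants_vector
        assert rel.max() < 0.02

    def test_parseval_on_band_limited_image(self):
        rng = np.random.default_rng(12)
        order = 10
        k = len(zernike_indices(order))
        coeffs = rng.normal(size=k) + 1j * rng.normal(size=k)
        for j, (n, m) in enumerate(zernike_indices(order)):
            if m == 0:
                coeffs[j] = coeffs[j].real
        img = band_limited_image(coeffs, order, 128)
        d = decompose(img, 20)
        weights = np.array([1.0 if m == 0 else 2.0 for n, m in d.indices])
        norms = np.array([np.pi / (n + 1) for n, m in d.indices])
        parseval = np.sum(weights * norms * d.invariants_vector**2)
        discrete = np.sum(img.values[img.mask] ** 2) * img.pixel_area
        assert parseval == pytest.approx(discrete, rel=0.10)


class TestReconstruct:
    def test_constant_roundtrip(self):
        img = DiskImage.from_function(lambda r, th: np.ones_like(r), 64)
        rec = reconstruct(decompose(img, 4), 64)
        rms = np.sqrt(np.mean((rec.values[img.mask] - 1.0) ** 2))
        assert rms < 1e-6

    def test_linear_image_roundtrip(self):
        img = DiskImage.from_function(lambda r, th: r * np.cos(th), 64)
        rec = reconstruct(decompose(img, 1), 64)
        rms = np.sqrt(np.mean((rec.values[img.mask] - img.values[img.mask]) ** 2))
        assert rms < 0.05

    def test_zero_descriptor(self):
        d = ZernikeDescriptor(order=4, coefficients=np.zeros(9, dtype=complex))
        rec = reconstruct(d, 32)
        assert np.all(rec.values == 0)


class TestDistance:
    def test_identity_and_345(self):
        a = ZernikeDescriptor(order=1, coefficients=np.array([3.0, 4.0j]))
        b = ZernikeDescriptor(order=1, coefficients=np.zeros(2, dtype=complex))
        assert zernike_distance(a, a) == 0.0
        assert zernike_distance(a, b) == pytest.approx(5.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_sum(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_descriptor(rng), random_descriptor(rng)
        expected = 0.0
        for ca, cb in zip(a.coefficients, b.coefficients):
            expected += (abs(ca) - abs(cb)) ** 2
        expected = math.sqrt(expected)
        assert zernike_distance(a, b) == pytest.approx(expected, abs=1e-12)
        sq = 0.0
        for ca, cb in zip(a.coefficients, b.coefficients):
            sq += (abs(ca) ** 2 - abs(cb) ** 2) ** 2
        assert zernike_distance(a, b, "modulus_squared") == pytest.approx(
            math.sqrt(sq), abs=1e-12
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_metric_axioms(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (random_descriptor(rng) for _ in range(3))
        dab, dba = zernike_distance(a, b), zernike_distance(b, a)
        assert dab == dba
        assert zernike_distance(a, c) <= dab + zernike_distance(b, c) + 1e-12

    def test_order_mismatch(self):
        a = ZernikeDescriptor(order=1, coefficients=np.zeros(2, dtype=complex))
        b = ZernikeDescriptor(order=2, coefficients=np.zeros(4, dtype=complex))
        with pytest.raises(DescriptorMismatchError):
            zernike_distance(a, b)

    def test_truncation_is_prefix(self):
        rng = np.random.default_rng(3)
        d = random_descriptor(rng, order=8)
        t = d.truncate(4)
        assert t.order == 4
        full = dict(zip(d.indices, d.coefficients))
        assert all(full[k] == c for k, c in zip(t.indices, t.coefficients))


def test_csv_roundtrip(tmp_path):
    rng = np.random.default_rng(9)
    d = random_descriptor(rng, order=5)
    path = tmp_path / "coeffs.csv"
    d.write_csv(path)
    back = ZernikeDescriptor.read_csv(path)
    assert back.order == d.order
    assert np.allclose(back.coefficients, d.coefficients, atol=1e-9)
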