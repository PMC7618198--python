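"""Joint reconstruction operators and solver contracts (small problems)."""

import numpy as np
import pytest

from repimap.fourier import fft2c, ifft2c
from repimap.recon import (
    EchoImages,
    ReconConfig,
    combine_sos,
    compress_coils,
    hankel_adjoint,
    hankel_build,
    lowrank_project,
    sense_solve,
    solve_joint,
)
from repimap.simulate import SensitivityMaps, acquire, make_coils, make_phantom
from repimap.trajectory import design_meepi, design_repi

rng = np.random.default_rng(42)


def crandn(*shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


class TestHankel:
    def test_small_case_shape_and_multiset(self):
        """1 echo, 1 coil, 4x4 k-space, 2x2 kernel: 9 x 4 matrix whose
        entries are the input entries with window-count multiplicity."""
        x = crandn(1, 1, 4, 4)
        H = hankel_build(x, (2, 2))
        assert H.shape == (9, 4)
        counts = hankel_adjoint(np.ones_like(H), (1, 1, 4, 4), (2, 2)).real
        # brute-force window count: corner 1, edge 2, interior 4
        expected = np.outer([1, 2, 1], [1, 2, 1]).repeat(2, 0)[:4:2]  # placeholder
        exp = np.array([[1, 2, 2, 1], [2, 4, 4, 2], [2, 4, 4, 2], [1, 2, 2, 1]])
        assert np.array_equal(counts[0, 0], exp)
        vals, mult = np.unique(H.round(12), return_counts=True)
        # every k-space entry appears exactly window-count times
        for i in range(4):
            for j in range(4):
                assert np.count_nonzero(np.isclose(H, x[0, 0, i, j])) == exp[i, j]

    def test_complex_exponential_is_rank_one(self):
        k1, k2 = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        x = np.exp(2j * np.pi * (0.13 * k1 + 0.31 * k2))[None, None]
        s = np.linalg.svd(hankel_build(x, (3, 3)), compute_uv=False)
        assert s[1] / s[0] < 1e-10

    def test_duplicate_echoes_add_no_rank(self):
        x = crandn(1, 2, 8, 8)
        x2 = np.concatenate([x, x], axis=0)
        r1 = np.linalg.matrix_rank(hankel_build(x, (3, 3)))
        r2 = np.linalg.matrix_rank(hankel_build(x2, (3, 3)))
        assert r1 == r2

    def test_kernel_larger_than_kspace_raises(self):
        with pytest.raises(ValueError):
            hankel_build(crandn(1, 1, 4, 4), (5, 5))

    def test_adjoint_dot_product(self):
        """<H(x), M> == <x, H*(M)> on random inputs to 1e-10."""
        dims, kern = (2, 3, 8, 7), (3, 3)
        for _ in range(20):
            x = crandn(*dims)
            M = crandn((8 - 2) * (7 - 2), 2 * 3 * 9)
            lhs = np.vdot(M, hankel_build(x, kern))
            rhs = np.vdot(hankel_adjoint(M, dims, kern), x)
            assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_adjoint_of_build_is_windowcount_scaling(self):
        dims, kern = (1, 2, 6, 6), (3, 3)
        x = crandn(*dims)
        w = hankel_adjoint(
            hankel_build(np.ones(dims), kern), dims, kern
        ).real
        assert np.allclose(hankel_adjoint(hankel_build(x, kern), dims, kern), w * x)

    def test_zero_matrix_maps_to_zero(self):
        out = hankel_adjoint(np.zeros((16, 9)), (1, 1, 6, 6), (3, 3))
        assert np.all(out == 0)


class TestLowrankProject:
    def test_full_rank_request_is_identity(self):
        m = crandn(6, 5)
        assert np.allclose(lowrank_project(m, 5), m)

    def test_rank_one_input_fixed_point(self):
        m = np.outer(crandn(6), crandn(4))
        assert np.allclose(lowrank_project(m, 1), m)

    def test_eckart_young_error(self):
        """Truncation error^2 equals the tail singular-value energy,
        checked against an independent eigendecomposition of M^H M."""
        m = crandn(10, 8)
        r = 3
        approx = lowrank_project(m, r)
        err2 = np.linalg.norm(m - approx) ** 2
        eigvals = np.sort(np.linalg.eigvalsh(m.conj().T @ m))[::-1]
        assert err2 == pytest.approx(float(np.sum(eigvals[r:])), rel=1e-10)


@pytest.fixture(scope="module")
def scene():
    ph = make_phantom(32, 32, seed=5)
    co = make_coils(32, 32, 8, seed=6)
    return ph, co


class TestSense:

    def test_full_sampling_equals_coil_combined_ifft(self, scene):
        ph, co = scene
        tr = design_meepi(32, 1, R=1)
        ks = acquire(ph, co, None, tr, 0.0)
        s = sense_solve(ks, co, 0)
        ref = np.sum(np.conj(co.maps) * ifft2c(ks.to_grid()[0][0]), 0)
        assert np.linalg.norm(s - ref) / np.linalg.norm(ref) < 1e-8

    def test_stride2_exact_recovery(self, scene):
        ph, co = scene
        tr = design_repi(32, 2, 2, R=1)  # per-echo stride 2
        ks = acquire(ph, co, None, tr, 0.0)
        s = sense_solve(ks, co, 0, tikhonov=1e-12)
        err = np.linalg.norm(np.abs(s) - ph.magnitude) / np.linalg.norm(ph.magnitude)
        assert err < 1e-6

    def test_high_stride_residual_aliasing_with_noise(self, scene):
        """At per-echo factor 6 the smooth-coil system is ill-conditioned:
        SENSE returns a solution but with large error."""
        ph, co = scene
        # need n_pe divisible by 6
        ph36 = make_phantom(36, 36, seed=5)
        co36 = make_coils(36, 36, 8, seed=6)
        tr = design_repi(36, 3, 2, R=2)
        ks = acquire(ph36, co36, None, tr, noise_sigma=0.025, seed=0)
        s = sense_solve(ks, co36, 0)
        err = np.linalg.norm(np.abs(s) - ph36.magnitude) / np.linalg.norm(ph36.magnitude)
        assert err > 0.2  # visible residual aliasing / noise amplification


class TestCompressCoils:
    def test_unitary_when_keeping_all(self):
        ph = make_phantom(32, 32, seed=1)
        co = make_coils(32, 32, 6, seed=1)
        tr = design_meepi(32, 1)
        ks = acquire(ph, co, None, tr, 0.0)
        ks2, co2, energy = compress_coils(ks, co, 6)
        assert energy == pytest.approx(1.0, abs=1e-12)
        rec = np.sum(np.conj(co2.maps) * ifft2c(ks2.to_grid()[0][0]), 0)
        assert np.linalg.norm(np.abs(rec) - ph.magnitude) / np.linalg.norm(ph.magnitude) < 1e-8

    def test_rank_deficient_coils_compress_losslessly(self):
        ph = make_phantom(32, 32, seed=1)
        base = make_coils(32, 32, 4, seed=2).maps
        mix = np.random.default_rng(0).standard_normal((8, 4))
        maps8 = np.einsum("oc,cxy->oxy", mix, base)
        maps8 /= np.sqrt(np.sum(np.abs(maps8) ** 2, 0))
        co8 = SensitivityMaps(maps=maps8)
        ks = acquire(ph, co8, None, design_meepi(32, 1), 0.0)
        _, _, energy = compress_coils(ks, co8, 4)
        assert energy > 0.999

    def test_single_output_coil_degenerate_but_valid(self):
        ph = make_phantom(32, 32, seed=1)
        co = make_coils(32, 32, 6, seed=1)
        ks = acquire(ph, co, None, design_meepi(32, 1), 0.0)
        ks1, co1, energy = compress_coils(ks, co, 1)
        assert energy < 1.0
        assert ks1.samples.shape[1] == 1 and co1.maps.shape[0] == 1

    def test_invalid_counts(self):
        ph = make_phantom(32, 32, seed=1)
        co = make_coils(32, 32, 4, seed=1)
        ks = acquire(ph, co, None, design_meepi(32, 1), 0.0)
        with pytest.raises(ValueError):
            compress_coils(ks, co, 0)
        with pytest.raises(ValueError):
            compress_coils(ks, co, 9)


class TestSolveJoint:
    def test_full_sampling_zero_field_exact(self):
        ph = make_phantom(32, 32, seed=3)
        co = make_coils(32, 32, 4, seed=4)
        tr = design_meepi(32, 2, R=1)
        ks = acquire(ph, co, None, tr, 0.0)
        out = solve_joint(ks, co, ReconConfig(rank=20, lam=0.0, n_iterations=2, n_inner=5))
        for e in range(2):
            err = np.linalg.norm(np.abs(out.data[e]) - ph.magnitude) / np.linalg.norm(ph.magnitude)
            assert err < 1e-6

    def test_deterministic(self):
        ph = make_phantom(36, 36, seed=3)
        co = make_coils(36, 36, 4, seed=4)
        tr = design_repi(36, 3, 2, R=1)
        ks = acquire(ph, co, None, tr, noise_sigma=0.02, seed=5)
        cfg = ReconConfig(rank=20, lam=1e-3, n_iterations=3, n_inner=5)
        a = solve_joint(ks, co, cfg)
        b = solve_joint(ks, co, cfg)
        assert np.array_equal(a.data, b.data)

    def test_surrogate_monotone_within_inner_solve(self):
        """The half-quadratic surrogate is non-increasing along each
        inner conjugate-gradient solve."""
        ph = make_phantom(36, 36, seed=3)
        co = make_coils(36, 36, 4, seed=4)
        tr = design_repi(36, 3, 2, R=1)
        ks = acquire(ph, co, None, tr, noise_sigma=0.02, seed=5)
        out = solve_joint(
            ks, co, ReconConfig(rank=20, lam=1e-3, n_iterations=3, n_inner=5),
            record_surrogate=True,
        )
        for trace in out.meta["surrogate_trace"]:
            assert all(b <= a + 1e-9 * abs(a) for a, b in zip(trace, trace[1:]))

    def test_rank_exceeding_matrix_raises(self):
        ph = make_phantom(32, 32, seed=3)
        co = make_coils(32, 32, 2, seed=4)
        ks = acquire(ph, co, None, design_meepi(32, 1), 0.0)
        with pytest.raises(ValueError, match="rank"):
            solve_joint(ks, co, ReconConfig(rank=10**6, lam=1e-3, n_iterations=1))

    def test_encoding_adjoint(self):
        """A and A^H pass the dot-product test through the mask/FFT/coil chain."""
        from repimap.recon import _Encoding

        co = make_coils(16, 16, 3, seed=0)
        masks = np.zeros((2, 16), dtype=bool)
        masks[0, ::2] = True
        masks[1, 1::2] = True
        enc = _Encoding(co.maps, masks)
        for _ in range(10):
            x = crandn(2, 16, 16)
            y = crandn(2, 3, 16, 16)
            lhs = np.vdot(y, enc.forward(x))
            rhs = np.vdot(enc.adjoint(y), x)
            assert abs(lhs - rhs) / abs(lhs) < 1e-10


class TestCombineSos:
    def test_identical_echoes_scale_sqrt_n(self):
        m = crandn(24, 24)
        stack = np.stack([m, m, m])
        assert np.allclose(combine_sos(stack), np.sqrt(3) * np.abs(m))

    def test_single_echo_is_modulus(self):
        m = crandn(8, 8)[None]
        assert np.allclose(combine_sos(m), np.abs(m[0]))

    def test_phase_invariance(self):
        m = crandn(16, 16)
        stack = np.stack([m, m * np.exp(0.7j), m * np.exp(-2.1j)])
        ref = np.stack([m, m, m])
        assert np.allclose(combine_sos(stack), combine_sos(ref))
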