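"""Conjugate-gradient brightness reconstruction."""

import numpy as np
import pytest

from illusim import encoding, filling_in, pipeline
from illusim.encoding import ChannelResponseSet
from illusim.filling_in import SolverConfig, objective, reconstruct, reconstruct_single_channel
from illusim.stimuli import LuminanceImage


def _encode(img, banks):
    return [encoding.filter_image(LuminanceImage(pixels=img), b) for b in banks]


def _zero_responses(banks, shape):
    return [
        ChannelResponseSet(
            responses={k.orientation: np.zeros(shape) for k in b.odd_kernels()}, channel=b.channel
        )
        for b in banks
    ]


class TestObjective:
    def test_zero_everywhere(self, small_banks):
        rs = _zero_responses(small_banks, (24, 24))
        assert objective(np.zeros((24, 24)), rs, small_banks) == 0.0

    def test_zero_image_gives_response_norm(self, small_banks, rng):
        """At z = 0 the objective is the squared norm of the responses (over
        their mirror-extended support)."""
        from illusim._conv import sym_pad

        shape = (24, 24)
        rs = [
            ChannelResponseSet(
                responses={k.orientation: rng.standard_normal(shape) for k in b.odd_kernels()},
                channel=b.channel,
            )
            for b in small_banks
        ]
        expected = 0.0
        for s, bank in zip(rs, small_banks):
            p = bank.kernels[0].weights.shape[0] // 2
            expected += sum(float((sym_pad(r, (2 * p, 2 * p)) ** 2).sum()) for r in s.responses.values())
        assert objective(np.zeros(shape), rs, small_banks) == pytest.approx(expected)

    def test_quadratic_homogeneity(self, small_banks, rng):
        z = rng.standard_normal((20, 20))
        rs = _zero_responses(small_banks, z.shape)
        e1 = objective(z, rs, small_banks, mu=0.01)
        e2 = objective(2 * z, rs, small_banks, mu=0.01)
        assert e2 == pytest.approx(4 * e1, rel=1e-10)

    def test_shape_mismatch_rejected(self, small_banks, rng):
        rs = _zero_responses(small_banks, (24, 24))
        with pytest.raises(ValueError, match="shape"):
            objective(np.zeros((16, 16)), rs, small_banks)


class TestReconstruct:
    def test_zero_responses_give_zero_map(self, small_banks):
        rs = _zero_responses(small_banks, (24, 24))
        out = reconstruct(rs, small_banks, SolverConfig(max_iter=50))
        assert np.abs(out.values).max() < 1e-12

    def test_step_edge_control_reconstruction(self, small_banks):
        """Unmodified encoding of a step is inverted back to the step
        (mean-removed correlation >= 0.95): the sanity oracle for the
        inverse problem."""
        img = np.full((64, 64), -0.25)
        img[:, 32:] = 0.25
        rs = _encode(img, small_banks)
        out = reconstruct(rs, small_banks, SolverConfig(max_iter=200, tol=1e-6))
        z = out.values - out.values.mean()
        ref = img - img.mean()
        corr = float((z * ref).sum() / np.sqrt((z**2).sum() * (ref**2).sum()))
        assert corr >= 0.95

    def test_objective_trace_non_increasing(self, small_banks):
        img = np.full((48, 48), -0.2)
        img[:, 24:] = 0.3
        rs = _encode(img, small_banks)
        out = reconstruct(rs, small_banks, SolverConfig(max_iter=60))
        trace = np.array(out.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9 * max(1.0, trace[0]))

    def test_trace_matches_objective_function(self, small_banks):
        """The incrementally tracked objective agrees with a direct evaluation
        at the solution."""
        img = np.full((32, 32), 0.1)
        img[:, 16:] = -0.1
        rs = _encode(img, small_banks)
        out = reconstruct(rs, small_banks, SolverConfig(max_iter=80))
        direct = objective(out.values, rs, small_banks, mu=0.01)
        assert out.objective_trace[-1] == pytest.approx(direct, rel=1e-6)

    def test_init_independence(self, small_banks):
        """The objective is strictly convex, so zeros- and random-init runs
        converge to the same minimizer."""
        img = np.full((40, 40), -0.15)
        img[10:30, 10:30] = 0.25
        rs = _encode(img, small_banks)
        tol = 1e-6
        a = reconstruct(rs, small_banks, SolverConfig(max_iter=400, tol=tol, init="zeros"))
        b = reconstruct(rs, small_banks, SolverConfig(max_iter=400, tol=tol, init="random", seed=9))
        rel = np.linalg.norm(a.values - b.values) / np.linalg.norm(a.values)
        assert rel <= 10 * tol * 1e3  # both at the unique optimum within solver accuracy

    def test_gradient_check(self, small_banks, rng):
        """The normal-equations operator is the exact half-gradient of the
        objective (finite differences, random 16x16 instances)."""
        shape = (16, 16)
        rs = [
            ChannelResponseSet(
                responses={k.orientation: 0.1 * rng.standard_normal(shape) for k in b.odd_kernels()},
                channel=b.channel,
            )
            for b in small_banks
        ]
        z = rng.standard_normal(shape) * 0.1
        mu = 0.01
        A = filling_in._NormalOperator(small_banks, mu)
        b_vec = filling_in._rhs(rs, small_banks)
        grad = 2 * (A(z) - b_vec)  # dE/dz
        eps = 1e-6
        for _ in range(5):
            i, j = rng.integers(0, shape[0]), rng.integers(0, shape[1])
            zp = z.copy()
            zp[i, j] += eps
            zm = z.copy()
            zm[i, j] -= eps
            fd = (objective(zp, rs, small_banks, mu) - objective(zm, rs, small_banks, mu)) / (2 * eps)
            assert fd == pytest.approx(grad[i, j], rel=1e-5, abs=1e-8)

    def test_channel_mismatch_rejected(self, small_banks):
        rs = _zero_responses(small_banks, (24, 24))
        with pytest.raises(ValueError, match="channel"):
            reconstruct([rs[1], rs[0]], small_banks)


class TestSingleChannel:
    def test_zero_responses(self, small_banks):
        rs = _zero_responses(small_banks, (24, 24))
        out = reconstruct_single_channel(rs[1], small_banks[1], SolverConfig(max_iter=30))
        assert np.abs(out.values).max() < 1e-12

    @staticmethod
    def _staircase(shape=(64, 64), n=4):
        levels = np.linspace(-0.4, 0.4, n)
        img = np.zeros(shape)
        w = shape[1] // n
        for i, lv in enumerate(levels):
            img[:, i * w : (i + 1) * w] = lv
        return img

    def test_cl_channel_dominates_early_reconstruction(self, default_banks):
        """At 10 iterations, the contrast-luminance channel alone recovers the
        staircase better than the contrast-only channel alone."""
        img = self._staircase()
        bank_co, bank_cl = default_banks
        rs_co = encoding.filter_image(LuminanceImage(pixels=img), bank_co)
        rs_cl = encoding.filter_image(LuminanceImage(pixels=img), bank_cl)
        cfg = SolverConfig(max_iter=10, tol=1e-12)
        z_cl = reconstruct_single_channel(rs_cl, bank_cl, cfg).values
        z_co = reconstruct_single_channel(rs_co, bank_co, cfg).values
        res_cl = np.linalg.norm(z_cl - img)
        res_co = np.linalg.norm(z_co - img)
        assert res_cl < res_co

    def test_co_channel_suppresses_high_frequency_artifacts(self, default_banks):
        """A CL-only full run shows more high-frequency energy near edges than
        the dual-channel run (undersampling artifacts)."""
        from scipy import ndimage

        img = self._staircase()
        bank_co, bank_cl = default_banks
        rs_co = encoding.filter_image(LuminanceImage(pixels=img), bank_co)
        rs_cl = encoding.filter_image(LuminanceImage(pixels=img), bank_cl)
        cfg = SolverConfig(max_iter=200, tol=1e-6)
        z_cl = reconstruct_single_channel(rs_cl, bank_cl, cfg).values
        z_both = reconstruct([rs_co, rs_cl], [bank_co, bank_cl], cfg).values

        def highpass_energy(z):
            return float(((z - ndimage.gaussian_filter(z, 2.0)) ** 2).sum())

        assert highpass_energy(z_cl) > highpass_energy(z_both)


def test_solver_config_validation():
    with pytest.raises(ValueError):
        SolverConfig(mu=-1)
    with pytest.raises(ValueError):
        SolverConfig(max_iter=0)
    with pytest.raises(ValueError):
        SolverConfig(init="midway")
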