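import numpy as np
import pytest
from hypothesis import given, strategies as st
from statsmodels.tools.numdiff import approx_fprime

from oracles import all_histories, unrolled_pradel_loglik

from paleocmr.formulas import ModelSpec, ParameterStructure, build_design
from paleocmr.likelihood import (
    _tails,
    first_last,
    pradel_conditional_loglik,
    pradel_loglik,
    total_conditional_loglik,
    total_loglik,
    total_loglik_grad,
)
from paleocmr.simulate import SimConfig, simulate_histories
from paleocmr.timescale import make_toy_table


def _rand_params(rng, n, T, lo=0.05, hi=0.95):
    return (
        rng.uniform(lo, hi, (n, T - 1)),
        rng.uniform(lo, hi, (n, T - 1)),
        rng.uniform(lo, hi, (n, T)),
    )


class TestKnownValues:
    def test_complete_history_certain_detection(self):
        """T=3, history 111, p=1, phi=0.5 each: probability 0.25."""
        ll = pradel_loglik(
            np.array([0.5, 0.5]),
            np.array([0.3, 0.7]),
            np.array([1.0, 1.0, 1.0]),
            np.array([1, 1, 1]),
        )
        assert ll[0] == pytest.approx(np.log(0.25), abs=1e-12)

    def test_single_missed_detection(self):
        """T=3, history 101, p=(1,.5,1), phi=(.8,.8): 0.8*0.5*0.8."""
        ll = pradel_loglik(
            np.array([0.8, 0.8]),
            np.array([0.3, 0.7]),
            np.array([1.0, 0.5, 1.0]),
            np.array([1, 0, 1]),
        )
        assert ll[0] == pytest.approx(np.log(0.32), abs=1e-12)

    def test_gamma_irrelevant_when_first_detection_at_occasion_one(self):
        rng = np.random.default_rng(1)
        phi, g1, p = _rand_params(rng, 1, 4)
        g2 = rng.uniform(0.05, 0.95, g1.shape)
        w = np.array([[1, 0, 1, 0]])
        assert pradel_loglik(phi, g1, p, w)[0] == pytest.approx(
            pradel_loglik(phi, g2, p, w)[0], abs=1e-14
        )


class TestUnrolledOracle:
    @pytest.mark.parametrize("T", [2, 3, 4, 5, 6])
    def test_every_history_matches_latent_enumeration(self, T):
        """Recursive tails equal the explicit sum over all latent
        (origination, extinction) occasion pairs, for every nonzero
        history, to 1e-12."""
        rng = np.random.default_rng(T)
        for w in all_histories(T):
            phi, gamma, p = _rand_params(rng, 1, T)
            got = pradel_loglik(phi, gamma, p, w[None, :])[0]
            want = unrolled_pradel_loglik(phi[0], gamma[0], p[0], w)
            assert got == pytest.approx(want, abs=1e-12)

    def test_spec_example_shape(self):
        """T=5 history 00110: the oracle enumerates <= 25 latent pairs."""
        w = np.array([0, 0, 1, 1, 0])
        f, l = 2, 3
        assert (f + 1) * (5 - l) <= 25


class TestProperties:
    @given(st.integers(0, 1000))
    def test_loglik_nonpositive_and_tails_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(2, 9))
        n = 5
        phi, gamma, p = _rand_params(rng, n, T, 0.01, 0.99)
        W = (rng.random((n, T)) < 0.5).astype(np.int8)
        W[:, rng.integers(0, T)] = 1  # at least one detection
        ll = pradel_loglik(phi, gamma, p, W)
        assert np.all(ll <= 1e-12)
        xi, chi = _tails(phi, gamma, p)
        assert np.all((xi > 0) & (xi <= 1))
        assert np.all((chi > 0) & (chi <= 1))

    def test_total_additivity_and_exchangeability(self, small_histories):
        hist, _, _ = small_histories
        spec = ModelSpec(
            ParameterStructure("phi", ("time", "size")),
            ParameterStructure("gamma", ("time",)),
            ParameterStructure("p", ("time", "size")),
        )
        d = build_design(spec, hist)
        rng = np.random.default_rng(3)
        beta = rng.normal(0, 0.3, d.k)
        base = total_loglik(d, beta, hist.detections)

        # duplicated data: exactly twice the log-likelihood
        import dataclasses

        dbl = dataclasses.replace(
            hist,
            genera=hist.genera * 2,
            detections=np.vstack([hist.detections] * 2),
            z_size=np.concatenate([hist.z_size] * 2),
            z_range=np.vstack([hist.z_range] * 2),
        )
        d2 = build_design(spec, dbl)
        assert total_loglik(d2, beta, dbl.detections) == pytest.approx(
            2 * base, rel=1e-12
        )

        # permuted order: identical
        perm = rng.permutation(hist.n_genera)
        shuf = dataclasses.replace(
            hist,
            genera=[hist.genera[i] for i in perm],
            detections=hist.detections[perm],
            z_size=hist.z_size[perm],
            z_range=hist.z_range[perm],
        )
        d3 = build_design(spec, shuf)
        assert total_loglik(d3, beta, shuf.detections) == pytest.approx(
            base, rel=1e-12
        )

    @pytest.mark.parametrize("T", [2, 3, 4, 5])
    def test_conditional_likelihood_normalizes_over_histories(self, T):
        """The conditional per-history probabilities sum to exactly 1 over
        all observable (nonzero) histories — the fitting objective is a
        proper distribution, which is what makes seniority estimable."""
        rng = np.random.default_rng(40 + T)
        phi = rng.uniform(0.1, 0.9, (1, T - 1))
        gamma = rng.uniform(0.1, 0.9, (1, T - 1))
        p = rng.uniform(0.1, 0.9, (1, T))
        total = sum(
            np.exp(pradel_conditional_loglik(phi, gamma, p, w[None, :])[0])
            for w in all_histories(T)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_first_last_requires_a_detection(self):
        with pytest.raises(ValueError, match="at least one detection"):
            first_last(np.array([[0, 0, 0]]))


class TestGradient:
    def test_analytic_gradient_matches_numerical(self, small_histories):
        """The hand-derived backpropagation through the xi/chi recursions
        agrees with central finite differences of the log-likelihood."""
        hist, _, _ = small_histories
        spec = ModelSpec(
            ParameterStructure("phi", ("time", "size*ME", "range")),
            ParameterStructure("gamma", ("time", "size*Rec")),
            ParameterStructure("p", ("time", "size")),
        )
        d = build_design(spec, hist)
        rng = np.random.default_rng(7)
        for conditional, fun in (
            (True, total_conditional_loglik),
            (False, total_loglik),
        ):
            beta = rng.normal(0, 0.4, d.k)
            val, g = total_loglik_grad(
                d, beta, hist.detections, conditional=conditional
            )
            assert val == pytest.approx(fun(d, beta, hist.detections), rel=1e-12)
            g_num = approx_fprime(
                beta,
                lambda b: fun(d, b, hist.detections),
                centered=True,
            )
            assert np.max(np.abs(g - g_num)) / (1 + np.max(np.abs(g_num))) < 1e-6
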