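import numpy as np
import pytest

from paleocmr.fit import FitResult
from paleocmr.formulas import ModelSpec, ParameterStructure
from paleocmr.selection import (
    ModelTable,
    aicc,
    akaike_weights,
    average_coefficients,
    rank_models,
    regime_support_summary,
)


def _fake_fit(phi_terms, loglik, beta_by_term, se=0.1, n=200, gamma_terms=("time",)):
    """A synthetic converged FitResult with the given phi covariates.
    ``gamma_terms`` only disambiguates the model id when two fakes share
    a phi structure."""
    spec = ModelSpec(
        ParameterStructure("phi", tuple(phi_terms)),
        ParameterStructure("gamma", tuple(gamma_terms)),
        ParameterStructure("p", ("time", "size")),
    )
    T = 5
    cols = [("phi", f"t{j+1}") for j in range(T - 1)]
    cols += [("phi", t) for t in beta_by_term]
    cols += [("gamma", f"t{j+1}") for j in range(T - 1)]
    cols += [("p", f"t{j+1}") for j in range(T)] + [("p", "size")]
    k = len(cols)
    beta = np.zeros(k)
    for i, t in enumerate(beta_by_term):
        beta[T - 1 + i] = beta_by_term[t]
    vcov = np.eye(k) * se**2
    return FitResult(
        spec=spec,
        beta=beta,
        loglik=loglik,
        k=k,
        n_histories=n,
        converged=True,
        se=np.full(k, se),
        vcov=vcov,
        col_names=cols,
    )


class TestAICc:
    def test_worked_arithmetic(self):
        assert aicc(-100.0, 5, 50) == pytest.approx(211.363636, abs=1e-4)

    def test_delta_two_weights(self):
        w = akaike_weights(np.array([0.0, 2.0]))
        assert w[0] == pytest.approx(0.73106, abs=1e-4)
        assert w[1] == pytest.approx(0.26894, abs=1e-4)

    def test_small_sample_guard(self):
        assert aicc(-10.0, 10, 11) == np.inf

    def test_ranking_invariant_to_loglik_shift(self):
        f1 = _fake_fit(("time",), -100.0, {})
        f2 = _fake_fit(("time", "size"), -98.0, {"size": 0.2})
        t1 = rank_models([f1, f2])
        g1 = _fake_fit(("time",), -100.0 + 7.0, {})
        g2 = _fake_fit(("time", "size"), -98.0 + 7.0, {"size": 0.2})
        t2 = rank_models([g1, g2])
        assert list(t1.frame["model_id"]) == list(t2.frame["model_id"])
        assert np.allclose(t1.frame["weight"], t2.frame["weight"])
        assert np.allclose(t1.frame["dAICc"], t2.frame["dAICc"])

    def test_weights_sum_to_one_and_rank1_delta_zero(self):
        fits = [
            _fake_fit(("time",), -100.0, {}),
            _fake_fit(("time", "size"), -97.0, {"size": 0.1}),
            _fake_fit(("time", "range"), -99.0, {"range": -0.3}),
        ]
        t = rank_models(fits)
        assert t.frame["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert t.frame["dAICc"].iloc[0] == 0.0

    def test_nonconverged_excluded(self):
        good = _fake_fit(("time",), -100.0, {})
        bad = _fake_fit(("time", "size"), -90.0, {"size": 0.5})
        bad.converged = False
        t = rank_models([good, bad])
        assert len(t) == 1

    def test_ess_rules(self, small_histories):
        hist, _, _ = small_histories
        f = _fake_fit(("time",), -100.0, {}, n=hist.n_genera)
        t_hist = rank_models([f], ess_rule="histories")
        t_det = rank_models([f], ess_rule="detections", histories=hist)
        t_cell = rank_models([f], ess_rule="cells", histories=hist)
        assert t_hist.ess == hist.n_genera
        assert t_det.ess == int(hist.detections.sum())
        assert t_cell.ess == hist.detections.size
        assert t_det.ess > t_hist.ess


class TestAveraging:
    def test_single_qualifying_model_passes_through(self):
        f = _fake_fit(("time", "size"), -100.0, {"size": 0.25}, se=0.1)
        t = rank_models([f])
        est = {(e.trait, e.regime): e for e in average_coefficients(t)}
        e = est[("size", "background")]
        # reported on the log-odds-of-extinction scale (negated survival)
        assert e.coefficient == pytest.approx(-0.25)
        assert e.se == pytest.approx(0.1)

    def test_weighted_mean_with_zero_substitution(self):
        # engineer logliks so renormalized weights are 0.6 / 0.4
        delta = 2.0 * np.log(0.6 / 0.4)
        f1 = _fake_fit(("time", "size"), -100.0, {"size": 0.10}, se=0.0)
        f2 = _fake_fit(
            ("time", "size"),
            -100.0 - delta / 2.0,
            {"size": -0.05},
            se=0.0,
            gamma_terms=("time", "size"),
        )
        t = rank_models([f1, f2])
        w = t.frame["weight"].to_numpy()
        assert w[0] / w.sum() == pytest.approx(0.6, abs=1e-9)
        est = {(e.trait, e.regime): e for e in average_coefficients(t)}
        # extinction scale: 0.6*(-0.10) + 0.4*(+0.05) = -0.04
        assert est[("size", "background")].coefficient == pytest.approx(
            -0.04, abs=1e-9
        )

    def test_mass_extinction_adds_interaction(self):
        f = _fake_fit(
            ("time", "size*ME"), -100.0, {"size": 0.3, "size:ME": -0.2}, se=0.1
        )
        t = rank_models([f])
        est = {(e.trait, e.regime): e for e in average_coefficients(t)}
        bg = est[("size", "background")].coefficient
        me = est[("size", "mass_extinction")].coefficient
        assert bg == pytest.approx(-0.3)
        assert me == pytest.approx(-0.1)  # -(0.3 - 0.2)

    def test_burnham_anderson_unconditional_se(self):
        delta = 2.0 * np.log(0.6 / 0.4)
        f1 = _fake_fit(("time", "size"), -100.0, {"size": 0.10}, se=0.05)
        f2 = _fake_fit(
            ("time", "size"),
            -100.0 - delta / 2.0,
            {"size": -0.05},
            se=0.02,
            gamma_terms=("time", "size"),
        )
        t = rank_models([f1, f2])
        est = {(e.trait, e.regime): e for e in average_coefficients(t)}
        th = np.array([-0.10, 0.05])
        se = np.array([0.05, 0.02])
        w = np.array([0.6, 0.4])
        bar = (w * th).sum()
        want = np.sqrt((w * (se**2 + (th - bar) ** 2)).sum())
        assert est[("size", "background")].se == pytest.approx(want, abs=1e-9)

    def test_min_weight_zero_equals_full_set_average(self):
        fits = [
            _fake_fit(("time", "size"), -100.0, {"size": 0.2}, se=0.1),
            _fake_fit(("time",), -100.5, {}, se=0.1),
            _fake_fit(("time", "size*ME"), -101.0, {"size": 0.1, "size:ME": 0.3}, se=0.1),
        ]
        t = rank_models(fits)
        full = average_coefficients(t, min_weight=0.0)
        theta_by_id = {
            fits[0].model_id: -0.2,
            fits[1].model_id: 0.0,
            fits[2].model_id: -0.1,
        }
        w = t.frame["weight"].to_numpy()
        want = float(
            sum(wi * theta_by_id[m] for wi, m in zip(w, t.frame["model_id"]))
        )
        got = {(e.trait, e.regime): e for e in full}[("size", "background")]
        assert got.coefficient == pytest.approx(want, abs=1e-9)

    def test_no_qualifying_model_raises(self):
        f = _fake_fit(("time", "size"), -100.0, {"size": 0.2}, se=0.1)
        t = rank_models([f])
        with pytest.raises(ValueError):
            average_coefficients(t, min_weight=1.1)


class TestRegimeSupport:
    def test_classification_and_partition(self):
        fits = [
            _fake_fit(("time", "range*ME"), -95.0, {"range": 0.5, "range:ME": -0.5}),
            _fake_fit(("time", "range"), -99.0, {"range": 0.5}),
        ]
        t = rank_models(fits)
        s = regime_support_summary(t)
        assert s["best_model_class"] == "two-regime"
        assert s["weight_single_regime"] + s["weight_two_regime"] == pytest.approx(
            1.0, abs=1e-9
        )

    def test_single_regime_best(self):
        fits = [
            _fake_fit(("time", "range"), -95.0, {"range": 0.5}),
            _fake_fit(("time", "range*ME"), -99.0, {"range": 0.5, "range:ME": 0.0}),
        ]
        s = regime_support_summary(rank_models(fits))
        assert s["best_model_class"] == "single-regime"
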