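import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

import lcdr
from lcdr.em import (
    MixtureSpec,
    e_step,
    fit_lcdr,
    init_weights_naive_cdf,
    init_weights_random,
    m_step,
    mixture_logpdf,
)
from lcdr.families import GAUSSIAN
from lcdr.gamlss import ModelSpec, SplineTerm, fit_weighted

SPEC1 = lcdr.scenario_model_spec()


def two_component_spec(**kw):
    return MixtureSpec(components=(SPEC1, SPEC1), **kw)


# ---------------------------------------------------------------------------
# mixture_logpdf
# ---------------------------------------------------------------------------


def test_mixture_logpdf_identical_components():
    ld = np.tile(np.array([[-1.3], [-0.4]]), (1, 2))
    rows, total = mixture_logpdf([0.25, 0.75], ld)
    np.testing.assert_allclose(rows, [-1.3, -0.4], atol=1e-12)
    assert total == pytest.approx(-1.7)


def test_mixture_logpdf_degenerate_weight_limit():
    ld = np.array([[-2.0, -50.0], [-1.0, -3.0]])
    rows, _ = mixture_logpdf([1 - 1e-16, 1e-16], ld)
    np.testing.assert_allclose(rows, ld[:, 0], atol=1e-10)


def test_mixture_logpdf_matches_brute_force():
    rng = np.random.default_rng(0)
    ld = rng.normal(-3, 2, size=(20, 3))
    alpha = np.array([0.5, 0.3, 0.2])
    rows, total = mixture_logpdf(alpha, ld)
    brute = np.log(np.sum(alpha[None, :] * np.exp(ld.astype(np.longdouble)), axis=1))
    np.testing.assert_allclose(rows, np.asarray(brute, dtype=float), rtol=1e-12)
    assert total == pytest.approx(float(brute.sum()))


def test_mixture_logpdf_rejects_bad_simplex():
    with pytest.raises(ValueError):
        mixture_logpdf([0.7, 0.7], np.zeros((3, 2)))


# ---------------------------------------------------------------------------
# e_step
# ---------------------------------------------------------------------------


def test_e_step_arithmetic_and_normalization():
    # alpha=(0.7,0.3), f=(0.2,0.1): w1 = 0.14/0.17
    ld = np.log(np.array([[0.2, 0.1]]))
    w = e_step([0.7, 0.3], ld)
    assert w[0, 0] == pytest.approx(0.14 / 0.17, abs=1e-12)
    # equal densities, equal weights
    w2 = e_step([0.5, 0.5], np.full((4, 2), -3.0))
    np.testing.assert_allclose(w2, 0.5, atol=1e-12)
    # arbitrary inputs still normalize
    rng = np.random.default_rng(1)
    w3 = e_step([0.2, 0.5, 0.3], rng.normal(-5, 3, (50, 3)))
    np.testing.assert_allclose(w3.sum(axis=1), 1.0, atol=1e-12)
    assert np.all((w3 >= 0) & (w3 <= 1))


def test_e_step_underflow_rows_become_uniform():
    ld = np.array([[-1.0, -2.0], [-np.inf, -np.inf]])
    w = e_step([0.5, 0.5], ld)
    np.testing.assert_allclose(w[1], [0.5, 0.5])


# ---------------------------------------------------------------------------
# m_step
# ---------------------------------------------------------------------------


def _toy_two_cluster(n=120, seed=2):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, n)
    label = rng.uniform(size=n) < 0.5
    y = np.where(label, rng.normal(0 + x, 1.0), rng.normal(10 - x, 2.0))
    return pd.DataFrame({"x": x, "y": y, "label": np.where(label, 1, 2)})


def test_m_step_with_true_labels_matches_separate_fits():
    data = _toy_two_cluster()
    w = np.column_stack([(data.label == 1).astype(float), (data.label == 2).astype(float)])
    fits, alpha = m_step(data, w, two_component_spec())
    assert alpha[0] == pytest.approx((data.label == 1).mean())
    from lcdr.gamlss import predict_params

    for m, lab in enumerate((1, 2)):
        cluster = data[data.label == lab].reset_index(drop=True)
        solo = fit_weighted(SPEC1, cluster)
        # same model up to basis parameterization: predictions must agree
        mu_mix, sigma_mix = predict_params(fits[m], cluster)
        mu_solo, sigma_solo = predict_params(solo, cluster)
        np.testing.assert_allclose(mu_mix, mu_solo, atol=5e-3)
        np.testing.assert_allclose(sigma_mix, sigma_solo, rtol=5e-3)
        assert fits[m].loglik == pytest.approx(solo.loglik, abs=1e-3)


def test_m_step_symmetric_weights_give_identical_components():
    data = _toy_two_cluster()
    w = np.full((len(data), 2), 0.5)
    fits, alpha = m_step(data, w, two_component_spec())
    np.testing.assert_allclose(alpha, [0.5, 0.5])
    np.testing.assert_allclose(fits[0].beta_mu, fits[1].beta_mu, atol=1e-8)


def test_m_step_collapse_detection():
    data = _toy_two_cluster()
    n = len(data)
    w = np.column_stack([np.full(n, 1 - 1e-12), np.full(n, 1e-12)])
    with pytest.raises(lcdr.DegenerateComponentError):
        m_step(data, w, two_component_spec())


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def test_naive_cdf_init_center_and_tails():
    scen = lcdr.Scenario(c=20, alpha1=0.7, n=400, seed=8)
    data = lcdr.simulate_dataset(scen)
    spec = two_component_spec()
    w0, naive = init_weights_naive_cdf(data, spec, mode="upper")
    # at the naive conditional median the weights are (0.5, 0.5)
    from lcdr.gamlss import predict_params

    mu, sigma = predict_params(naive, data)
    med_idx = int(np.argmin(np.abs(data.y.to_numpy() - mu)))
    np.testing.assert_allclose(w0[med_idx], [0.5, 0.5], atol=0.02)
    # a far-upper-tail observation goes (almost) entirely to component 2
    probe = data.copy()
    probe.loc[0, "y"] = mu[0] + 40 * sigma[0]
    w_tail, _ = init_weights_naive_cdf(probe, spec, mode="upper")
    assert w_tail[0, 1] > 1 - 1e-6
    # contaminated rows start with more component-2 weight than healthy rows
    lab = data.label.to_numpy()
    assert w0[lab == 2, 1].mean() > w0[lab == 1, 1].mean()


def test_naive_cdf_init_modes_and_m_restriction():
    scen = lcdr.Scenario(c=10, alpha1=0.7, n=200, seed=1)
    data = lcdr.simulate_dataset(scen)
    spec = two_component_spec()
    w_up, _ = init_weights_naive_cdf(data, spec, mode="upper")
    w_lo, _ = init_weights_naive_cdf(data, spec, mode="lower")
    np.testing.assert_allclose(w_up[:, 0], w_lo[:, 1], atol=1e-10)
    w_two, _ = init_weights_naive_cdf(data, spec, mode="two-sided")
    assert np.all(w_two >= 0)
    three = MixtureSpec(components=(SPEC1, SPEC1, SPEC1))
    with pytest.raises(ValueError, match="M=2"):
        init_weights_naive_cdf(data, three)


def test_random_init_reproducible_one_hot():
    w1 = init_weights_random(500, 2, seed=123)
    w2 = init_weights_random(500, 2, seed=123)
    np.testing.assert_array_equal(w1, w2)
    assert np.all(w1.sum(axis=1) == 1.0)
    assert set(np.unique(w1)) == {0.0, 1.0}
    # column means near 1/M (binomial 3-sigma)
    assert abs(w1[:, 0].mean() - 0.5) < 3 * 0.5 / np.sqrt(500)


# ---------------------------------------------------------------------------
# fit_lcdr
# ---------------------------------------------------------------------------


def test_em_monotone_loglik_and_invariants(scenario_fit):
    _, _, fit = scenario_fit
    trace = np.array(fit.loglik_trace)
    assert np.all(np.diff(trace) >= -1e-8)
    assert fit.alpha.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(fit.alpha > 0)
    np.testing.assert_allclose(fit.weights.sum(axis=1), 1.0, atol=1e-12)


def test_alpha_recovery_well_separated():
    """Mean mixture-weight estimate over a handful of replicates of the
    well-separated scenario recovers the true healthy proportion."""
    spec = two_component_spec()
    alphas = []
    for seed in range(5):
        scen = lcdr.Scenario(c=20, alpha1=0.7, n=1000, seed=seed)
        fit = fit_lcdr(lcdr.simulate_dataset(scen), spec)
        assert fit.status in ("converged", "max-iter")
        alphas.append(fit.alpha[0])
    assert np.mean(alphas) == pytest.approx(0.7, abs=0.05)


def test_epsilon_inf_stops_after_first_iteration():
    scen = lcdr.Scenario(c=20, alpha1=0.7, n=300, seed=5)
    data = lcdr.simulate_dataset(scen)
    fit = fit_lcdr(data, two_component_spec(epsilon=float("inf")))
    assert fit.status == "converged"
    assert fit.n_iter == 1


def test_label_symmetry_under_mirrored_initial_weights():
    scen = lcdr.Scenario(c=20, alpha1=0.7, n=300, seed=6)
    data = lcdr.simulate_dataset(scen)
    spec = two_component_spec(init="user")
    w0, _ = init_weights_naive_cdf(data, two_component_spec(), mode="upper")
    f1 = fit_lcdr(data, spec, init_weights=w0)
    f2 = fit_lcdr(data, spec, init_weights=w0[:, ::-1])
    np.testing.assert_allclose(f1.alpha, f2.alpha[::-1], atol=1e-6)
    np.testing.assert_allclose(
        f1.components[0].beta_mu, f2.components[1].beta_mu, atol=1e-4
    )


def test_one_component_data_never_breaks_monotonicity():
    """Fitting M=2 to single-population data either converges (overlapping
    components) or fails by collapse; the trace stays monotone regardless."""
    rng = np.random.default_rng(17)
    data = pd.DataFrame({"x": rng.uniform(0, 1, 300)})
    data["y"] = rng.normal(data.x, 1.0)
    fit = fit_lcdr(data, two_component_spec(init="random", seed=4))
    assert fit.status in ("converged", "max-iter", "failed")
    trace = np.array(fit.loglik_trace)
    if len(trace) > 1:
        assert np.all(np.diff(trace) >= -1e-8)


def test_extreme_initial_weights_fail_cleanly():
    data = _toy_two_cluster(n=100)
    w0 = np.column_stack([np.ones(100), np.zeros(100)])
    fit = fit_lcdr(data, two_component_spec(init="user"), init_weights=w0)
    assert fit.status == "failed"
    assert "collapsed" in fit.diagnostics["failure"]


def test_malformed_input_raises():
    data = _toy_two_cluster(n=50)
    with pytest.raises(ValueError):
        fit_lcdr(data, two_component_spec(init="user"))  # no weights supplied
    with pytest.raises(ValueError):
        MixtureSpec(components=(SPEC1,))
    with pytest.raises(ValueError):
        two_component_spec(epsilon=0.0)
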