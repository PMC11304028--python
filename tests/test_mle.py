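"""Corrected likelihood, score, MLE, observed information, intervals."""

import numpy as np
import pytest
from scipy.optimize import brentq

from mwpffc.censoring import CensoringScheme, PFFCSample, make_scheme, sample_pffc
from mwpffc.distribution import MWDParams, logpdf, sf
from mwpffc.mle import (
    MLEFit, delta_ci, fit_mle, loglik, observed_info, profile_lam,
    reliability_point, score, wald_ci,
)

PRINTED = MWDParams(0.65122, 1.77911, 0.09011)


def _random_case(seed):
    rng = np.random.default_rng(seed)
    n, m, k = 20, 10, int(rng.integers(1, 4))
    scheme = make_scheme(("SC1", "SC2", "SC3")[seed % 3], n, m, k)
    truth = MWDParams(*np.exp(rng.normal(0, 0.4, 3)))
    s = sample_pffc(truth, scheme, rng)
    p = MWDParams(*np.exp(rng.normal(0, 0.3, 3)))
    return p, s


def test_loglik_on_renal_subsample(renal_sub):
    # hand-evaluated term by term with the corrected formula
    assert loglik(PRINTED, renal_sub) == pytest.approx(-22.978204761878, abs=1e-9)


def test_loglik_reduces_to_complete_sample(study_truth):
    scheme = make_scheme("SC1", 6, 6, 1)  # k=1, R=0, m=n
    s = sample_pffc(study_truth, scheme, np.random.default_rng(2))
    p = MWDParams(0.8, 0.2, 1.5)
    assert loglik(p, s) == pytest.approx(float(np.sum(logpdf(s.x, p))), rel=1e-12)


def test_loglik_matches_joint_density():
    # exp(l) = prod f(x_i) * S(x_i)^(k*(R_i+1)-1) exactly (constant absorbed)
    scheme = CensoringScheme(n=6, m=3, k=2, R=(2, 1, 0))
    s = PFFCSample(scheme=scheme, x=np.array([0.2, 0.7, 1.1]))
    for triple in [(1, 1, 1), (0.7, 1.5, 0.5), (2.0, 0.8, 1.2), (1.3, 2.0, 0.3)]:
        p = MWDParams(*triple)
        direct = sum(
            float(logpdf(xi, p)) + (scheme.k * (ri + 1) - 1) * float(np.log(sf(xi, p)))
            for xi, ri in zip(s.x, scheme.R)
        )
        assert loglik(p, s) == pytest.approx(direct, rel=1e-10)


def test_loglik_rejects_zero_times():
    scheme = make_scheme("SC1", 4, 3, 1)
    s = PFFCSample(scheme=scheme, x=np.array([0.0, 0.5, 1.0]))
    with pytest.raises(ValueError):
        loglik(MWDParams(1, 1, 1), s)


@pytest.mark.parametrize("seed", range(20))
def test_score_matches_finite_differences(seed):
    p, s = _random_case(seed)
    theta = p.as_array()
    g = score(p, s)
    g_fd = np.empty(3)
    for j in range(3):
        h = 1e-6 * theta[j]
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        g_fd[j] = (loglik(MWDParams.from_array(tp), s) - loglik(MWDParams.from_array(tm), s)) / (2 * h)
    np.testing.assert_allclose(g, g_fd, rtol=1e-6, atol=1e-8 * np.abs(g).max())


def test_lambda_profile_matches_score_root(renal_sub):
    a, b = 0.5, 2.0
    lam_closed = profile_lam(a, b, renal_sub)
    root = brentq(
        lambda l: score(MWDParams(a, b, l), renal_sub)[2], 1e-6, 10.0, xtol=1e-14
    )
    assert lam_closed == pytest.approx(root, rel=1e-10)


def test_fit_on_renal_subsample(renal_sub_fit, renal_sub):
    # frozen optimum of the corrected likelihood on the censored subsample
    p = renal_sub_fit.params_hat
    assert renal_sub_fit.converged and not renal_sub_fit.boundary
    assert p.alpha == pytest.approx(0.405234, rel=1e-3)
    assert p.beta == pytest.approx(3.891838, rel=1e-3)
    assert p.lam == pytest.approx(0.063534, rel=1e-3)
    assert renal_sub_fit.loglik == pytest.approx(-20.470341061, abs=1e-6)
    # first-order condition, scaled
    g = score(p, renal_sub) * p.as_array()
    assert np.max(np.abs(g)) < 1e-5 * renal_sub.scheme.m
    # joint optimum consistent with the lambda profile
    lam_prof = profile_lam(p.alpha, p.beta, renal_sub)
    assert abs(p.lam - lam_prof) / p.lam < 1e-6


def test_fit_multistart_agreement(renal_sub, renal_sub_fit):
    rng = np.random.default_rng(0)
    ref = renal_sub_fit.params_hat.as_array()
    for _ in range(5):
        init = MWDParams.from_array(ref * np.exp(rng.normal(0, 0.4, 3)))
        f = fit_mle(renal_sub, init=init)
        np.testing.assert_allclose(f.params_hat.as_array(), ref, rtol=1e-4)


def test_fit_requires_enough_data():
    scheme = make_scheme("SC1", 2, 2, 1)
    s = PFFCSample(scheme=scheme, x=np.array([0.5, 1.0]))
    with pytest.raises(ValueError):
        fit_mle(s)


def test_fit_flags_degenerate_data():
    scheme = make_scheme("SC1", 4, 4, 1)
    s = PFFCSample(scheme=scheme, x=np.full(4, 2.0))
    f = fit_mle(s)
    assert not f.converged


def test_observed_info_matches_loglik_curvature(renal_sub, renal_sub_fit):
    p = renal_sub_fit.params_hat
    I_fd = observed_info(p, renal_sub)
    I_cs = observed_info(p, renal_sub, method="cs")
    np.testing.assert_allclose(I_fd, I_cs, rtol=1e-4)
    # second finite differences of the log-likelihood itself
    theta = p.as_array()
    h = 1e-4 * theta

    def ll(t):
        return loglik(MWDParams.from_array(t), renal_sub)

    for i in range(3):
        e = np.zeros(3)
        e[i] = h[i]
        d2 = (ll(theta + e) - 2 * ll(theta) + ll(theta - e)) / h[i] ** 2
        assert -d2 == pytest.approx(I_cs[i, i], rel=1e-4)
    # closed form for the lam block
    assert I_cs[2, 2] == pytest.approx(renal_sub.scheme.m / p.lam**2, rel=1e-12)
    # positive definite at an interior maximum
    assert np.all(np.linalg.eigvalsh(I_cs) > 0)


def test_wald_ci_geometry(renal_sub_fit):
    from scipy.stats import norm

    cis = wald_ci(renal_sub_fit, gamma=0.05)
    z = norm.ppf(0.975)
    assert z == pytest.approx(1.959964, abs=1e-6)
    for name, idx in (("alpha", 0), ("beta", 1), ("lam", 2)):
        lo, hi = cis[name]
        se = np.sqrt(renal_sub_fit.cov[idx, idx])
        assert hi - lo == pytest.approx(2 * z * se, rel=1e-12)
    lo_t, _ = wald_ci(renal_sub_fit, gamma=0.05, truncate_at_zero=True)["beta"]
    assert lo_t >= 0.0


def test_wald_ci_degenerate_and_invalid_cases(renal_sub_fit):
    fit0 = MLEFit(
        params_hat=renal_sub_fit.params_hat, loglik=0.0, cov=np.zeros((3, 3)),
        converged=True, n_iter=0,
    )
    cis = wald_ci(fit0)
    for name, est in zip(("alpha", "beta", "lam"), renal_sub_fit.params_hat.as_array()):
        assert cis[name] == (est, est)
    bad = MLEFit(
        params_hat=renal_sub_fit.params_hat, loglik=0.0, cov=-np.eye(3),
        converged=True, n_iter=0,
    )
    with pytest.raises(ValueError, match="positive definite"):
        wald_ci(bad)
    notconv = MLEFit(
        params_hat=renal_sub_fit.params_hat, loglik=0.0, cov=np.eye(3),
        converged=False, n_iter=0,
    )
    with pytest.raises(ValueError):
        wald_ci(notconv)


def test_reliability_point_plugin_values():
    # direct evaluation at the printed parameter triple
    rp = reliability_point(PRINTED, 1.0)
    assert rp.S == pytest.approx(0.8535047147636, rel=1e-10)
    assert rp.h == pytest.approx(0.1426263363057, rel=1e-10)
    assert rp.r == pytest.approx(0.8309636060293, rel=1e-10)
    assert rp.var_S == rp.var_h == rp.var_r == 0.0
    with pytest.raises(ValueError):
        reliability_point(PRINTED, 0.0)


def test_delta_ci_zero_cov_is_degenerate(renal_sub_fit):
    fit0 = MLEFit(
        params_hat=renal_sub_fit.params_hat, loglik=0.0, cov=np.zeros((3, 3)),
        converged=True, n_iter=0,
    )
    cis = delta_ci(fit0, 1.0)
    for lo, hi in cis.values():
        assert hi == pytest.approx(lo, abs=1e-14)


def test_time_rescaling_invariance(renal_sub):
    # data in units c*t fits to (alpha, c*beta, lam/c)
    c = 3.0
    f1 = fit_mle(renal_sub)
    scaled = PFFCSample(scheme=renal_sub.scheme, x=c * renal_sub.x)
    f2 = fit_mle(scaled)
    assert f2.params_hat.alpha == pytest.approx(f1.params_hat.alpha, rel=1e-3)
    assert f2.params_hat.beta == pytest.approx(c * f1.params_hat.beta, rel=1e-3)
    assert f2.params_hat.lam == pytest.approx(f1.params_hat.lam / c, rel=1e-3)


def test_delta_variance_matches_parametric_bootstrap(study_truth):
    # the gradient-sandwich variance of S(t) against a bootstrap cloud
    scheme = make_scheme("SC1", 90, 75, 2)
    rng = np.random.default_rng(9)
    s = sample_pffc(study_truth, scheme, rng)
    f = fit_mle(s)
    rp = reliability_point(f.params_hat, 0.1, cov=f.cov)
    cloud = []
    for b in range(200):
        rngb = np.random.default_rng(np.random.SeedSequence(entropy=(9, b)))
        sb = sample_pffc(f.params_hat, scheme, rngb)
        fb = fit_mle(sb)
        if fb.converged and not fb.boundary:
            cloud.append(reliability_point(fb.params_hat, 0.1).S)
    boot = np.var(cloud, ddof=1)
    assert rp.var_S == pytest.approx(boot, rel=0.25)
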