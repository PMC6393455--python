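import numpy as np
import pytest
from scipy import stats

from vitdmr.estimators import (
    cochran_q,
    ivw,
    mr_egger,
    wald_ratio,
    weighted_median,
)
from vitdmr.harmonize import HarmonizedInstrument

from conftest import make_instruments


def _inst(rsid, bx, sx, by, sy):
    return HarmonizedInstrument(
        rsid=rsid, effect_allele="A", other_allele="G",
        beta_exposure=bx, se_exposure=sx, beta_outcome=by, se_outcome=sy,
    )


# --- Wald ratio ---


def test_wald_ratio_arithmetic():
    est = wald_ratio(_inst("rs1", 0.5, 0.01, 0.1, 0.05))
    assert est.beta == pytest.approx(0.2)
    assert est.se == pytest.approx(0.1)
    null = wald_ratio(_inst("rs2", 0.5, 0.01, 0.0, 0.05))
    assert null.beta == 0.0


def test_wald_first_order_se_matches_monte_carlo():
    """Delta-method SE within 5% of the simulated ratio SD at low exposure CV."""
    rng = np.random.default_rng(11)
    bx, sx, by, sy = 0.5, 0.03, 0.1, 0.05  # sx/bx = 0.06 < 0.1
    draws_x = rng.normal(bx, sx, 100_000)
    draws_y = rng.normal(by, sy, 100_000)
    mc_sd = np.std(draws_y / draws_x, ddof=1)
    est = wald_ratio(_inst("rs1", bx, sx, by, sy))
    assert est.se == pytest.approx(mc_sd, rel=0.05)


# --- IVW ---


def test_ivw_consensus_ratio_and_zero_q():
    instruments = [_inst(f"rs{i}", b, 0.01, 0.25 * b, 0.03) for i, b in enumerate([0.1, 0.2, 0.3])]
    est = ivw(instruments)
    assert est.beta == pytest.approx(0.25, abs=1e-12)
    assert cochran_q(instruments, est.beta).Q == pytest.approx(0.0, abs=1e-20)


def test_ivw_two_instruments_hand_computed():
    a = _inst("rs1", 0.2, 0.01, 0.05, 0.04)
    b = _inst("rs2", 0.1, 0.01, -0.02, 0.05)
    w1, w2 = 0.2**2 / 0.04**2, 0.1**2 / 0.05**2
    r1, r2 = 0.05 / 0.2, -0.02 / 0.1
    expected_beta = (w1 * r1 + w2 * r2) / (w1 + w2)
    expected_se = (w1 + w2) ** -0.5
    est = ivw([a, b])
    assert est.beta == pytest.approx(expected_beta, abs=1e-12)
    assert est.se == pytest.approx(expected_se, abs=1e-12)


def test_ivw_fixed_equals_weighted_through_origin_regression(rng):
    """Algebraic identity with the 1/se_out^2-weighted no-intercept slope."""
    for _ in range(10):
        instruments = make_instruments(rng, k=7)
        bx = np.array([h.beta_exposure for h in instruments])
        by = np.array([h.beta_outcome for h in instruments])
        sy = np.array([h.se_outcome for h in instruments])
        slope = np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2)
        assert ivw(instruments).beta == pytest.approx(slope, abs=1e-10)


def test_ivw_mre_floors_residual_sd_at_one():
    # homogeneous ratios: sigma < 1, so the MRE SE equals the fixed SE
    instruments = [_inst(f"rs{i}", b, 0.01, 0.2 * b + e, 0.05)
                   for i, (b, e) in enumerate([(0.1, 1e-4), (0.2, -1e-4), (0.3, 0.0)])]
    assert ivw(instruments, "multiplicative_random").se == pytest.approx(ivw(instruments).se)
    # heterogeneous ratios: MRE SE strictly wider
    noisy = [_inst(f"rs{i}", b, 0.01, r * b, 0.01)
             for i, (b, r) in enumerate([(0.1, 0.6), (0.2, -0.4), (0.3, 0.3)])]
    assert ivw(noisy, "multiplicative_random").se > ivw(noisy).se


def test_ivw_needs_two_instruments():
    with pytest.raises(ValueError, match="wald_ratio"):
        ivw([_inst("rs1", 0.2, 0.01, 0.05, 0.04)])


# --- MR-Egger ---


def test_egger_recovers_noiseless_line():
    c, b = 0.013, 0.27
    instruments = [_inst(f"rs{i}", x, 0.01, c + b * x, 0.03 + 0.01 * i)
                   for i, x in enumerate([0.05, 0.1, 0.18, 0.25])]
    res = mr_egger(instruments)
    assert res.intercept == pytest.approx(c, abs=1e-10)
    assert res.slope.beta == pytest.approx(b, abs=1e-10)


def test_egger_null_intercept_when_no_pleiotropy():
    instruments = [_inst(f"rs{i}", x, 0.01, 0.3 * x, 0.03) for i, x in enumerate([0.05, 0.12, 0.2])]
    assert mr_egger(instruments).intercept == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", [3, 4, 5])
def test_egger_matches_normal_equations_oracle(seed):
    """Independent closed-form WLS (normal equations) to 1e-10 on random sets."""
    rng = np.random.default_rng(seed)
    instruments = make_instruments(rng, k=7)
    x = np.array([h.beta_exposure for h in instruments])
    y = np.array([h.beta_outcome for h in instruments])
    w = 1.0 / np.array([h.se_outcome for h in instruments]) ** 2
    A = np.array([[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]])
    c0, b0 = np.linalg.solve(A, np.array([(w * y).sum(), (w * x * y).sum()]))
    resid = y - c0 - b0 * x
    sigma2 = float((w * resid**2).sum() / (len(x) - 2))
    cov = np.linalg.inv(A) * max(1.0, sigma2)
    res = mr_egger(instruments)
    assert res.intercept == pytest.approx(c0, abs=1e-10)
    assert res.slope.beta == pytest.approx(b0, abs=1e-10)
    assert res.intercept_se == pytest.approx(np.sqrt(cov[0, 0]), abs=1e-10)
    assert res.slope.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)
    # t reference widens or keeps p-values relative to normal
    res_t = mr_egger(instruments, reference="t")
    assert res_t.intercept_pvalue >= res.intercept_pvalue


def test_egger_needs_three_instruments():
    with pytest.raises(ValueError):
        mr_egger([_inst("rs1", 0.2, 0.01, 0.05, 0.04), _inst("rs2", 0.1, 0.01, 0.02, 0.05)])


# --- weighted median ---


def test_weighted_median_equal_weights_is_middle_ratio():
    instruments = [_inst(f"rs{i}", 0.1, 0.01, r * 0.1, 0.05) for i, r in enumerate([0.1, 0.4, 0.9])]
    est = weighted_median(instruments, n_boot=200, seed=1)
    assert est.beta == pytest.approx(0.4, abs=1e-12)


def test_weighted_median_dominant_instrument():
    # >50% of weight in the middle ratio with symmetric flanks
    mk = lambda i, b, r, sy: _inst(f"rs{i}", b, 0.01, r * b, sy)
    lo = mk(0, 0.1, -0.2, 0.05)
    dom = mk(1, 0.3, 0.5, 0.05 * 3 / np.sqrt(3))  # weight 3x the flanks
    hi = mk(2, 0.1, 1.4, 0.05)
    est = weighted_median([lo, dom, hi], n_boot=200, seed=1)
    assert est.beta == pytest.approx(0.5, abs=1e-12)


def test_weighted_median_bootstrap_se_self_consistent(rng):
    """SE stabilizes: 2k vs 20k bootstrap draws agree within 10%."""
    instruments = make_instruments(rng, k=7)
    se_small = weighted_median(instruments, n_boot=2000, seed=7).se
    se_big = weighted_median(instruments, n_boot=20000, seed=8).se
    assert se_small == pytest.approx(se_big, rel=0.10)


def test_weighted_median_guards():
    rng = np.random.default_rng(0)
    instruments = make_instruments(rng, k=3)
    with pytest.raises(ValueError, match="n_boot"):
        weighted_median(instruments, n_boot=50, seed=1)
    with pytest.raises(ValueError, match="seed"):
        weighted_median(instruments, n_boot=500)


# --- Cochran Q / heterogeneity ---


def test_cochran_q_two_instruments_hand_computed():
    a = _inst("rs1", 0.2, 0.01, 0.06, 0.04)
    b = _inst("rs2", 0.1, 0.01, -0.01, 0.05)
    ref = ivw([a, b]).beta
    w = np.array([0.2**2 / 0.04**2, 0.1**2 / 0.05**2])
    r = np.array([0.06 / 0.2, -0.01 / 0.1])
    expected_q = float(np.sum(w * (r - ref) ** 2))
    res = cochran_q([a, b], ref)
    assert res.Q == pytest.approx(expected_q, abs=1e-12)
    assert res.df == 1
    assert res.pvalue == pytest.approx(stats.chi2.sf(expected_q, 1))
    assert res.i_squared == pytest.approx(max(0.0, (expected_q - 1) / expected_q) * 100)


def test_identical_ratios_give_zero_heterogeneity():
    instruments = [_inst(f"rs{i}", b, 0.01, 0.3 * b, 0.04) for i, b in enumerate([0.1, 0.15, 0.2])]
    res = cochran_q(instruments, 0.3)
    assert res.Q == pytest.approx(0.0, abs=1e-18)
    assert res.i_squared == 0.0 and res.tau_squared == 0.0


# --- shared estimator properties ---


def test_estimators_equivariant_under_reordering(rng):
    instruments = make_instruments(rng, k=7)
    perm = [instruments[i] for i in rng.permutation(7)]
    assert ivw(perm).beta == pytest.approx(ivw(instruments).beta, abs=1e-12)
    assert mr_egger(perm).intercept == pytest.approx(mr_egger(instruments).intercept, abs=1e-12)
    ref = ivw(instruments).beta
    assert cochran_q(perm, ref).Q == pytest.approx(cochran_q(instruments, ref).Q, abs=1e-12)
    wm_a = weighted_median(instruments, n_boot=200, seed=3).beta
    wm_b = weighted_median(perm, n_boot=200, seed=3).beta
    assert wm_a == pytest.approx(wm_b, abs=1e-12)


def test_negating_outcomes_negates_estimates_keeps_ses(rng):
    instruments = make_instruments(rng, k=7)
    flipped = [
        HarmonizedInstrument(
            rsid=h.rsid, effect_allele=h.effect_allele, other_allele=h.other_allele,
            beta_exposure=h.beta_exposure, se_exposure=h.se_exposure,
            beta_outcome=-h.beta_outcome, se_outcome=h.se_outcome,
        )
        for h in instruments
    ]
    for variant in ("fixed", "multiplicative_random"):
        a, b = ivw(instruments, variant), ivw(flipped, variant)
        assert b.beta == pytest.approx(-a.beta, abs=1e-14)
        assert b.se == pytest.approx(a.se, abs=1e-14)
    ea, eb = mr_egger(instruments), mr_egger(flipped)
    assert eb.slope.beta == pytest.approx(-ea.slope.beta, abs=1e-12)
    assert eb.intercept == pytest.approx(-ea.intercept, abs=1e-12)
    assert eb.slope.se == pytest.approx(ea.slope.se, abs=1e-12)
    w = wald_ratio(instruments[0]), wald_ratio(flipped[0])
    assert w[1].beta == -w[0].beta and w[1].se == w[0].se


def test_or_scale_is_exponentiated_ci():
    est = ivw([_inst("rs1", 0.2, 0.01, 0.05, 0.04), _inst("rs2", 0.1, 0.01, 0.01, 0.05)])
    orr = est.or_scale
    assert orr.odds_ratio == pytest.approx(np.exp(est.beta))
    assert orr.ci_low == pytest.approx(np.exp(est.ci_low))
    assert orr.ci_high == pytest.approx(np.exp(est.ci_high))
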