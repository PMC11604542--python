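import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from spatimmune import (
    association_screen,
    bh_adjust,
    interaction_test,
    lr_logistic,
    simulate_feature_matrix,
)
from spatimmune.platform_features import BiomarkerMatrix


def test_constant_feature_gives_lr_zero_p_one():
    y = np.array([0, 1, 0, 1, 0, 1, 0, 1])
    res = lr_logistic(np.full(8, 3.0), y)
    assert res.lr_stat == 0.0
    assert res.lr_p == 1.0


def _binary_2x2_deviance(n_hi, k_hi, n_lo, k_lo):
    """Closed-form LR statistic for a binary feature from saturated 2x2
    binomial log-likelihoods (the logistic model with a binary predictor is
    saturated per group)."""

    def ll(k, n):
        out = 0.0
        p = k / n
        if 0 < p < 1:
            out = k * np.log(p) + (n - k) * np.log(1 - p)
        return out

    k, n = k_hi + k_lo, n_hi + n_lo
    return 2.0 * (ll(k_hi, n_hi) + ll(k_lo, n_lo) - ll(k, n))


def test_binary_feature_matches_closed_form_deviance():
    # pCR counts 8/10 in the high group vs 2/10 in the low group
    x = np.r_[np.ones(10), np.zeros(10)]
    y = np.r_[np.ones(8), np.zeros(2), np.ones(2), np.zeros(8)]
    res = lr_logistic(x, y)
    expected = _binary_2x2_deviance(10, 8, 10, 2)
    assert res.lr_stat == pytest.approx(expected, abs=1e-6)
    assert res.coef_sign == 1


def test_all_one_class_outcome_is_missing():
    assert lr_logistic(np.arange(10.0), np.ones(10)) is None
    assert lr_logistic(np.arange(10.0), np.r_[np.zeros(9), 1.0]) is None


def test_listwise_deletion_of_missing_values(rng):
    x = rng.normal(size=60)
    y = (rng.uniform(size=60) < 0.4).astype(float)
    x_miss = x.copy()
    x_miss[:10] = np.nan
    res_full = lr_logistic(x[10:], y[10:])
    res_miss = lr_logistic(x_miss, y)
    assert res_miss.n == 50
    assert res_miss.lr_p == pytest.approx(res_full.lr_p, rel=1e-9)


def test_label_swap_flips_direction_keeps_p(rng):
    x = rng.normal(size=80)
    y = (rng.uniform(size=80) < 1 / (1 + np.exp(-x))).astype(float)
    a = lr_logistic(x, y)
    b = lr_logistic(x, 1 - y)
    assert a.coef_sign == -b.coef_sign
    assert a.lr_p == pytest.approx(b.lr_p, rel=1e-6)


def test_separation_handled_and_flagged():
    # perfectly separated: feature sign determines outcome exactly
    x = np.r_[np.linspace(1, 2, 10), np.linspace(-2, -1, 10)]
    y = np.r_[np.ones(10), np.zeros(10)]
    res = lr_logistic(x, y)
    assert res is not None
    assert res.separation_flagged
    assert res.coef_sign == 1
    assert 0.0 <= res.lr_p < 0.05


def test_null_pvalues_uniform():
    """Under the null the LR p-value is Uniform(0,1); KS check over replicates."""
    rng = np.random.default_rng(7)
    pvals = []
    for _ in range(400):
        x = rng.normal(size=120)
        y = (rng.uniform(size=120) < 0.35).astype(float)
        res = lr_logistic(x, y)
        if res is not None:
            pvals.append(res.lr_p)
    assert kstest(pvals, "uniform").pvalue > 0.01


# -- interaction test -------------------------------------------------------

def test_interaction_requires_both_arms():
    with pytest.raises(ValueError, match="both treatment arms"):
        interaction_test(np.arange(10.0), np.ones(10),
                         np.r_[np.zeros(5), np.ones(5)])


def test_arm_specific_effect_flagged(rng):
    hits = 0
    for rep in range(20):
        r = np.random.default_rng(rep)
        n = 400
        x = r.normal(size=n)
        arm = (r.uniform(size=n) < 0.5).astype(float)
        logit = -0.5 + 2.0 * x * arm  # effect only in the experimental arm
        y = (r.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(float)
        p = interaction_test(x, arm, y)
        hits += p < 0.05
    assert hits >= 16  # >= 80% power


def test_permuted_arm_labels_destroy_interaction(rng):
    pvals = []
    for rep in range(30):
        r = np.random.default_rng(100 + rep)
        n = 300
        x = r.normal(size=n)
        arm = (r.uniform(size=n) < 0.5).astype(float)
        logit = -0.5 + 2.0 * x * arm
        y = (r.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(float)
        pvals.append(interaction_test(x, r.permutation(arm), y))
    assert np.mean(pvals) > 0.3


# -- BH adjustment ----------------------------------------------------------

def test_bh_single_p_unchanged():
    np.testing.assert_allclose(bh_adjust([0.031]), [0.031])


def test_bh_hand_stepup_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])


def test_bh_equal_ps_fixed_point():
    np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])


def test_bh_nan_restored_in_place():
    out = bh_adjust([0.01, np.nan, 0.04])
    assert np.isnan(out[1])
    np.testing.assert_allclose(out[[0, 2]], [0.02, 0.04])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_bh_never_rejects_more_than_raw():
    rng = np.random.default_rng(1)
    p = rng.uniform(size=200) ** 2
    adj = bh_adjust(p)
    assert (adj >= p - 1e-12).all()
    assert (adj[np.argsort(p)] == np.sort(adj)).all()  # monotone transform


# -- screen -----------------------------------------------------------------

def _screen_inputs(seed=0, coefs=None, n=200):
    feats, clin = simulate_feature_matrix(n, response_coefs=coefs or {}, seed=seed)
    from spatimmune.registries import feature_platform

    platforms = pd.Series({f: feature_platform(f) for f in feats.columns})
    return BiomarkerMatrix(feats, platforms), clin


def test_screen_recovers_spiked_features():
    spiked = {"TIL": 1.5, "DC_sig": 1.5, "CD3e": -1.5}
    matrix, clin = _screen_inputs(seed=5, coefs=spiked, n=500)
    out = association_screen(matrix, clin, cohorts=(("ALL", "pembro"),))
    hits = out.set_index("feature")
    for feat, coef in spiked.items():
        assert hits.loc[feat, "tier"] == "bh_significant"
        assert hits.loc[feat, "direction"] == np.sign(coef)


def test_screen_small_cohorts_skipped():
    matrix, clin = _screen_inputs(seed=2, n=40)
    out = association_screen(matrix, clin, cohorts=(("ALL", "pembro"),),
                             min_cohort_size=1000)
    assert out.empty


def test_screen_bh_family_scope_changes_families():
    matrix, clin = _screen_inputs(seed=3, coefs={"TIL": 1.0}, n=300)
    by_platform = association_screen(matrix, clin, cohorts=(("ALL", "pembro"),),
                                     family_scope="platform")
    by_cohort = association_screen(matrix, clin, cohorts=(("ALL", "pembro"),),
                                   family_scope="cohort")
    # same raw p-values, different adjusted values in general
    a = by_platform.set_index("feature")["lr_p"]
    b = by_cohort.set_index("feature")["lr_p"]
    pd.testing.assert_series_equal(a.sort_index(), b.sort_index())
    assert not np.allclose(by_platform.set_index("feature")["bh_p"].sort_index(),
                           by_cohort.set_index("feature")["bh_p"].sort_index())


def test_screen_tiers_consistent_with_thresholds():
    matrix, clin = _screen_inputs(seed=4, coefs={"TIL": 1.2}, n=300)
    out = association_screen(matrix, clin, cohorts=(("ALL", "pembro"),))
    assert (out["bh_p"] >= out["lr_p"] - 1e-12).all()
    sig = out[out["tier"] == "bh_significant"]
    assert (sig["bh_p"] < 0.05).all()
    nom = out[out["tier"] == "nominal"]
    assert ((nom["lr_p"] < 0.05) & (nom["bh_p"] >= 0.05)).all()


def test_dot_matrix_renders(tmp_path):
    matrix, clin = _screen_inputs(seed=6, coefs={"TIL": 1.5}, n=200)
    out = association_screen(matrix, clin, cohorts=(("ALL", "pembro"),))
    fig = __import__("spatimmune").association.render_dot_matrix(
        out.head(30), path=tmp_path / "dots.png")
    assert (tmp_path / "dots.png").stat().st_size > 0
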