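import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from spatimmune import (
    classify_ime,
    cross_platform_correlations,
    fisher_exact_rxc,
    pcr_rate_table,
)


def _series(vals, prefix="PT"):
    return pd.Series(vals, index=[f"{prefix}{i}" for i in range(len(vals))])


def test_til_low_regardless_of_mh():
    out = classify_ime(_series([10.0]), _series([0.99]), mh_cut=0.5)
    assert out["ime_class"].iloc[0] == "TIL_low"


def test_til_high_split_by_median():
    til = _series([30.0, 30.0, 30.0, 30.0])
    mh = _series([0.1, 0.2, 0.6, 0.8])  # median 0.4
    out = classify_ime(til, mh)
    assert out.attrs["mh_cut"] == pytest.approx(0.4)
    assert list(out["ime_class"]) == [
        "TIL_high_coloc_low", "TIL_high_coloc_low",
        "TIL_high_coloc_high", "TIL_high_coloc_high"]


def test_boundary_conventions():
    # TIL exactly at the cut is high; MH exactly at the median cut is low
    out = classify_ime(_series([12.5, 40.0]), _series([0.5, 0.5]), mh_cut=0.5)
    assert (out["ime_class"] == "TIL_high_coloc_low").all()


def test_missing_mh_for_til_high_patient_unclassified():
    out = classify_ime(_series([40.0, 5.0]), _series([np.nan, np.nan]), mh_cut=0.3)
    assert pd.isna(out["ime_class"].iloc[0])
    assert out["ime_class"].iloc[1] == "TIL_low"  # TIL-low needs no MH


def test_classification_partition(rng):
    til = _series(rng.uniform(0, 50, size=200))
    mh = _series(rng.uniform(0, 1, size=200))
    out = classify_ime(til, mh)
    assert out["ime_class"].notna().all()
    assert out["ime_class"].value_counts().sum() == 200


# -- Fisher exact -----------------------------------------------------------

def brute_force_fisher_2x2(table):
    """Enumerate all 2x2 tables with fixed margins; two-sided p by probability."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs + 1e-12)


def test_fisher_2x2_example_vs_enumeration():
    table = [[3, 1], [1, 3]]
    assert fisher_exact_rxc(table) == pytest.approx(brute_force_fisher_2x2(table))
    assert fisher_exact_rxc(table) == pytest.approx(
        scipy_fisher(np.array(table))[1])


@pytest.mark.parametrize("table", [
    [[5, 0], [1, 4]],
    [[2, 3], [3, 2]],
    [[10, 2], [3, 9]],
])
def test_fisher_2x2_matches_scipy(table):
    assert fisher_exact_rxc(table) == pytest.approx(
        scipy_fisher(np.array(table))[1], abs=1e-12)


def test_fisher_2x3_matches_r(tmp_path):
    """Independent oracle: R stats::fisher.test on a 2x3 table."""
    import subprocess

    table = [[8, 1], [4, 3], [2, 7]]
    script = tmp_path / "fisher.R"
    script.write_text(
        "m <- matrix(c(8,4,2,1,3,7), nrow=3)\n"
        'cat(sprintf("%.12f", fisher.test(m)$p.value))\n'
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
    assert out.returncode == 0, out.stderr
    assert fisher_exact_rxc(table) == pytest.approx(float(out.stdout), abs=1e-9)


def test_fisher_degenerate_rows_dropped():
    assert fisher_exact_rxc([[0, 0], [3, 4]]) == 1.0
    assert fisher_exact_rxc([[5, 0, 3], [0, 0, 0]]) == 1.0


# -- pCR rate table ---------------------------------------------------------

def _cohort():
    classes = _series(
        ["TIL_low"] * 9 + ["TIL_high_coloc_low"] * 10 + ["TIL_high_coloc_high"] * 12)
    pcr = _series([0] * 9 + [0] * 9 + [1] + [1] * 9 + [0] * 3)
    subtype = _series(["TN", "HR+HER2-"] * 15 + ["TN"])
    return classes, pcr, subtype


def test_rate_table_zero_responders_class():
    classes, pcr, subtype = _cohort()
    rates, p = pcr_rate_table(classes, pcr, subtype)
    overall = rates[rates["group"] == "ALL"].set_index("ime_class")
    assert overall.loc["TIL_low", "pcr_rate_pct"] == 0.0
    assert overall.loc["TIL_low", "n"] == 9
    assert overall.loc["TIL_high_coloc_high", "pcr_rate_pct"] == pytest.approx(75.0)
    assert 0.0 < p < 0.05  # strongly graded outcome across classes


def test_rate_table_patient_order_invariant():
    classes, pcr, subtype = _cohort()
    perm = np.random.default_rng(0).permutation(len(classes))
    r1, p1 = pcr_rate_table(classes, pcr, subtype)
    r2, p2 = pcr_rate_table(classes.iloc[perm], pcr.iloc[perm], subtype.iloc[perm])
    pd.testing.assert_frame_equal(r1, r2)
    assert p1 == p2


def test_monotone_dose_effect_on_simulated_classes(rng):
    """Cohorts where both TIL and colocalization raise response probability show
    nondecreasing pCR rates across the ordered classes."""
    n = 600
    til = rng.uniform(0, 40, size=n)
    mh = rng.uniform(0, 1, size=n)
    logit = -2.0 + 0.08 * til + 1.5 * mh
    pcr = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(int)
    out = classify_ime(_series(til), _series(mh))
    rates, _ = pcr_rate_table(out["ime_class"], _series(pcr))
    overall = rates[rates["group"] == "ALL"].set_index("ime_class")
    seq = overall.loc[["TIL_low", "TIL_high_coloc_low", "TIL_high_coloc_high"],
                      "pcr_rate_pct"]
    assert seq.is_monotonic_increasing


# -- cross-platform correlations -------------------------------------------

def test_feature_against_itself_r1(rng):
    df = pd.DataFrame({"a": rng.normal(size=30)})
    out = cross_platform_correlations(df, [("a", "a")])
    assert out.loc[0, "r"] == pytest.approx(1.0)


def test_anticorrelated_pair_negative(rng):
    x = rng.normal(size=50)
    df = pd.DataFrame({"a": x, "b": -x + rng.normal(scale=0.1, size=50)})
    out = cross_platform_correlations(df, [("a", "b")])
    assert out.loc[0, "r"] < -0.9


def test_bivariate_normal_recovery():
    rs = []
    for rep in range(200):
        r = np.random.default_rng(rep)
        x = r.normal(size=100)
        y = 0.6 * x + np.sqrt(1 - 0.36) * r.normal(size=100)
        df = pd.DataFrame({"a": x, "b": y})
        rs.append(cross_platform_correlations(df, [("a", "b")]).loc[0, "r"])
    assert abs(np.mean(rs) - 0.6) < 0.05


def test_constant_feature_reported_missing(rng):
    df = pd.DataFrame({"a": np.ones(20), "b": rng.normal(size=20)})
    out = cross_platform_correlations(df, [("a", "b"), ("b", "missing_feat")])
    assert out["r"].isna().all()
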