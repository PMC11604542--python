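"""Biomarker-response association screening.

Each biomarker is tested for association with pathologic complete response by a
likelihood-ratio test between nested logistic models: logit(pCR) ~ covariates +
feature versus logit(pCR) ~ covariates, with 2·(ℓ₁ − ℓ₀) ~ χ²₁.  Features enter
continuous and z-scored; tests are two-sided with direction read off the
coefficient sign.  Screens run per cohort (arm × receptor subtype), with
Benjamini-Hochberg correction within cohort × platform family by default, and
classify each result into three tiers: BH-significant, nominal (raw p < α), or
not significant.  A biomarker × arm interaction test flags treatment-specific
effects.

Quasi-complete separation is detected (non-convergence or runaway coefficients)
and handled by refitting both nested models with a small L2 ridge penalty; such
results are flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .platform_features import BiomarkerMatrix

log = logging.getLogger(__name__)

RIDGE_ALPHA = 1e-4
_SEP_COEF_LIMIT = 20.0  # |coef| on z-scored predictors beyond this ⇒ separation

DEFAULT_COHORTS: tuple[tuple[str, str], ...] = (
    ("ALL", "pembro"), ("ALL", "control"),
    ("TN", "pembro"), ("TN", "control"),
    ("HR+HER2-", "pembro"), ("HR+HER2-", "control"),
)


@dataclass
class LRResult:
    """One likelihood-ratio test: direction sign, p, and diagnostics."""

    coef_sign: int
    lr_p: float
    lr_stat: float
    n: int
    n_pcr: int
    separation_flagged: bool = False


def _loglike_fit(y: np.ndarray, X: np.ndarray):
    """Fit a logistic model, returning (llf, params, converged)."""
    model = sm.Logit(y, X)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation is detected below
            res = model.fit(disp=0, warn_convergence=False, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", False))
        if converged and np.max(np.abs(res.params)) > _SEP_COEF_LIMIT:
            converged = False
        return float(res.llf), np.asarray(res.params), converged
    except Exception:
        return -np.inf, np.zeros(X.shape[1]), False


def _ridge_fit(y: np.ndarray, X: np.ndarray):
    """Ridge-stabilized logistic fit; returns (llf at penalized params, params)."""
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with np.errstate(all="ignore"):
        res = model.fit_regularized(alpha=RIDGE_ALPHA, L1_wt=0.0)
    params = np.asarray(res.params)
    return float(model.loglike(params)), params


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def lr_logistic(feature, pcr, covariates=None) -> LRResult | None:
    """LR test of one biomarker against pCR, optionally covariate-adjusted.

    ``feature`` and ``pcr`` are aligned 1-d sequences; ``covariates`` an
    aligned 2-d array/frame.  Patients with any missing value are dropped
    listwise.  Returns None when the test is undefined (all-one-class outcome
    or fewer than two observed outcomes per class).  A constant feature yields
    LR statistic 0 and p = 1.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(pcr, dtype=float)
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    keep = np.isfinite(x) & np.isfinite(y)
    if C is not None:
        keep &= np.isfinite(C).all(axis=1)
    x, y = x[keep], y[keep]
    if C is not None:
        C = C[keep]
    n = len(y)
    n_pcr = int(y.sum())
    if n_pcr < 2 or (n - n_pcr) < 2:
        return None
    if x.std(ddof=0) == 0:
        return LRResult(0, 1.0, 0.0, n, n_pcr)
    xz = _zscore(x)
    ones = np.ones((n, 1))
    X0 = ones if C is None else np.column_stack([ones, np.apply_along_axis(_zscore, 0, C)])
    X1 = np.column_stack([X0, xz])
    ll0, _, ok0 = _loglike_fit(y, X0)
    ll1, params1, ok1 = _loglike_fit(y, X1)
    flagged = False
    if not (ok0 and ok1):
        ll0, _ = _ridge_fit(y, X0)
        ll1, params1 = _ridge_fit(y, X1)
        flagged = True
        log.debug("separation-flagged LR fit (n=%d)", n)
    stat = max(0.0, 2.0 * (ll1 - ll0))
    p = float(chi2.sf(stat, df=1))
    sign = int(np.sign(params1[-1]))
    return LRResult(sign, p, stat, n, n_pcr, flagged)


def interaction_test(feature, arm, pcr, covariates=None) -> float | None:
    """LR p-value for a biomarker × treatment-arm interaction term.

    Tests logit(pCR) ~ feature + arm + feature:arm against the model without
    the interaction.  ``arm`` is a binary indicator (1 = experimental arm).
    Raises if only one arm is present; returns None when undefined.
    """
    x = np.asarray(feature, dtype=float)
    a = np.asarray(arm, dtype=float)
    y = np.asarray(pcr, dtype=float)
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(a)
    if C is not None:
        keep &= np.isfinite(C).all(axis=1)
    x, a, y = x[keep], a[keep], y[keep]
    if C is not None:
        C = C[keep]
    if len(np.unique(a)) < 2:
        raise ValueError("interaction test requires both treatment arms")
    n = len(y)
    if y.sum() < 2 or (n - y.sum()) < 2 or x.std(ddof=0) == 0:
        return None
    xz = _zscore(x)
    base_cols = [np.ones(n), xz, a]
    if C is not None:
        base_cols.extend(np.apply_along_axis(_zscore, 0, C).T)
    X0 = np.column_stack(base_cols)
    X1 = np.column_stack(base_cols + [xz * a])
    ll0, _, ok0 = _loglike_fit(y, X0)
    ll1, _, ok1 = _loglike_fit(y, X1)
    if not (ok0 and ok1):
        ll0, _ = _ridge_fit(y, X0)
        ll1, _ = _ridge_fit(y, X1)
    stat = max(0.0, 2.0 * (ll1 - ll0))
    return float(chi2.sf(stat, df=1))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries are excluded from the family and restored in place as NaN.
    Values outside [0, 1] raise.
    """
    p = np.asarray(pvals, dtype=float)
    mask = np.isfinite(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def association_screen(matrix: BiomarkerMatrix,
                       clinical: pd.DataFrame,
                       cohorts: tuple[tuple[str, str], ...] = DEFAULT_COHORTS,
                       covariate_cols: list[str] | None = None,
                       alpha: float = 0.05,
                       family_scope: str = "platform",
                       min_cohort_size: int = 10,
                       with_interaction: bool = False) -> pd.DataFrame:
    """Screen every biomarker for pCR association per cohort.

    ``clinical`` is indexed by patient with columns ``arm``, ``subtype``,
    ``pCR`` and any covariates.  ``cohorts`` are (subtype, arm) pairs; subtype
    "ALL" pools subtypes.  BH families are cohort × platform when
    ``family_scope="platform"`` (default) or whole-cohort with
    ``family_scope="cohort"``.  Returns the dot-matrix table: one row per
    feature × cohort with direction, lr_p, bh_p and tier; optionally an
    ``interaction_p`` column (pembro-vs-control interaction, subtype-matched).
    """
    if family_scope not in ("platform", "cohort"):
        raise ValueError("family_scope must be 'platform' or 'cohort'")
    common = matrix.values.index.intersection(clinical.index)
    if common.empty:
        raise ValueError("no patients shared between matrix and clinical table")
    values = matrix.values.loc[common]
    clin = clinical.loc[common]

    rows = []
    for subtype, arm in cohorts:
        in_cohort = clin["arm"] == arm
        if subtype != "ALL":
            in_cohort &= clin["subtype"] == subtype
        idx = clin.index[in_cohort]
        if len(idx) < min_cohort_size:
            log.warning("cohort %s/%s below minimum size (%d < %d); skipped",
                        subtype, arm, len(idx), min_cohort_size)
            continue
        y = clin.loc[idx, "pCR"].to_numpy(dtype=float)
        C = (clin.loc[idx, covariate_cols].to_numpy(dtype=float)
             if covariate_cols else None)
        for feat in values.columns:
            x = values.loc[idx, feat].to_numpy(dtype=float)
            if not np.isfinite(x).any():
                log.info("feature %s: all missing in cohort %s/%s; omitted",
                         feat, subtype, arm)
                continue
            res = lr_logistic(x, y, C)
            if res is None:
                continue
            rows.append({
                "feature": feat,
                "platform": matrix.platforms[feat],
                "subtype": subtype,
                "arm": arm,
                "cohort": f"{subtype}, {arm}",
                "direction": res.coef_sign,
                "lr_p": res.lr_p,
                "n": res.n,
                "n_pCR": res.n_pcr,
                "separation_flagged": res.separation_flagged,
            })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    family_cols = ["cohort"] if family_scope == "cohort" else ["cohort", "platform"]
    out["bh_p"] = (
        out.groupby(family_cols, group_keys=False)["lr_p"]
        .transform(lambda s: pd.Series(bh_adjust(s.to_numpy()), index=s.index))
    )
    out["tier"] = np.select(
        [out["bh_p"] < alpha, out["lr_p"] < alpha],
        ["bh_significant", "nominal"], default="ns")
    if with_interaction:
        inter = []
        arm_bin = (clin["arm"] == "pembro").astype(float)
        for _, row in out.iterrows():
            subtype = row["subtype"]
            sel = slice(None) if subtype == "ALL" else clin["subtype"] == subtype
            sub = clin.loc[sel] if subtype != "ALL" else clin
            x = values.loc[sub.index, row["feature"]].to_numpy(dtype=float)
            try:
                p = interaction_test(x, arm_bin.loc[sub.index].to_numpy(),
                                     sub["pCR"].to_numpy(dtype=float))
            except ValueError:
                p = np.nan
            inter.append(np.nan if p is None else p)
        out["interaction_p"] = inter
    return out


def render_dot_matrix(screen: pd.DataFrame, path=None):
    """Render the association dot-matrix (dot size ∝ −log10 p, color =
    direction, background shade = significance tier).  Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    feats = sorted(screen["feature"].unique())
    cohorts = sorted(screen["cohort"].unique())
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(feats)),
                                    max(3, 0.5 * len(cohorts))))
    tier_shade = {"bh_significant": "white", "nominal": "0.8", "ns": "0.5"}
    for _, row in screen.iterrows():
        xi = feats.index(row["feature"])
        yi = cohorts.index(row["cohort"])
        ax.add_patch(plt.Rectangle((xi - 0.5, yi - 0.5), 1, 1,
                                   color=tier_shade[row["tier"]], zorder=1))
        size = 20 * max(0.5, -np.log10(max(row["lr_p"], 1e-10)))
        color = "firebrick" if row["direction"] > 0 else "steelblue"
        ax.scatter([xi], [yi], s=size, c=color, zorder=2)
    ax.set_xticks(range(len(feats)), feats, rotation=90, fontsize=6)
    ax.set_yticks(range(len(cohorts)), cohorts, fontsize=7)
    ax.set_xlim(-0.5, len(feats) - 0.5)
    ax.set_ylim(-0.5, len(cohorts) - 0.5)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
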