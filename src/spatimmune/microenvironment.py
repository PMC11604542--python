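"""Tumor immune microenvironment classification and response tabulation.

Patients are stratified by tumor-infiltrating-lymphocyte level and PD-1/PD-L1
colocalization into three ordered classes:

* ``TIL_low`` — TIL below 12.5% of total cells;
* ``TIL_high_coloc_low`` — TIL-high but PD1Tc_PDL1 Morisita-Horn colocalization
  at or below the cohort median;
* ``TIL_high_coloc_high`` — TIL-high with above-median colocalization.

Boundary conventions: TIL exactly at the cut counts as high; a colocalization
score exactly at the median counts as low.  The median cut is computed within
the cohort being classified unless a fixed cut is supplied.

Class-response association uses Fisher's exact test; the 2×3 case (and any
r×c) is evaluated by exhaustive enumeration over all tables with the observed
margins (Freeman-Halton), with a Monte-Carlo fallback above a configurable
table-total.
"""

from __future__ import annotations

import logging
from math import lgamma

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _fisher_2x2
from scipy.stats import pearsonr

log = logging.getLogger(__name__)

TIL_CUT_DEFAULT = 12.5
CLASSES = ("TIL_low", "TIL_high_coloc_low", "TIL_high_coloc_high")


def classify_ime(til_pct: pd.Series, mh_score: pd.Series,
                 til_cut: float = TIL_CUT_DEFAULT,
                 mh_cut: float | None = None) -> pd.DataFrame:
    """Assign each patient an immune-microenvironment class.

    ``til_pct`` and ``mh_score`` are aligned per-patient series (TIL percent of
    total cells; PD1Tc_PDL1 MH index).  ``mh_cut`` defaults to the median MH
    over classified (TIL and MH both present) patients.  Patients missing TIL
    are unclassified; TIL-high patients missing MH get a missing class.

    Returns a frame with columns ``ime_class, til_pct, mh_score`` plus the cut
    points used (attrs ``til_cut``/``mh_cut``).
    """
    df = pd.DataFrame({"til_pct": til_pct, "mh_score": mh_score})
    if mh_cut is None:
        usable = df.dropna()
        if usable.empty:
            raise ValueError("no patient has both TIL and MH; cannot set median cut")
        mh_cut = float(usable["mh_score"].median())
    cls = pd.Series(pd.NA, index=df.index, dtype="object", name="ime_class")
    has_til = df["til_pct"].notna()
    low = has_til & (df["til_pct"] < til_cut)
    cls[low] = "TIL_low"
    high = has_til & ~low
    cls[high & (df["mh_score"] > mh_cut)] = "TIL_high_coloc_high"
    cls[high & (df["mh_score"] <= mh_cut)] = "TIL_high_coloc_low"
    # TIL-high with missing MH stays NA
    out = df.assign(ime_class=cls)
    out.attrs["til_cut"] = float(til_cut)
    out.attrs["mh_cut"] = float(mh_cut)
    log.info("IME classification cuts: TIL %.3g%%, MH %.4g", til_cut, mh_cut)
    return out


# ---------------------------------------------------------------------------
# Fisher exact test (r x c by exhaustive enumeration)
# ---------------------------------------------------------------------------

def _log_table_prob(table: np.ndarray, lg_fixed: float) -> float:
    return lg_fixed - sum(lgamma(v + 1) for v in table.ravel())


def fisher_exact_rxc(table, max_total: int = 2000, n_sim: int = 100_000,
                     seed: int = 0) -> float:
    """Two-sided Fisher exact p for an r×c contingency table.

    Exhaustive enumeration over all tables with the observed margins; p is the
    total probability of tables no more probable than the observed one
    (Freeman-Halton).  2×2 tables are delegated to scipy.  Above ``max_total``
    cells-total the p-value is estimated by Monte-Carlo sampling of margin-fixed
    tables instead.
    """
    T = np.asarray(table, dtype=int)
    if T.ndim != 2 or (T < 0).any():
        raise ValueError("table must be a nonnegative 2-d array")
    # drop empty rows/columns: they carry no information
    T = T[T.sum(axis=1) > 0][:, T.sum(axis=0) > 0]
    if T.shape[0] < 2 or T.shape[1] < 2:
        return 1.0
    if T.shape == (2, 2):
        return float(_fisher_2x2(T, alternative="two-sided")[1])
    rows, cols = T.sum(axis=1), T.sum(axis=0)
    N = int(T.sum())
    lg_fixed = (sum(lgamma(r + 1) for r in rows)
                + sum(lgamma(c + 1) for c in cols) - lgamma(N + 1))
    logp_obs = _log_table_prob(T, lg_fixed)
    if N > max_total:
        rng = np.random.default_rng(seed)
        hits = 0
        flat_rows = np.repeat(np.arange(len(rows)), rows)
        for _ in range(n_sim):
            perm = rng.permutation(flat_rows)
            sim = np.zeros_like(T)
            start = 0
            for j, c in enumerate(cols):
                r_idx, r_cnt = np.unique(perm[start:start + c], return_counts=True)
                sim[r_idx, j] = r_cnt
                start += c
            if _log_table_prob(sim, lg_fixed) <= logp_obs + 1e-9:
                hits += 1
        return (hits + 1) / (n_sim + 1)
    # exhaustive recursion over all margin-consistent tables
    p_total = 0.0

    def recurse(row: int, remaining_cols: np.ndarray, acc: list[np.ndarray]):
        nonlocal p_total
        if row == len(rows) - 1:
            cand = np.vstack(acc + [remaining_cols])
            if (remaining_cols >= 0).all():
                lp = _log_table_prob(cand, lg_fixed)
                if lp <= logp_obs + 1e-9:
                    p_total += float(np.exp(lp))
            return
        target = rows[row]

        def fill(j: int, left: int, current: list[int]):
            if j == len(cols) - 1:
                if 0 <= left <= remaining_cols[-1]:
                    recurse(row + 1,
                            remaining_cols - np.array(current + [left]),
                            acc + [np.array(current + [left])])
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                fill(j + 1, left - v, current + [v])

        fill(0, int(target), [])

    recurse(0, cols.copy(), [])
    return min(1.0, p_total)


def pcr_rate_table(classes: pd.Series, pcr: pd.Series,
                   subtype: pd.Series | None = None) -> tuple[pd.DataFrame, float]:
    """pCR rate per immune-microenvironment class plus a Fisher exact p.

    Returns ``(rates, p)``: rates has one row per class (and per subtype ×
    class when ``subtype`` is given) with n, n_pCR and rate in percent; the p
    is from the Fisher exact test on the class × response table over all
    classified patients (empty classes excluded).
    """
    df = pd.DataFrame({"ime_class": classes, "pCR": pcr})
    if subtype is not None:
        df["subtype"] = subtype
    df = df.dropna(subset=["ime_class", "pCR"])
    if df.empty:
        raise ValueError("no classified patients with observed response")

    def _rates(sub: pd.DataFrame, label: str) -> list[dict]:
        out = []
        for cls in CLASSES:
            grp = sub[sub["ime_class"] == cls]
            n = len(grp)
            out.append({
                "group": label, "ime_class": cls, "n": n,
                "n_pCR": int(grp["pCR"].sum()),
                "pcr_rate_pct": 100.0 * grp["pCR"].mean() if n else np.nan,
            })
        return out

    rows = _rates(df, "ALL")
    if subtype is not None:
        for s, sub in df.groupby("subtype", observed=True):
            rows.extend(_rates(sub, str(s)))
    rates = pd.DataFrame(rows)

    tab = (df.groupby(["ime_class", "pCR"], observed=True).size()
           .unstack(fill_value=0)
           .reindex(index=list(CLASSES), columns=[0, 1], fill_value=0))
    tab = tab[tab.sum(axis=1) > 0]
    p = fisher_exact_rxc(tab.to_numpy())
    return rates, float(p)


# ---------------------------------------------------------------------------
# Cross-platform correlation panel
# ---------------------------------------------------------------------------

def cross_platform_correlations(matrix, pairs: list[tuple[str, str]]
                                ) -> pd.DataFrame:
    """Pearson r with two-sided p for configured cross-platform feature pairs.

    ``matrix`` is a BiomarkerMatrix or a patients × features frame.  Pairs with
    fewer than 3 complete observations or a constant member are reported with
    missing r/p.
    """
    values = matrix if isinstance(matrix, pd.DataFrame) else getattr(matrix, "values", None)
    if not isinstance(values, pd.DataFrame):
        raise TypeError("matrix must be a BiomarkerMatrix or DataFrame")
    rows = []
    for fa, fb in pairs:
        rec = {"feature_a": fa, "feature_b": fb, "n": 0,
               "r": np.nan, "p": np.nan}
        if fa in values.columns and fb in values.columns:
            sub = pd.DataFrame({"a": values[fa], "b": values[fb]}).dropna()
            rec["n"] = len(sub)
            a, b = sub["a"].to_numpy(), sub["b"].to_numpy()
            if len(sub) >= 3 and a.std() > 0 and b.std() > 0:
                r, p = pearsonr(a, b)
                rec["r"], rec["p"] = float(r), float(p)
        rows.append(rec)
    return pd.DataFrame(rows)
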