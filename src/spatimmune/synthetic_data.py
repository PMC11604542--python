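"""Synthetic cohorts with known ground truth.

Two generators:

* :func:`simulate_cohort` — a cell-level generator.  Each patient contributes
  15-20 ROIs per staining panel; cells are drawn per phenotype with per-patient
  abundance heterogeneity, co-flags (Ki67, PD-1, PD-L1) are assigned with
  per-patient positivity rates, and chosen cell-type pairs are placed as
  colocalized (Thomas-type parent/offspring cluster process with dispersion σ),
  independent (homogeneous uniform) or segregated (disjoint window halves)
  patterns.  Pathologic complete response is drawn from a logistic model on the
  *realized*, cohort-standardized feature values, so coefficients are scale-free
  and downstream recovery is testable against known signs.

* :func:`simulate_feature_matrix` — a patient-level shortcut that draws the
  biomarker matrix directly from a Gaussian model with the same logistic
  response link.  It is the workhorse for statistical calibration and power
  simulations where thousands of replicate screens are needed and the spatial
  generative detail is irrelevant.

All randomness flows from a single integer seed; per-(patient, ROI, panel)
substreams are derived by seeding from the tuple, so any subset of patients is
reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_table import FLAG_PREFIX, CellTable
from .density_features import pdl1_scores, cell_fractions
from .registries import (
    DEFAULT_POPULATIONS,
    DEFAULT_RPPA_ENDPOINTS,
    DEFAULT_SIGNATURES,
    DEFAULT_MH_PAIRS,
    DEFAULT_SPS_PAIRS,
    PANEL_PHENOTYPES,
    all_feature_names,
)
from .spatial_metrics import mh_features, sps_features

log = logging.getLogger(__name__)

MODES = ("colocalized", "independent", "segregated")

#: expected cells per ROI by phenotype, per panel (tumor-rich fields with a
#: moderately infiltrated stroma; immune abundances get per-patient multipliers)
DEFAULT_INTENSITIES: dict[str, dict[str, float]] = {
    "P1": {"Tm": 120.0, "T": 30.0, "Treg": 8.0, "B": 12.0, "Mast": 4.0, "other": 40.0},
    "P2": {"Tm": 120.0, "Tc": 18.0, "CD8nT": 20.0, "Mac": 15.0, "other": 45.0},
}

_IMMUNE_PHENOS = {
    "P1": ("T", "Treg", "B", "Mast"),
    "P2": ("Tc", "CD8nT", "Mac"),
}


@dataclass
class PairMode:
    """Spatial placement mode for one (type_a, type_b) pair of spatial types.

    ``sigma`` is the cluster dispersion in μm for the colocalized mode; if
    ``sigma_range = (lo, hi)`` is given, each patient draws its own σ
    log-uniformly, creating between-patient colocalization variance.
    """

    mode: str = "independent"
    sigma: float = 30.0
    sigma_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class SimulationConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the biomarker cohort the pipeline targets: ~100 patients,
    two receptor subtypes (HR+HER2- slightly more frequent than TN), a
    pembrolizumab and a control arm, 15-20 ROIs per patient and panel on
    600 × 450 μm fields.
    """

    n_patients: int = 98
    subtype_props: dict[str, float] = field(
        default_factory=lambda: {"HR+HER2-": 0.55, "TN": 0.45})
    arm_props: dict[str, float] = field(
        default_factory=lambda: {"pembro": 0.55, "control": 0.45})
    rois_per_patient: tuple[int, int] = (15, 20)
    roi_width: float = 600.0
    roi_height: float = 450.0
    phenotype_intensities: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(v) for p, v in DEFAULT_INTENSITIES.items()})
    #: per-patient lognormal sd of the shared immune-abundance multiplier
    immune_lognorm_sigma: float = 0.7
    #: co-flag positivity: per-patient rate ~ Beta(a, b)
    flag_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"Ki67": (2.0, 10.0), "PD1": (1.5, 12.0),
                                 "PDL1": (1.5, 12.0)})
    pair_modes: dict[tuple[str, str], PairMode] = field(default_factory=dict)
    response_coefs: dict[str, float] = field(default_factory=dict)
    #: additional per-feature coefficients active in the pembro arm only
    arm_interaction_coefs: dict[str, float] = field(default_factory=dict)
    response_intercept: float = -1.0
    seed: int = 0

    def __post_init__(self):
        for name, props in (("subtype_props", self.subtype_props),
                            ("arm_props", self.arm_props)):
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(v < 0 for v in props.values()):
                raise ValueError(f"{name} must be nonnegative")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.rois_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("rois_per_patient must be an increasing range >= 1")
        if min(self.roi_width, self.roi_height) <= 0:
            raise ValueError("ROI dimensions must be positive")


@dataclass
class GroundTruth:
    """What the simulator knows: one record per patient."""

    feature_values: pd.DataFrame  # realized response-model features per patient
    response_coefs: dict[str, float]
    arm_interaction_coefs: dict[str, float]
    response_intercept: float
    pair_modes: dict[tuple[str, str], PairMode]
    pair_sigmas: pd.DataFrame | None = None  # per-patient σ where sampled


# ---------------------------------------------------------------------------
# Point-pattern primitives
# ---------------------------------------------------------------------------

def _substream(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic substream from a global seed and integer keys."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def simulate_pair_pattern(n_a: int, n_b: int, window: tuple[float, float],
                          mode: str, sigma: float = 30.0,
                          seed: int | np.random.Generator = 0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Generate two point sets in a rectangular window under a placement mode.

    * ``colocalized`` — both sets are offspring of shared uniformly placed parent
      points with isotropic Gaussian dispersion σ (Thomas-type cluster process);
      offspring wrap toroidally at the window edges, keeping the marginal
      intensity uniform (no boundary pile-up) so that σ → ∞ recovers the
      independent-uniform case.
    * ``independent`` — two independent homogeneous uniform patterns.
    * ``segregated`` — the a-set confined to the left half of the window, the
      b-set to the right half.

    Returns two (n, 2) arrays of μm coordinates inside the window.
    """
    if n_a < 0 or n_b < 0:
        raise ValueError("counts must be nonnegative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    w, h = float(window[0]), float(window[1])
    if w <= 0 or h <= 0:
        raise ValueError("window must be nonempty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def uniform(n, x_lo=0.0, x_hi=w):
        pts = np.empty((n, 2))
        pts[:, 0] = rng.uniform(x_lo, x_hi, size=n)
        pts[:, 1] = rng.uniform(0.0, h, size=n)
        return pts

    if mode == "independent":
        return uniform(n_a), uniform(n_b)
    if mode == "segregated":
        return uniform(n_a, 0.0, w / 2), uniform(n_b, w / 2, w)
    # colocalized: shared parents, Gaussian offspring dispersion
    n_total = n_a + n_b
    if n_total == 0:
        return np.empty((0, 2)), np.empty((0, 2))
    n_parents = max(1, int(round(n_total / 20)))
    parents = uniform(n_parents)

    def offspring(n):
        idx = rng.integers(0, n_parents, size=n)
        pts = parents[idx] + rng.normal(scale=sigma, size=(n, 2))
        pts[:, 0] %= w
        pts[:, 1] %= h
        return pts

    return offspring(n_a), offspring(n_b)


# ---------------------------------------------------------------------------
# Cell-level cohort
# ---------------------------------------------------------------------------

def _resolve_pair_members(pair: tuple[str, str]):
    """Phenotype/flag specs of the two spatial types in a pair mode."""
    from .registries import SPATIAL_TYPES

    for t in pair:
        if t not in SPATIAL_TYPES:
            raise ValueError(f"pair mode references unknown spatial type {t!r}")
    a, b = SPATIAL_TYPES[pair[0]], SPATIAL_TYPES[pair[1]]
    if a.panel != b.panel:
        raise ValueError(f"pair {pair} spans panels {a.panel}/{b.panel}")
    return a, b


def _simulate_roi(rng, config, panel, patient_ctx, roi_id):
    """One ROI of one panel: returns a cells DataFrame."""
    window = (config.roi_width, config.roi_height)
    intensities = config.phenotype_intensities[panel]
    mult = patient_ctx["multipliers"][panel]
    counts = {ph: int(rng.poisson(lam * mult.get(ph, 1.0)))
              for ph, lam in intensities.items()}
    n_total = sum(counts.values())
    phenos = np.repeat(list(counts), list(counts.values()))
    # co-flags with per-patient positivity rates
    flags = {}
    from .registries import PANEL_COFLAGS

    for flag in PANEL_COFLAGS[panel]:
        rate = patient_ctx["flag_rates"][flag]
        applies = np.isin(phenos, _flag_carriers(panel, flag))
        flags[flag] = applies & (rng.uniform(size=n_total) < rate)

    xy = np.empty((n_total, 2))
    placed = np.zeros(n_total, dtype=bool)
    # spatial pair modes within this panel
    for pair, pm in config.pair_modes.items():
        spec_a, spec_b = _resolve_pair_members(pair)
        if spec_a.panel != panel:
            continue
        mask_a = _member_mask(phenos, flags, spec_a) & ~placed
        mask_b = _member_mask(phenos, flags, spec_b) & ~placed & ~mask_a
        sigma = patient_ctx["pair_sigmas"].get(pair, pm.sigma)
        pts_a, pts_b = simulate_pair_pattern(
            int(mask_a.sum()), int(mask_b.sum()), window, pm.mode, sigma, rng)
        xy[mask_a] = pts_a
        xy[mask_b] = pts_b
        placed |= mask_a | mask_b
    rest = ~placed
    xy[rest, 0] = rng.uniform(0, window[0], size=int(rest.sum()))
    xy[rest, 1] = rng.uniform(0, window[1], size=int(rest.sum()))

    df = pd.DataFrame({
        "patient_id": patient_ctx["patient_id"],
        "roi_id": roi_id,
        "panel": panel,
        "x_um": xy[:, 0],
        "y_um": xy[:, 1],
        "phenotype": phenos,
    })
    for flag, vals in flags.items():
        df[FLAG_PREFIX + flag] = vals
    return df


def _flag_carriers(panel: str, flag: str) -> tuple[str, ...]:
    """Phenotypes on which a co-flag can occur."""
    if flag == "Ki67":
        return ("Tm", "T", "Treg", "B")
    if flag == "PD1":
        return ("Tc", "CD8nT")
    if flag == "PDL1":
        return PANEL_PHENOTYPES["P2"]
    raise ValueError(f"unknown flag {flag!r}")


def _member_mask(phenos, flags, spec) -> np.ndarray:
    mask = np.isin(phenos, spec.phenotypes)
    for flag, wanted in spec.flags.items():
        mask &= flags[flag] == wanted
    return mask


def _mif_feature_subset(table: CellTable, names: list[str]) -> pd.DataFrame:
    """Compute only the mIF features named (density, PD-L1 score, MH, SPS)."""
    pieces = []
    pops = [p for p in DEFAULT_POPULATIONS if p.name in names]
    if pops:
        pieces.append(cell_fractions(table, tuple(pops)))
    if {"TPS", "CPS"} & set(names):
        pieces.append(pdl1_scores(table)[[n for n in ("TPS", "CPS") if n in names]])
    mh = [p for p in DEFAULT_MH_PAIRS if p.name in names]
    if mh:
        pieces.append(mh_features(table, tuple(mh)))
    sp = [p for p in DEFAULT_SPS_PAIRS if p.name in names]
    if sp:
        pieces.append(sps_features(table, tuple(sp)))
    if not pieces:
        return pd.DataFrame(index=pd.Index([], name="patient_id"))
    out = pieces[0]
    for piece in pieces[1:]:
        out = out.join(piece, how="outer")
    return out


def _zscore(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=0)
    if not np.isfinite(sd) or sd == 0:
        return col * 0.0
    return (col - col.mean()) / sd


def simulate_cohort(config: SimulationConfig):
    """Simulate a full multi-platform cohort.

    Returns ``(cell_table, expression, rppa, clinical, ground_truth)`` where
    ``expression`` is a genes × patients log2-scale matrix (synthetic signature
    gene lists: five genes per signature named ``<sig>_g<k>``), ``rppa`` is an
    endpoints × patients matrix, and ``clinical`` has one row per patient with
    arm, HR/HER2 status, subtype, covariates and the pCR outcome drawn from the
    configured logistic model on cohort-standardized realized features.
    """
    unknown = [n for n in {**config.response_coefs, **config.arm_interaction_coefs}
               if n not in all_feature_names()]
    if unknown:
        raise ValueError(f"response_coefs name unknown features: {sorted(unknown)}")

    master = _substream(config.seed, 0)
    n = config.n_patients
    patient_ids = [f"PT{i:04d}" for i in range(1, n + 1)]
    subtypes = master.choice(list(config.subtype_props),
                             p=list(config.subtype_props.values()), size=n)
    arms = master.choice(list(config.arm_props),
                         p=list(config.arm_props.values()), size=n)

    frames, pair_sigma_rows = [], []
    for i, pid in enumerate(patient_ids):
        prng = _substream(config.seed, 1, i)
        immune_mult = float(prng.lognormal(mean=0.0, sigma=config.immune_lognorm_sigma))
        multipliers = {}
        for panel, intensities in config.phenotype_intensities.items():
            multipliers[panel] = {
                ph: (immune_mult if ph in _IMMUNE_PHENOS.get(panel, ()) else 1.0)
                * float(prng.lognormal(0.0, 0.3))
                for ph in intensities
            }
        flag_rates = {flag: float(prng.beta(a, b))
                      for flag, (a, b) in config.flag_beta.items()}
        pair_sigmas = {}
        for pair, pm in config.pair_modes.items():
            if pm.sigma_range is not None:
                lo, hi = pm.sigma_range
                pair_sigmas[pair] = float(np.exp(prng.uniform(np.log(lo), np.log(hi))))
        if pair_sigmas:
            pair_sigma_rows.append({"patient_id": pid,
                                    **{f"{a}_{b}": s for (a, b), s in pair_sigmas.items()}})
        ctx = {"patient_id": pid, "multipliers": multipliers,
               "flag_rates": flag_rates, "pair_sigmas": pair_sigmas}
        n_rois = int(prng.integers(config.rois_per_patient[0],
                                   config.rois_per_patient[1] + 1))
        for panel_idx, panel in enumerate(sorted(config.phenotype_intensities)):
            for r in range(n_rois):
                rng = _substream(config.seed, 2, i, r, panel_idx)
                frames.append(_simulate_roi(rng, config, panel, ctx,
                                            roi_id=f"{pid}_{panel}_R{r:02d}"))
    cells = pd.concat(frames, ignore_index=True)
    # co-flag columns exist only for the panel that stains them; absent = negative
    for col in cells.columns:
        if col.startswith(FLAG_PREFIX):
            cells[col] = cells[col].where(cells[col].notna(), False).astype(bool)
    windows = {r: (config.roi_width, config.roi_height)
               for r in cells["roi_id"].unique()}
    table = CellTable(cells, windows)

    # -- expression and RPPA matrices with per-patient latents ---------------
    erng = _substream(config.seed, 3)
    sig_latents = pd.DataFrame(
        erng.normal(size=(n, len(DEFAULT_SIGNATURES))),
        index=patient_ids, columns=list(DEFAULT_SIGNATURES))
    gene_rows = {}
    for sig in DEFAULT_SIGNATURES:
        for k in range(1, 6):
            gene_rows[f"{sig}_g{k}"] = (
                9.5 + sig_latents[sig].to_numpy() + erng.normal(scale=0.5, size=n))
    expression = pd.DataFrame(gene_rows, index=patient_ids).T
    expression.index.name = "gene"

    rppa_latents = pd.DataFrame(
        erng.normal(size=(n, len(DEFAULT_RPPA_ENDPOINTS))),
        index=patient_ids, columns=list(DEFAULT_RPPA_ENDPOINTS))
    rppa = rppa_latents.T.copy()
    rppa.index.name = "endpoint"

    # -- response model on realized, cohort-standardized features ------------
    model_features = sorted({**config.response_coefs, **config.arm_interaction_coefs})
    mif_names = [f for f in model_features
                 if f not in DEFAULT_SIGNATURES and f not in DEFAULT_RPPA_ENDPOINTS]
    realized = _mif_feature_subset(table, mif_names) if mif_names else \
        pd.DataFrame(index=pd.Index(patient_ids, name="patient_id"))
    realized = realized.reindex(patient_ids)
    for f in model_features:
        if f in DEFAULT_SIGNATURES:
            realized[f] = sig_latents[f]
        elif f in DEFAULT_RPPA_ENDPOINTS:
            realized[f] = rppa_latents[f]

    logit = np.full(n, config.response_intercept)
    is_pembro = (arms == "pembro").astype(float)
    for f, coef in config.response_coefs.items():
        logit += coef * _zscore(realized[f]).fillna(0.0).to_numpy()
    for f, coef in config.arm_interaction_coefs.items():
        logit += coef * is_pembro * _zscore(realized[f]).fillna(0.0).to_numpy()
    orng = _substream(config.seed, 4)
    pcr = (orng.uniform(size=n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    clinical = pd.DataFrame({
        "patient_id": patient_ids,
        "arm": arms,
        "subtype": subtypes,
        "HR": (subtypes == "HR+HER2-").astype(int),
        "HER2": 0,
        "pCR": pcr,
        "age": np.round(orng.normal(50, 10, size=n), 1),
        "mri_ld_cm": np.round(orng.lognormal(1.2, 0.4, size=n), 2),
        "palpable_nodes": orng.integers(0, 2, size=n),
    }).set_index("patient_id")

    truth = GroundTruth(
        feature_values=realized[model_features] if model_features else realized,
        response_coefs=dict(config.response_coefs),
        arm_interaction_coefs=dict(config.arm_interaction_coefs),
        response_intercept=config.response_intercept,
        pair_modes=dict(config.pair_modes),
        pair_sigmas=pd.DataFrame(pair_sigma_rows).set_index("patient_id")
        if pair_sigma_rows else None,
    )
    return table, expression, rppa, clinical, truth


# ---------------------------------------------------------------------------
# Patient-level fast path
# ---------------------------------------------------------------------------

def simulate_feature_matrix(n_patients: int,
                            response_coefs: dict[str, float] | None = None,
                            arm_interaction_coefs: dict[str, float] | None = None,
                            response_intercept: float = -1.0,
                            feature_names: list[str] | None = None,
                            subtype_props: dict[str, float] | None = None,
                            arm_props: dict[str, float] | None = None,
                            seed: int = 0):
    """Draw a biomarker matrix directly: features ~ N(0, 1), logistic response.

    Patient-level shortcut for calibration, FDR and power simulations; skips the
    spatial generative model entirely.  Returns ``(features, clinical)`` frames
    indexed by patient.
    """
    response_coefs = response_coefs or {}
    arm_interaction_coefs = arm_interaction_coefs or {}
    names = feature_names if feature_names is not None else all_feature_names()
    unknown = [f for f in {**response_coefs, **arm_interaction_coefs}
               if f not in names]
    if unknown:
        raise ValueError(f"response_coefs name unknown features: {sorted(unknown)}")
    subtype_props = subtype_props or {"HR+HER2-": 0.55, "TN": 0.45}
    arm_props = arm_props or {"pembro": 0.55, "control": 0.45}
    rng = np.random.default_rng(seed)
    pids = [f"PT{i:04d}" for i in range(1, n_patients + 1)]
    feats = pd.DataFrame(rng.normal(size=(n_patients, len(names))),
                         index=pd.Index(pids, name="patient_id"), columns=names)
    arms = rng.choice(list(arm_props), p=list(arm_props.values()), size=n_patients)
    subtypes = rng.choice(list(subtype_props), p=list(subtype_props.values()),
                          size=n_patients)
    logit = np.full(n_patients, response_intercept)
    for f, c in response_coefs.items():
        logit += c * feats[f].to_numpy()
    is_pembro = (arms == "pembro").astype(float)
    for f, c in arm_interaction_coefs.items():
        logit += c * is_pembro * feats[f].to_numpy()
    pcr = (rng.uniform(size=n_patients) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    clinical = pd.DataFrame({
        "arm": arms, "subtype": subtypes,
        "HR": (subtypes == "HR+HER2-").astype(int), "HER2": 0, "pCR": pcr,
    }, index=pd.Index(pids, name="patient_id"))
    return feats, clinical
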