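"""Spatial colocalization and proximity metrics for mIF point patterns.

Two families of per-patient spatial features:

* **Morisita-Horn (MH) colocalization** — each ROI is divided into non-overlapping
  200 μm × 200 μm quadrat squares, cells of each type are counted per square, and
  the MH similarity index of the two count vectors measures colocalization: 0 for
  fully segregated types (no shared squares), 1 when both types have proportional
  counts in every square.  Counts are pooled (square vectors concatenated) across
  a patient's ROIs before one MH evaluation.

* **Nearest-neighbor proximity (SPS)** — G(r), the fraction of type-a cells whose
  nearest type-b cell lies within radius r, is evaluated per ROI on a fine radius
  grid from 0 to 20 μm.  The area under G(r), normalized by the 20 μm horizon,
  averaged over the patient's ROIs, is the spatial proximity score — a unitless
  number in [0, 1], directional in (a, b).

No edge correction is applied to G(r): the score is the raw empirical fraction,
and the 20 μm horizon is small relative to the ROI field, so boundary effects are
minor; this is a deliberate divergence from the defaults of general-purpose
point-pattern software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cell_table import CellTable
from .registries import (
    DEFAULT_MH_PAIRS,
    DEFAULT_SPS_PAIRS,
    SPATIAL_TYPES,
    SpatialPair,
)

log = logging.getLogger(__name__)

DEFAULT_SQUARE_UM = 200.0
DEFAULT_MAX_RADIUS_UM = 20.0
DEFAULT_RADIUS_STEP_UM = 0.25
#: an MH pair is reported for a patient only with at least this many cells of
#: each type patient-wide (configurable; logged when applied)
DEFAULT_MIN_CELLS_MH = 10


# ---------------------------------------------------------------------------
# Quadrat counting
# ---------------------------------------------------------------------------

def quadrat_counts(points: np.ndarray, window: tuple[float, float],
                   square: float = DEFAULT_SQUARE_UM) -> np.ndarray:
    """Count points per non-overlapping square of side ``square`` μm.

    The grid is anchored at the ROI origin; membership is half-open,
    ``[k*s, (k+1)*s)`` in each axis, so a point at exactly x = 200 falls in
    column index 1.  Partial squares at the right/bottom edges are retained.
    Returns an (ny, nx) integer array covering the full window.
    """
    if square <= 0:
        raise ValueError("square side must be positive")
    w, h = float(window[0]), float(window[1])
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) and ((pts < 0).any() or (pts[:, 0] > w).any() or (pts[:, 1] > h).any()):
        raise ValueError("point outside ROI window")
    nx = max(int(np.ceil(w / square)), 1)
    ny = max(int(np.ceil(h / square)), 1)
    counts = np.zeros((ny, nx), dtype=np.int64)
    if len(pts):
        ix = np.minimum((pts[:, 0] // square).astype(int), nx - 1)
        iy = np.minimum((pts[:, 1] // square).astype(int), ny - 1)
        np.add.at(counts, (iy, ix), 1)
    return counts


# ---------------------------------------------------------------------------
# Morisita-Horn index
# ---------------------------------------------------------------------------

def morisita_horn(a_counts: np.ndarray, b_counts: np.ndarray) -> float:
    """Morisita-Horn similarity of two quadrat count vectors.

    MH = 2 Σᵢ aᵢbᵢ / [(Σᵢaᵢ²/A² + Σᵢbᵢ²/B²) · A · B] with A = Σaᵢ, B = Σbᵢ.
    Symmetric in its arguments; 0 for disjoint supports, 1 when the two vectors
    are proportional.  Raises on negative counts or a zero total.
    """
    a = np.asarray(a_counts, dtype=float).ravel()
    b = np.asarray(b_counts, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("count vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be nonnegative")
    A, B = a.sum(), b.sum()
    if A == 0 or B == 0:
        raise ValueError("each type needs a positive total count")
    num = 2.0 * float(a @ b)
    den = (float(a @ a) / A**2 + float(b @ b) / B**2) * A * B
    return num / den


def _type_mask(df: pd.DataFrame, type_name: str) -> np.ndarray:
    """Boolean mask selecting cells of a spatial type within a panel frame."""
    spec = SPATIAL_TYPES[type_name]
    mask = df["phenotype"].isin(spec.phenotypes).to_numpy()
    for flag, wanted in spec.flags.items():
        col = "flag_" + flag
        if col not in df.columns:
            return np.zeros(len(df), dtype=bool)
        mask &= df[col].to_numpy() == wanted
    return mask


def mh_features(table: CellTable,
                pairs: tuple[SpatialPair, ...] = DEFAULT_MH_PAIRS,
                square: float = DEFAULT_SQUARE_UM,
                min_cells: int = DEFAULT_MIN_CELLS_MH,
                per_roi_average: bool = False) -> pd.DataFrame:
    """Per-patient MH index for each configured unordered pair.

    By default quadrat count vectors are concatenated across all of a patient's
    ROIs of the pair's panel before a single MH evaluation; ``per_roi_average``
    instead averages per-ROI MH values (sensitivity analysis).  A pair is
    missing (NaN) for a patient with fewer than ``min_cells`` cells of either
    type patient-wide.
    """
    rows = {}
    for patient, pdf in table.cells.groupby("patient_id", observed=True):
        feats = {}
        for pair in pairs:
            panel = pair.panel
            sub = pdf[pdf["panel"] == panel]
            mask_a = _type_mask(sub, pair.type_a)
            mask_b = _type_mask(sub, pair.type_b)
            if mask_a.sum() < min_cells or mask_b.sum() < min_cells:
                feats[pair.name] = np.nan
                continue
            vec_a, vec_b, per_roi = [], [], []
            for roi, rdf in sub.groupby("roi_id", observed=True):
                win = table.windows[roi]
                rmask_a = _type_mask(rdf, pair.type_a)
                rmask_b = _type_mask(rdf, pair.type_b)
                xy = rdf[["x_um", "y_um"]].to_numpy(dtype=float)
                qa = quadrat_counts(xy[rmask_a], win, square).ravel()
                qb = quadrat_counts(xy[rmask_b], win, square).ravel()
                vec_a.append(qa)
                vec_b.append(qb)
                if per_roi_average and qa.sum() > 0 and qb.sum() > 0:
                    per_roi.append(morisita_horn(qa, qb))
            if per_roi_average:
                feats[pair.name] = float(np.mean(per_roi)) if per_roi else np.nan
            else:
                feats[pair.name] = morisita_horn(
                    np.concatenate(vec_a), np.concatenate(vec_b)
                )
        rows[patient] = feats
    out = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    out = out.reindex(columns=[p.name for p in pairs])
    out.index.name = "patient_id"
    return out


# ---------------------------------------------------------------------------
# Nearest-neighbor distribution function and SPS
# ---------------------------------------------------------------------------

@dataclass
class GCurve:
    """Empirical nearest-neighbor distribution function for one ROI.

    ``g[i]`` is the fraction of a-cells whose nearest b-cell lies within
    ``radii[i]`` μm.  ``g`` is nondecreasing and identically 0 when no b-cells
    exist.
    """

    radii: np.ndarray
    g: np.ndarray
    roi_id: str = ""
    n_a: int = 0
    n_b: int = 0

    def auc_normalized(self) -> float:
        """Trapezoid area under G(r), divided by the radius horizon."""
        return float(np.trapezoid(self.g, self.radii) / (self.radii[-1] - self.radii[0]))


def default_radii(max_radius: float = DEFAULT_MAX_RADIUS_UM,
                  step: float = DEFAULT_RADIUS_STEP_UM) -> np.ndarray:
    return np.arange(0.0, max_radius + step / 2, step)


def g_curve(a_points: np.ndarray, b_points: np.ndarray,
            radii: np.ndarray | None = None, roi_id: str = "") -> GCurve:
    """Exact-nearest-neighbor G(r) for a-cells relative to b-cells.

    Uses a KD-tree for the nearest-neighbor queries; no edge correction.
    Raises on an empty a set (curve undefined); an empty b set gives G ≡ 0.
    """
    if radii is None:
        radii = default_radii()
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    a = np.asarray(a_points, dtype=float).reshape(-1, 2)
    b = np.asarray(b_points, dtype=float).reshape(-1, 2)
    if len(a) == 0:
        raise ValueError("G(r) undefined with no a-cells")
    if len(b) == 0:
        return GCurve(radii, np.zeros_like(radii), roi_id, len(a), 0)
    dists, _ = cKDTree(b).query(a, k=1)
    g = np.mean(dists[None, :] <= radii[:, None], axis=1)
    return GCurve(radii, g, roi_id, len(a), len(b))


def sps(curves: list[GCurve]) -> float:
    """Spatial proximity score: mean normalized AUC over per-ROI G-curves.

    ROIs without a defined curve (no a-cells) simply do not contribute; raises
    if no curve is defined at all.  The paper-scale raw AUC in μm is this score
    times the 20 μm horizon.
    """
    if not curves:
        raise ValueError("no defined G-curves; SPS is missing")
    return float(np.mean([c.auc_normalized() for c in curves]))


def sps_features(table: CellTable,
                 pairs: tuple[SpatialPair, ...] = DEFAULT_SPS_PAIRS,
                 radii: np.ndarray | None = None) -> pd.DataFrame:
    """Per-patient SPS for each configured ordered pair.

    For pair A_B, each ROI with ≥1 A-cell contributes a G-curve of A-to-nearest-B
    distances (G ≡ 0 when the ROI has no B-cells); the SPS is the unweighted mean
    of normalized AUCs over contributing ROIs.  Missing (NaN) when no ROI has any
    A-cells.
    """
    if radii is None:
        radii = default_radii()
    rows = {}
    for patient, pdf in table.cells.groupby("patient_id", observed=True):
        feats = {}
        for pair in pairs:
            sub = pdf[pdf["panel"] == pair.panel]
            curves = []
            for roi, rdf in sub.groupby("roi_id", observed=True):
                xy = rdf[["x_um", "y_um"]].to_numpy(dtype=float)
                mask_a = _type_mask(rdf, pair.type_a)
                if not mask_a.any():
                    continue
                mask_b = _type_mask(rdf, pair.type_b)
                curves.append(g_curve(xy[mask_a], xy[mask_b], radii, roi_id=roi))
            feats[pair.name] = sps(curves) if curves else np.nan
        rows[patient] = feats
    out = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    out = out.reindex(columns=[p.name for p in pairs])
    out.index.name = "patient_id"
    return out
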