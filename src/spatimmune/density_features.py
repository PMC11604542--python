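"""Cell-population density features and PD-L1 scores.

Fractions are percent of total cells, pooled (cell-weighted) across all ROIs of
the relevant panel per patient — not averaged per-ROI.  Panel-1 and panel-2
fractions use their own panel's total-cell denominator.

PD-L1 scoring follows the clinical conventions on panel 2:

* TPS = 100 × (PD-L1+ tumor cells) / (tumor cells)
* CPS = 100 × (PD-L1+ tumor cells + PD-L1+ immune cells) / (tumor cells),
  where immune = Tc + CD8- T + macrophages.  CPS ≥ TPS always; CPS is not
  capped at 100 (some clinical conventions cap; no cap is applied here and the
  choice is logged per run).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cell_table import FLAG_PREFIX, CellTable
from .registries import DEFAULT_POPULATIONS, Population

log = logging.getLogger(__name__)

P2_IMMUNE_PHENOTYPES = ("Tc", "CD8nT", "Mac")


class MissingDataError(ValueError):
    """A feature is undefined for a patient (e.g. zero denominator)."""


def _population_mask(df: pd.DataFrame, pop: Population) -> np.ndarray:
    mask = df["phenotype"].isin(pop.phenotypes).to_numpy()
    for flag, wanted in pop.flags.items():
        col = FLAG_PREFIX + flag
        if col not in df.columns:
            return np.zeros(len(df), dtype=bool)
        mask &= df[col].to_numpy() == wanted
    return mask


def cell_fractions(table: CellTable,
                   populations: tuple[Population, ...] = DEFAULT_POPULATIONS
                   ) -> pd.DataFrame:
    """Per-patient population fractions (percent of total cells, per panel).

    For each registered population: 100 × (cells in population, pooled over the
    patient's ROIs of that panel) / (total cells in those ROIs).  A patient with
    no cells in a population's panel gets NaN for that population (missing, not
    zero).
    """
    rows = {}
    for patient, pdf in table.cells.groupby("patient_id", observed=True):
        feats = {}
        totals = pdf.groupby("panel", observed=True).size()
        for pop in populations:
            total = int(totals.get(pop.panel, 0))
            if total == 0:
                feats[pop.name] = np.nan
                continue
            sub = pdf[pdf["panel"] == pop.panel]
            feats[pop.name] = 100.0 * float(_population_mask(sub, pop).sum()) / total
        rows[patient] = feats
    out = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    out = out.reindex(columns=[p.name for p in populations])
    out.index.name = "patient_id"
    return out


def _pdl1_counts(df: pd.DataFrame) -> tuple[int, int, int]:
    """(tumor cells, PD-L1+ tumor cells, PD-L1+ immune cells) on a panel-2 frame."""
    col = FLAG_PREFIX + "PDL1"
    pdl1 = df[col].to_numpy() if col in df.columns else np.zeros(len(df), dtype=bool)
    tumor = (df["phenotype"] == "Tm").to_numpy()
    immune = df["phenotype"].isin(P2_IMMUNE_PHENOTYPES).to_numpy()
    return int(tumor.sum()), int((tumor & pdl1).sum()), int((immune & pdl1).sum())


def tps(table: CellTable, patient_id: str | None = None) -> float:
    """Tumor proportion score from panel 2 for one patient's cells."""
    df = table.cells if patient_id is None else table.subset(patient_id).cells
    n_tm, n_tm_pos, _ = _pdl1_counts(df[df["panel"] == "P2"])
    if n_tm == 0:
        raise MissingDataError("TPS undefined: no tumor cells in panel 2")
    return 100.0 * n_tm_pos / n_tm


def cps(table: CellTable, patient_id: str | None = None) -> float:
    """Combined positive score from panel 2 for one patient's cells."""
    df = table.cells if patient_id is None else table.subset(patient_id).cells
    n_tm, n_tm_pos, n_im_pos = _pdl1_counts(df[df["panel"] == "P2"])
    if n_tm == 0:
        raise MissingDataError("CPS undefined: no tumor cells in panel 2")
    return 100.0 * (n_tm_pos + n_im_pos) / n_tm


def pdl1_scores(table: CellTable) -> pd.DataFrame:
    """Per-patient TPS and CPS (NaN where no tumor cells in panel 2)."""
    log.info("CPS convention: uncapped (no 100 ceiling applied)")
    rows = {}
    for patient, pdf in table.cells.groupby("patient_id", observed=True):
        n_tm, n_tm_pos, n_im_pos = _pdl1_counts(pdf[pdf["panel"] == "P2"])
        if n_tm == 0:
            rows[patient] = {"TPS": np.nan, "CPS": np.nan}
        else:
            rows[patient] = {
                "TPS": 100.0 * n_tm_pos / n_tm,
                "CPS": 100.0 * (n_tm_pos + n_im_pos) / n_tm,
            }
    out = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    out = out.reindex(columns=["TPS", "CPS"])
    out.index.name = "patient_id"
    return out


def density_features(table: CellTable,
                     populations: tuple[Population, ...] = DEFAULT_POPULATIONS
                     ) -> pd.DataFrame:
    """All density-family features: population fractions plus TPS/CPS."""
    return cell_fractions(table, populations).join(pdl1_scores(table))
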