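"""Per-cell phenotype tables from two mIF staining panels.

A :class:`CellTable` holds one cohort's segmented cells — one row per cell with
patient, ROI, panel, x/y position in μm and a phenotype label — together with a
registry of ROI field dimensions.  Coordinates are in μm with origin at the ROI
top-left; there are no global tissue coordinates because all analyses are per-ROI.

Also provides a density-valley marker-gating operator (a deliberately simple
stand-in for automated cytometry-style gating) and rule-based phenotype
derivation from marker flags.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

from .registries import PANEL_COFLAGS, PANEL_PHENOTYPES, PANELS, PHENOTYPE_RULES

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("patient_id", "roi_id", "panel", "x_um", "y_um")

FLAG_PREFIX = "flag_"
INTENSITY_PREFIX = "int_"


class CellTableError(ValueError):
    """Malformed cell table input."""


@dataclass
class CellTable:
    """Cohort cell table: a cells DataFrame plus ROI window registry.

    Parameters
    ----------
    cells
        One row per cell with columns ``patient_id, roi_id, panel, x_um, y_um``,
        optionally ``phenotype``, boolean ``flag_<MARKER>`` columns and float
        ``int_<MARKER>`` columns.
    windows
        Mapping ``roi_id -> (width_um, height_um)``; every ROI appearing in
        ``cells`` must be registered.
    """

    cells: pd.DataFrame
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        df = self.cells
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise CellTableError(f"missing required column {col!r}")
        bad_panel = ~df["panel"].isin(PANELS)
        if bad_panel.any():
            row = int(np.flatnonzero(bad_panel.to_numpy())[0])
            raise CellTableError(
                f"row {row}: unknown panel {df['panel'].iloc[row]!r} (expected P1/P2)"
            )
        xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
        bad = ~np.isfinite(xy) | (xy < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.any(axis=1))[0])
            raise CellTableError(f"row {row}: non-finite or negative coordinate")
        missing = set(df["roi_id"].unique()) - set(self.windows)
        if missing:
            raise CellTableError(f"unregistered ROI ids: {sorted(missing)[:5]}")
        if "phenotype" in df.columns:
            for panel, sub in df.groupby("panel", observed=True):
                legal = set(PANEL_PHENOTYPES[panel])
                bad_ph = ~sub["phenotype"].isin(legal)
                if bad_ph.any():
                    lbl = sub["phenotype"][bad_ph].iloc[0]
                    row = sub.index[np.flatnonzero(bad_ph.to_numpy())[0]]
                    raise CellTableError(
                        f"row {row}: illegal phenotype {lbl!r} for panel {panel} "
                        f"(legal: {sorted(legal)})"
                    )

    # -- convenience --------------------------------------------------------
    def __len__(self) -> int:
        return len(self.cells)

    @property
    def marker_flags(self) -> list[str]:
        return [c[len(FLAG_PREFIX):] for c in self.cells.columns if c.startswith(FLAG_PREFIX)]

    @property
    def marker_intensities(self) -> list[str]:
        return [c[len(INTENSITY_PREFIX):] for c in self.cells.columns
                if c.startswith(INTENSITY_PREFIX)]

    def panel(self, panel: str) -> pd.DataFrame:
        """Cells of one staining panel."""
        return self.cells[self.cells["panel"] == panel]

    def subset(self, patient_id: str) -> "CellTable":
        sub = self.cells[self.cells["patient_id"] == patient_id]
        wins = {r: self.windows[r] for r in sub["roi_id"].unique()}
        return CellTable(sub.reset_index(drop=True), wins)

    def roi_counts(self) -> pd.DataFrame:
        """Number of ROIs per patient and panel."""
        return (
            self.cells.groupby(["patient_id", "panel"], observed=True)["roi_id"]
            .nunique()
            .rename("n_rois")
            .reset_index()
        )

    def equals(self, other: "CellTable") -> bool:
        a = self.cells.reset_index(drop=True)
        b = other.cells.reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return {k: tuple(v) for k, v in self.windows.items()} == {
            k: tuple(v) for k, v in other.windows.items()
        }


# ---------------------------------------------------------------------------
# I/O — delimited text, comma or tab auto-detected
# ---------------------------------------------------------------------------

_WINDOW_COLS = ("roi_w_um", "roi_h_um")


def read_cell_table(path, schema: dict[str, str] | None = None,
                    default_window: tuple[float, float] | None = None) -> CellTable:
    """Read a cell table from delimited text (comma or tab, auto-detected).

    Required columns (after renaming through ``schema``, a map from file column
    name to canonical name): ``patient_id, roi_id, panel, x_um, y_um``.  ROI
    window dimensions come from ``roi_w_um``/``roi_h_um`` columns if present,
    else from ``default_window``.
    """
    with open(path) as fh:
        head = fh.readline()
    sep = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","
    df = pd.read_csv(path, sep=sep)
    if schema:
        df = df.rename(columns=schema)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise CellTableError(f"file {path}: missing required column {col!r}")
    for col in ("x_um", "y_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CellTableError(
                f"file {path}: row {row}: non-numeric coordinate {df[col].iloc[row]!r}"
            )
        df[col] = coerced
    df["patient_id"] = df["patient_id"].astype(str)
    df["roi_id"] = df["roi_id"].astype(str)
    df["panel"] = df["panel"].astype(str)
    for col in df.columns:
        if col.startswith(FLAG_PREFIX):
            if df[col].dtype == object:
                df[col] = df[col].map(
                    {"True": True, "False": False, True: True, False: False,
                     1: True, 0: False})
                if df[col].isna().any():
                    row = int(np.flatnonzero(df[col].isna().to_numpy())[0])
                    raise CellTableError(
                        f"file {path}: row {row}: non-boolean value in {col}")
                df[col] = df[col].astype(bool)
            else:
                df[col] = df[col].astype(bool)
    if all(c in df.columns for c in _WINDOW_COLS):
        wins = (
            df.groupby("roi_id")[list(_WINDOW_COLS)].first()
            .apply(lambda r: (float(r.iloc[0]), float(r.iloc[1])), axis=1)
            .to_dict()
        )
        df = df.drop(columns=list(_WINDOW_COLS))
    elif default_window is not None:
        wins = {r: tuple(default_window) for r in df["roi_id"].unique()}
    else:
        raise CellTableError(
            f"file {path}: no roi_w_um/roi_h_um columns and no default_window given"
        )
    return CellTable(df.reset_index(drop=True), wins)


def write_cell_table(table: CellTable, path, sep: str = ",") -> None:
    """Write a cell table to delimited text, embedding ROI window columns.

    The output round-trips through :func:`read_cell_table` to an equal table.
    Panels are serialized as the literal strings "P1"/"P2".
    """
    df = table.cells.copy()
    df["roi_w_um"] = df["roi_id"].map(lambda r: table.windows[r][0])
    df["roi_h_um"] = df["roi_id"].map(lambda r: table.windows[r][1])
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Marker gating — density-valley threshold stand-in
# ---------------------------------------------------------------------------

def _valley_threshold(log_int: np.ndarray, grid_n: int = 512) -> float | None:
    """Deepest density minimum between the two largest modes of a log-intensity
    distribution, or None if the pooled distribution is effectively unimodal."""
    if np.ptp(log_int) < 1e-12:
        return None
    kde = gaussian_kde(log_int)
    grid = np.linspace(log_int.min(), log_int.max(), grid_n)
    dens = kde(grid)
    maxima = argrelextrema(dens, np.greater)[0]
    # include boundary modes
    if dens[0] > dens[1]:
        maxima = np.r_[0, maxima]
    if dens[-1] > dens[-2]:
        maxima = np.r_[maxima, grid_n - 1]
    if len(maxima) < 2:
        return None
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = sorted(top2)
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    if valley in (lo, hi):
        return None
    return float(grid[valley])


def gate_markers(table: CellTable, markers: list[str],
                 fallback_quantile: float = 0.99) -> CellTable:
    """Threshold marker intensities into boolean positivity flags.

    For each marker the pooled log-intensities across the whole cohort are
    thresholded at the deepest density minimum between the two largest KDE modes;
    cells with intensity strictly above the threshold are flagged positive.  If
    the distribution is unimodal the gate falls back to the ``fallback_quantile``
    of intensities (default 0.99) with a warning, so that near-degenerate
    markers yield (almost) no positives rather than arbitrary splits.

    Thresholds are reported through the module logger and returned on the table
    as ``table.gates`` (marker -> intensity threshold).
    """
    df = table.cells.copy()
    gates: dict[str, float] = {}
    for marker in markers:
        col = INTENSITY_PREFIX + marker
        if col not in df.columns:
            raise CellTableError(f"no intensity column for marker {marker!r}")
        intens = df[col].to_numpy(dtype=float)
        if (intens <= 0).any():
            raise CellTableError(f"marker {marker!r}: non-positive intensities")
        log_t = _valley_threshold(np.log(intens))
        if log_t is None:
            thr = float(np.quantile(intens, fallback_quantile))
            warnings.warn(
                f"marker {marker}: unimodal intensity distribution; falling back "
                f"to quantile {fallback_quantile} threshold {thr:.4g}",
                stacklevel=2,
            )
        else:
            thr = float(np.exp(log_t))
        gates[marker] = thr
        df[FLAG_PREFIX + marker] = intens > thr
        log.info("gate %s: threshold %.4g (%.1f%% positive)", marker, thr,
                 100.0 * float(np.mean(intens > thr)))
    out = CellTable(df, dict(table.windows))
    out.gates = gates
    return out


# ---------------------------------------------------------------------------
# Phenotype derivation — first-matching-rule, priority order fixed per panel
# ---------------------------------------------------------------------------

def derive_phenotypes(table: CellTable,
                      panel_rules: dict | None = None) -> CellTable:
    """Assign exactly one phenotype per cell from its marker flags.

    Rules are applied first-match-wins in a fixed priority order (CK first, so
    conflicting CK+/CD3+ cells resolve to tumor); cells matching no rule become
    "other".  Co-flags (Ki67, PD-1, PD-L1) are left untouched on the table.
    """
    rules = panel_rules or PHENOTYPE_RULES
    df = table.cells.copy()
    phenos = np.full(len(df), "other", dtype=object)
    assigned = np.zeros(len(df), dtype=bool)
    for panel, panel_rule in rules.items():
        in_panel = (df["panel"] == panel).to_numpy()
        if not in_panel.any():
            continue
        for pheno, conditions in panel_rule:
            mask = in_panel & ~assigned
            for marker, wanted in conditions.items():
                col = FLAG_PREFIX + marker
                if col not in df.columns:
                    raise CellTableError(
                        f"panel {panel} rule {pheno!r} needs missing flag {marker!r}"
                    )
                mask &= df[col].to_numpy() == wanted
            phenos[mask] = pheno
            assigned |= mask
    df["phenotype"] = phenos
    return CellTable(df, dict(table.windows))
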