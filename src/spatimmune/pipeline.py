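"""End-to-end pipeline orchestration.

Stages run in dependency order — simulate (or load inputs) → features →
associate → stratify → report — under one :class:`RunConfig`; every threshold,
cut point, seed and exclusion is recorded in a JSON manifest so a rerun with
the same config reproduces outputs bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import association_screen
from .cell_table import CellTable, read_cell_table
from .density_features import density_features
from .microenvironment import TIL_CUT_DEFAULT, classify_ime, pcr_rate_table
from .platform_features import (
    BiomarkerMatrix,
    assemble_matrix,
    score_signatures,
    synthetic_signature_definitions,
)
from .registries import validate_registries
from .spatial_metrics import mh_features, sps_features
from .synthetic_data import SimulationConfig, simulate_cohort

log = logging.getLogger(__name__)

STAGES = ("simulate", "features", "associate", "stratify", "report")


@dataclass
class RunConfig:
    """Configuration for one pipeline run (YAML/JSON loadable)."""

    outdir: str = "spatimmune_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # either simulate... or load from paths
    simulation: dict = field(default_factory=dict)
    cell_table_path: str | None = None
    clinical_path: str | None = None
    expression_path: str | None = None
    rppa_path: str | None = None
    mif_only: bool = False
    alpha: float = 0.05
    bh_family_scope: str = "platform"
    covariate_cols: list[str] | None = None
    min_cohort_size: int = 10
    til_cut: float = TIL_CUT_DEFAULT
    mh_cut_feature: str = "PD1Tc_PDL1"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; expected subset of {STAGES}")
        for attr in ("cell_table_path", "clinical_path",
                     "expression_path", "rppa_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{attr}: file not found: {p}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def compute_mif_features(table: CellTable) -> pd.DataFrame:
    """All 61 default mIF features per patient (densities + PD-L1 + MH + SPS)."""
    return (density_features(table)
            .join(mh_features(table))
            .join(sps_features(table)))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns a dict of in-memory outputs.

    Writes delimited-text tables and a JSON manifest under ``config.outdir``.
    """
    counts = validate_registries()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "registry_counts": counts,
        "alpha": config.alpha,
        "bh_family_scope": config.bh_family_scope,
        "til_cut": config.til_cut,
        "cps_cap": None,
        "exclusions": [],
    }
    outputs: dict = {}
    stages = set(config.stages)

    table = expression = rppa = clinical = None
    if "simulate" in stages:
        sim_cfg = SimulationConfig(**{"seed": config.seed, **config.simulation})
        table, expression, rppa, clinical, truth = simulate_cohort(sim_cfg)
        outputs["ground_truth"] = truth
        manifest["simulation"] = {
            k: v for k, v in asdict(sim_cfg).items()
            if k not in ("pair_modes", "phenotype_intensities")}
    else:
        if config.cell_table_path is None or config.clinical_path is None:
            raise ValueError("without the simulate stage, cell_table_path and "
                             "clinical_path are required")
        table = read_cell_table(config.cell_table_path)
        clinical = pd.read_csv(config.clinical_path, sep=None, engine="python",
                               index_col=0)
        if config.expression_path:
            expression = pd.read_csv(config.expression_path, sep=None,
                                     engine="python", index_col=0)
        if config.rppa_path:
            rppa = pd.read_csv(config.rppa_path, sep=None, engine="python",
                               index_col=0)
    outputs["cell_table"] = table
    outputs["clinical"] = clinical

    matrix: BiomarkerMatrix | None = None
    if "features" in stages:
        if table is None:
            raise ValueError("features stage requires a cell table")
        mif = compute_mif_features(table)
        ges = rppa_block = None
        if not config.mif_only and expression is not None:
            ges = score_signatures(expression, synthetic_signature_definitions())
        if not config.mif_only and rppa is not None:
            rppa_block = rppa  # synthetic RPPA is already on a z-like scale
        matrix = assemble_matrix(density=mif, ges=ges, rppa=rppa_block)
        matrix.write(outdir / "biomarker_matrix.tsv")
        manifest["n_features"] = len(matrix.features)
        manifest["feature_completeness"] = {
            k: round(v, 4) for k, v in matrix.completeness().items()}
        outputs["matrix"] = matrix

    if "associate" in stages:
        if matrix is None:
            raise ValueError("associate stage requires the features stage")
        screen = association_screen(
            matrix, clinical, covariate_cols=config.covariate_cols,
            alpha=config.alpha, family_scope=config.bh_family_scope,
            min_cohort_size=config.min_cohort_size)
        screen.to_csv(outdir / "association_screen.tsv", sep="\t", index=False)
        outputs["screen"] = screen
        manifest["n_tests"] = len(screen)

    if "stratify" in stages:
        if matrix is None:
            raise ValueError("stratify stage requires the features stage")
        needed = {"TIL", config.mh_cut_feature}
        if not needed <= set(matrix.features):
            raise ValueError(f"stratify stage needs features {sorted(needed)}")
        classes = classify_ime(matrix.values["TIL"],
                               matrix.values[config.mh_cut_feature],
                               til_cut=config.til_cut)
        common = classes.index.intersection(clinical.index)
        rates, fisher_p = pcr_rate_table(
            classes.loc[common, "ime_class"], clinical.loc[common, "pCR"],
            clinical.loc[common, "subtype"])
        classes.to_csv(outdir / "ime_classes.tsv", sep="\t")
        rates.to_csv(outdir / "ime_pcr_rates.tsv", sep="\t", index=False)
        manifest["mh_cut"] = classes.attrs["mh_cut"]
        manifest["ime_fisher_p"] = fisher_p
        outputs["ime_classes"] = classes
        outputs["ime_rates"] = rates
        outputs["ime_fisher_p"] = fisher_p

    if "report" in stages:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    outputs["manifest"] = manifest
    return outputs
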