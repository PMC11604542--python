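"""Feature registries: cell populations, spatial pair lists, signatures, RPPA endpoints.

The default registries define the 126-feature biomarker space used throughout the
pipeline: 61 mIF features (18 cell populations + 2 PD-L1 scores + 21 Morisita-Horn
pairs + 20 spatial proximity scores), 38 gene-expression signatures and 27 RPPA
endpoints.  Every registry is plain data (dataclasses / dicts) and can be replaced or
edited via YAML config; ``validate_registries`` enforces the count arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

# ---------------------------------------------------------------------------
# Panels and phenotypes
# ---------------------------------------------------------------------------

PANELS = ("P1", "P2")

#: Legal phenotype labels per staining panel.  Panel 1 identifies CK+ tumor cells,
#: CD3+Foxp3- T cells, CD3+Foxp3+ Tregs, CD20+ B cells and CD117+CK- mast cells,
#: with a Ki67 proliferation co-flag.  Panel 2 identifies CK+ tumor cells, CD8+
#: cytotoxic T cells (Tc), CD8- T cells and CD68+ macrophages, with PD-1 and PD-L1
#: co-flags.
PANEL_PHENOTYPES: dict[str, tuple[str, ...]] = {
    "P1": ("Tm", "T", "Treg", "B", "Mast", "other"),
    "P2": ("Tm", "Tc", "CD8nT", "Mac", "other"),
}

#: Co-expression flags carried orthogonally to the phenotype, per panel.
PANEL_COFLAGS: dict[str, tuple[str, ...]] = {
    "P1": ("Ki67",),
    "P2": ("PD1", "PDL1"),
}

#: Marker -> phenotype priority rules per panel, applied first-match-wins.
#: Epithelial identity (CK) dominates so that CPS/TPS denominators are stable.
PHENOTYPE_RULES: dict[str, tuple[tuple[str, dict[str, bool]], ...]] = {
    "P1": (
        ("Tm", {"CK": True}),
        ("Treg", {"CD3": True, "Foxp3": True}),
        ("T", {"CD3": True}),
        ("B", {"CD20": True}),
        ("Mast", {"CD117": True}),
    ),
    "P2": (
        ("Tm", {"CK": True}),
        ("Tc", {"CD3": True, "CD8": True}),
        ("CD8nT", {"CD3": True}),
        ("Mac", {"CD68": True}),
    ),
}


# ---------------------------------------------------------------------------
# Cell populations (density features)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Population:
    """A countable cell population: phenotypes within one panel, plus flag filters.

    ``flags`` maps co-flag name -> required boolean value; empty means any.
    """

    name: str
    panel: str
    phenotypes: tuple[str, ...]
    flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):  # dataclass(frozen) workaround for dict field
        object.__setattr__(self, "flags", dict(self.flags))


#: The 18 default cell populations, reported as percent of total cells per panel.
#: "T" counts all CD3+ cells (CD3+Foxp3- plus Tregs); TIL = T + B.
DEFAULT_POPULATIONS: tuple[Population, ...] = (
    Population("T", "P1", ("T", "Treg")),
    Population("Treg", "P1", ("Treg",)),
    Population("B", "P1", ("B",)),
    Population("Mast", "P1", ("Mast",)),
    Population("TIL", "P1", ("T", "Treg", "B")),
    Population("Ki67Tm", "P1", ("Tm",), {"Ki67": True}),
    Population("Ki67T", "P1", ("T", "Treg"), {"Ki67": True}),
    Population("Ki67B", "P1", ("B",), {"Ki67": True}),
    Population("Tc", "P2", ("Tc",)),
    Population("CD8nT", "P2", ("CD8nT",)),
    Population("Mac", "P2", ("Mac",)),
    Population("PD1T", "P2", ("Tc", "CD8nT"), {"PD1": True}),
    Population("PD1Tc", "P2", ("Tc",), {"PD1": True}),
    Population("CD8nPD1T", "P2", ("CD8nT",), {"PD1": True}),
    Population("PDL1", "P2", ("Tm", "Tc", "CD8nT", "Mac", "other"), {"PDL1": True}),
    Population("PDL1Tm", "P2", ("Tm",), {"PDL1": True}),
    Population("PDL1Im", "P2", ("Tc", "CD8nT", "Mac"), {"PDL1": True}),
    Population("PDL1Mac", "P2", ("Mac",), {"PDL1": True}),
)


# ---------------------------------------------------------------------------
# Spatial cell types and pair registries
# ---------------------------------------------------------------------------

#: Cell types usable in spatial pairs, resolved per panel to (phenotypes, flags).
SPATIAL_TYPES: dict[str, Population] = {
    p.name: p
    for p in (
        Population("Tm", "P1", ("Tm",)),
        Population("T", "P1", ("T", "Treg")),
        Population("Treg", "P1", ("Treg",)),
        Population("B", "P1", ("B",)),
        Population("Mast", "P1", ("Mast",)),
        Population("TIL", "P1", ("T", "Treg", "B")),
        Population("Tm2", "P2", ("Tm",)),
        Population("Tc", "P2", ("Tc",)),
        Population("CD8nT", "P2", ("CD8nT",)),
        Population("Mac", "P2", ("Mac",)),
        Population("PD1T", "P2", ("Tc", "CD8nT"), {"PD1": True}),
        Population("PD1Tc", "P2", ("Tc",), {"PD1": True}),
        Population("CD8nPD1T", "P2", ("CD8nT",), {"PD1": True}),
        Population("PDL1", "P2", ("Tm", "Tc", "CD8nT", "Mac", "other"), {"PDL1": True}),
        Population("PDL1Tm", "P2", ("Tm",), {"PDL1": True}),
        Population("PDL1Im", "P2", ("Tc", "CD8nT", "Mac"), {"PDL1": True}),
    )
}


@dataclass(frozen=True)
class SpatialPair:
    """A pair of spatial cell types from the same panel.

    ``name`` is the reported feature name (MH pairs unordered, e.g. ``T_Treg``;
    SPS pairs ordered and suffixed ``.SPS``, where ``A_B.SPS`` reads "fraction of
    A cells with a B cell within r").  ``type_a``/``type_b`` key SPATIAL_TYPES.
    """

    name: str
    type_a: str
    type_b: str

    @property
    def panel(self) -> str:
        return SPATIAL_TYPES[self.type_a].panel


def _mh(name, a, b):
    return SpatialPair(name, a, b)


#: 21 unordered Morisita-Horn pairs (8 from panel 1, 13 from panel 2).
DEFAULT_MH_PAIRS: tuple[SpatialPair, ...] = (
    _mh("Tm_T", "Tm", "T"),
    _mh("Tm_Treg", "Tm", "Treg"),
    _mh("Tm_B", "Tm", "B"),
    _mh("Tm_Mast", "Tm", "Mast"),
    _mh("Tm_TIL", "Tm", "TIL"),
    _mh("T_Treg", "T", "Treg"),
    _mh("T_B", "T", "B"),
    _mh("Treg_B", "Treg", "B"),
    _mh("Tm_Tc", "Tm2", "Tc"),
    _mh("Tm_CD8nT", "Tm2", "CD8nT"),
    _mh("Tm_Mac", "Tm2", "Mac"),
    _mh("Tc_Mac", "Tc", "Mac"),
    _mh("PD1T_PDL1", "PD1T", "PDL1"),
    _mh("PD1T_PDL1Tm", "PD1T", "PDL1Tm"),
    _mh("PD1T_PDL1Im", "PD1T", "PDL1Im"),
    _mh("PD1Tc_PDL1", "PD1Tc", "PDL1"),
    _mh("PD1Tc_PDL1Tm", "PD1Tc", "PDL1Tm"),
    _mh("PD1Tc_PDL1Im", "PD1Tc", "PDL1Im"),
    _mh("CD8nPD1T_PDL1", "CD8nPD1T", "PDL1"),
    _mh("CD8nPD1T_PDL1Tm", "CD8nPD1T", "PDL1Tm"),
    _mh("CD8nPD1T_PDL1Im", "CD8nPD1T", "PDL1Im"),
)

#: 20 ordered spatial-proximity-score pairs (6 from panel 1, 14 from panel 2).
DEFAULT_SPS_PAIRS: tuple[SpatialPair, ...] = (
    _mh("Tm_T.SPS", "Tm", "T"),
    _mh("T_Tm.SPS", "T", "Tm"),
    _mh("Tm_Treg.SPS", "Tm", "Treg"),
    _mh("Tm_B.SPS", "Tm", "B"),
    _mh("T_B.SPS", "T", "B"),
    _mh("Tm_TIL.SPS", "Tm", "TIL"),
    _mh("Tm_Tc.SPS", "Tm2", "Tc"),
    _mh("Tm_CD8nT.SPS", "Tm2", "CD8nT"),
    _mh("Tm_Mac.SPS", "Tm2", "Mac"),
    _mh("Tc_Tm.SPS", "Tc", "Tm2"),
    _mh("CD8nT_Tm.SPS", "CD8nT", "Tm2"),
    _mh("PD1T_PDL1.SPS", "PD1T", "PDL1"),
    _mh("PD1T_PDL1Tm.SPS", "PD1T", "PDL1Tm"),
    _mh("PD1T_PDL1Im.SPS", "PD1T", "PDL1Im"),
    _mh("PD1Tc_PDL1.SPS", "PD1Tc", "PDL1"),
    _mh("PD1Tc_PDL1Tm.SPS", "PD1Tc", "PDL1Tm"),
    _mh("PD1Tc_PDL1Im.SPS", "PD1Tc", "PDL1Im"),
    _mh("CD8nPD1T_PDL1.SPS", "CD8nPD1T", "PDL1"),
    _mh("CD8nPD1T_PDL1Tm.SPS", "CD8nPD1T", "PDL1Tm"),
    _mh("CD8nPD1T_PDL1Im.SPS", "CD8nPD1T", "PDL1Im"),
)


# ---------------------------------------------------------------------------
# Expression signatures and RPPA endpoints
# ---------------------------------------------------------------------------

#: 38 expression signatures: 26 immune, 10 DNA-damage-response, 1 proliferation,
#: 1 hormone-receptor.  Member gene lists are configuration (see
#: platform_features.SignatureDefinition); synthetic runs generate synthetic lists.
DEFAULT_SIGNATURES: dict[str, str] = {
    # immune (26)
    "Tcell_sig": "immune",
    "CD8Tcell_sig": "immune",
    "Th1_sig": "immune",
    "Treg_sig": "immune",
    "Bcell_sig": "immune",
    "NK56d_sig": "immune",
    "DC_sig": "immune",
    "Mast_sig": "immune",
    "Mac_sig": "immune",
    "ExhTc_sig": "immune",
    "TcClassII_sig": "immune",
    "Mod4_TB": "immune",
    "Chemokine12": "immune",
    "GeparSixto": "immune",
    "ICS5": "immune",
    "TIS": "immune",
    "STAT1_sig": "immune",
    "PDCD1": "immune",
    "CD274": "immune",
    "CTLA4": "immune",
    "IFNg_sig": "immune",
    "CYT_sig": "immune",
    "TLStruct_sig": "immune",
    "Checkpoint_sig": "immune",
    "MHC2_sig": "immune",
    "CXCL9_sig": "immune",
    # DNA damage response (10)
    "PARPi7": "DDR",
    "FA_sig": "DDR",
    "MMR_sig": "DDR",
    "BER_sig": "DDR",
    "HRrep_sig": "DDR",
    "TLSyn_sig": "DDR",
    "NER_sig": "DDR",
    "NHEJ_sig": "DDR",
    "DR_sig": "DDR",
    "DamageSens": "DDR",
    # proliferation (1) and hormone receptor (1)
    "Mitotic_sig": "proliferation",
    "ER_PR_sig": "ER-PR",
}

#: 27 RPPA endpoints: 17 immune (11 surface + 6 signaling), 10 DDR.
DEFAULT_RPPA_ENDPOINTS: dict[str, str] = {
    "CD3e": "immune",
    "CD3z": "immune",
    "PD1_Pembro": "immune",
    "PD1_Nivo": "immune",
    "PDL1_22C3": "immune",
    "PDL1_SP142": "immune",
    "PDL1_E1L3N": "immune",
    "PDL1_288": "immune",
    "PDL1_Atezo": "immune",
    "HLADRPQX": "immune",
    "HLADRB1": "immune",
    "pSTAT1_Y701": "immune",
    "STAT1": "immune",
    "pSTAT3_Y705": "immune",
    "STAT3": "immune",
    "pJAK2_Y1007": "immune",
    "pNFkB_S536": "immune",
    "pBRCA1_S1524": "DDR",
    "pCHK1_S345": "DDR",
    "pCHK2_T68": "DDR",
    "PARP_cleaved": "DDR",
    "Caspase3_cleaved": "DDR",
    "Caspase9_cleaved": "DDR",
    "pH2AX_S139": "DDR",
    "MLH1": "DDR",
    "MSH6": "DDR",
    "MSH2": "DDR",
}

#: PD-L1 scores computed from panel 2 (tumor proportion score / combined positive
#: score).
PDL1_SCORES = ("TPS", "CPS")


def mif_feature_names(
    populations=DEFAULT_POPULATIONS,
    mh_pairs=DEFAULT_MH_PAIRS,
    sps_pairs=DEFAULT_SPS_PAIRS,
) -> list[str]:
    """All mIF feature names in registry order (61 by default)."""
    return (
        [p.name for p in populations]
        + list(PDL1_SCORES)
        + [p.name for p in mh_pairs]
        + [p.name for p in sps_pairs]
    )


def all_feature_names() -> list[str]:
    """The full default biomarker registry (126 features)."""
    return (
        mif_feature_names()
        + list(DEFAULT_SIGNATURES)
        + list(DEFAULT_RPPA_ENDPOINTS)
    )


def feature_platform(name: str) -> str:
    """Platform tag for a default-registry feature name."""
    if name in DEFAULT_SIGNATURES:
        return "mRNA"
    if name in DEFAULT_RPPA_ENDPOINTS:
        return "RPPA"
    if name in mif_feature_names():
        return "mIF"
    raise KeyError(f"unknown feature {name!r}")


def validate_registries(
    populations=DEFAULT_POPULATIONS,
    mh_pairs=DEFAULT_MH_PAIRS,
    sps_pairs=DEFAULT_SPS_PAIRS,
    signatures=DEFAULT_SIGNATURES,
    rppa=DEFAULT_RPPA_ENDPOINTS,
) -> dict[str, int]:
    """Registry self-check: 18 + 2 + 21 + 20 = 61 mIF; 61 + 38 + 27 = 126 total.

    Returns the count breakdown; raises ``ValueError`` on any violation
    (including duplicate names or cross-panel pairs).
    """
    names = (
        [p.name for p in populations]
        + list(PDL1_SCORES)
        + [p.name for p in mh_pairs]
        + [p.name for p in sps_pairs]
        + list(signatures)
        + list(rppa)
    )
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate feature names in registry: {dupes}")
    for pair in tuple(mh_pairs) + tuple(sps_pairs):
        pa = SPATIAL_TYPES[pair.type_a].panel
        pb = SPATIAL_TYPES[pair.type_b].panel
        if pa != pb:
            raise ValueError(f"pair {pair.name} spans panels {pa}/{pb}")
    counts = {
        "populations": len(populations),
        "pdl1_scores": len(PDL1_SCORES),
        "mh_pairs": len(mh_pairs),
        "sps_pairs": len(sps_pairs),
        "mif": len(populations) + len(PDL1_SCORES) + len(mh_pairs) + len(sps_pairs),
        "mrna": len(signatures),
        "rppa": len(rppa),
    }
    counts["total"] = counts["mif"] + counts["mrna"] + counts["rppa"]
    return counts


def load_pair_registry(path) -> list[SpatialPair]:
    """Load a pair registry from YAML: list of {name, type_a, type_b}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [SpatialPair(d["name"], d["type_a"], d["type_b"]) for d in raw]
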