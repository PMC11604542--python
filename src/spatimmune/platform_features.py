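"""Expression-signature scoring, RPPA standardization, biomarker-matrix assembly.

The unified biomarker matrix is patients × features over three platforms:
61 mIF features (densities, PD-L1 scores, spatial metrics), 38 expression
signatures and 27 RPPA endpoints — 126 features in the default registry.
Signature scores are unweighted means of member genes on the log2 scale (the
simplest rule; per-signature weights can be supplied in config).  RPPA arrays
are z-scored endpoint-wise against subtype-balanced resampling moments before
concatenation, which removes between-array batch shifts while preserving the
receptor-subtype case mix of the reference population.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registries import (
    DEFAULT_RPPA_ENDPOINTS,
    DEFAULT_SIGNATURES,
    mif_feature_names,
)

log = logging.getLogger(__name__)

#: receptor-subtype mix of the reference population used for balanced resampling
DEFAULT_SUBTYPE_PROPS = {
    "HR+HER2-": 0.384,
    "TN": 0.368,
    "HR+HER2+": 0.158,
    "HR-HER2+": 0.09,
}


@dataclass(frozen=True)
class SignatureDefinition:
    """A named gene set with a platform category tag."""

    name: str
    genes: tuple[str, ...]
    category: str = "immune"  # immune / DDR / proliferation / ER-PR

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has an empty gene list")


def synthetic_signature_definitions(genes_per_signature: int = 5
                                    ) -> list[SignatureDefinition]:
    """Signature definitions matching the synthetic expression matrix layout."""
    return [
        SignatureDefinition(name, tuple(f"{name}_g{k}"
                                        for k in range(1, genes_per_signature + 1)),
                            category)
        for name, category in DEFAULT_SIGNATURES.items()
    ]


def read_signature_definitions(path) -> list[SignatureDefinition]:
    """Read signatures from a two-column delimited file: name,gene per row."""
    df = pd.read_csv(path, sep=None, engine="python")
    name_col, gene_col = df.columns[:2]
    out = []
    for name, sub in df.groupby(name_col, sort=False):
        out.append(SignatureDefinition(str(name), tuple(sub[gene_col].astype(str))))
    return out


def score_signature(expression: pd.DataFrame, sig: SignatureDefinition) -> pd.Series:
    """Per-patient signature score: mean of member-gene values (log2 scale).

    ``expression`` is genes × patients.  Missing member genes are ignored (their
    fraction is logged); a signature with no member genes present returns an
    all-NaN series with a warning.
    """
    present = [g for g in sig.genes if g in expression.index]
    missing_frac = 1.0 - len(present) / len(sig.genes)
    if not present:
        warnings.warn(f"signature {sig.name}: no member genes in matrix",
                      stacklevel=2)
        return pd.Series(np.nan, index=expression.columns, name=sig.name)
    if missing_frac > 0:
        log.info("signature %s: %.0f%% of member genes missing",
                 sig.name, 100 * missing_frac)
    return expression.loc[present].mean(axis=0).rename(sig.name)


def score_signatures(expression: pd.DataFrame,
                     signatures: list[SignatureDefinition]) -> pd.DataFrame:
    """Patients × signatures score matrix."""
    return pd.concat([score_signature(expression, s) for s in signatures], axis=1)


# ---------------------------------------------------------------------------
# RPPA standardization
# ---------------------------------------------------------------------------

def rppa_standardize(arrays: list[pd.DataFrame],
                     subtype_labels: pd.Series,
                     props: dict[str, float] | None = None,
                     n_resamples: int = 5000,
                     seed: int = 0) -> pd.DataFrame:
    """Z-score each RPPA array against subtype-balanced resampling moments.

    Per array: draw ``n_resamples`` subtype-stratified resamples of the array's
    samples matching the reference proportions ``props``; per endpoint compute
    the mean of resample means and the mean of resample standard deviations;
    z-score the endpoint by those two numbers.  Arrays (endpoints × samples) are
    then concatenated along samples.

    Proportions for subtypes absent from an array are renormalized over the
    present ones (logged).  An endpoint with zero variance in every resample is
    set missing.
    """
    props = dict(props or DEFAULT_SUBTYPE_PROPS)
    rng = np.random.default_rng(seed)
    out = []
    for ai, arr in enumerate(arrays):
        labels = subtype_labels.reindex(arr.columns)
        if labels.isna().any():
            missing = list(arr.columns[labels.isna()])[:5]
            raise ValueError(f"array {ai}: samples without subtype labels: {missing}")
        present = [s for s in props if (labels == s).any()]
        if not present:
            raise ValueError(f"array {ai}: no samples from any known subtype")
        total = sum(props[s] for s in present)
        if len(present) < len(props):
            log.info("array %d: renormalizing subtype props over %s", ai, present)
        weights = {s: props[s] / total for s in present}
        groups = {s: np.flatnonzero((labels == s).to_numpy()) for s in present}
        n_samp = arr.shape[1]
        draw_sizes = {s: max(1, int(round(weights[s] * n_samp))) for s in present}
        values = arr.to_numpy(dtype=float)
        means = np.zeros((n_resamples, arr.shape[0]))
        sds = np.zeros((n_resamples, arr.shape[0]))
        for r in range(n_resamples):
            cols = np.concatenate([
                rng.choice(groups[s], size=draw_sizes[s],
                           replace=draw_sizes[s] > len(groups[s]))
                for s in present
            ])
            sub = values[:, cols]
            means[r] = sub.mean(axis=1)
            sds[r] = sub.std(axis=1, ddof=1) if sub.shape[1] > 1 else 0.0
        mu = means.mean(axis=0)
        sd = sds.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (values - mu[:, None]) / sd[:, None]
        z[sd == 0, :] = np.nan
        out.append(pd.DataFrame(z, index=arr.index, columns=arr.columns))
    return pd.concat(out, axis=1)


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerMatrix:
    """Patients × features with per-feature platform annotation."""

    values: pd.DataFrame
    platforms: pd.Series  # feature -> platform in {mIF, mRNA, RPPA}

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def platform_features(self, platform: str) -> list[str]:
        return list(self.platforms.index[self.platforms == platform])

    def completeness(self, registry: list[str] | None = None) -> pd.Series:
        """Fraction of patients populated per registry feature (0 if absent)."""
        registry = registry or self.features
        frac = self.values.notna().mean(axis=0)
        return frac.reindex(registry).fillna(0.0)

    def write(self, path, sep: str = "\t") -> None:
        self.values.rename_axis("patient_id").to_csv(path, sep=sep)


def assemble_matrix(density: pd.DataFrame | None = None,
                    spatial: pd.DataFrame | None = None,
                    ges: pd.DataFrame | None = None,
                    rppa: pd.DataFrame | None = None) -> BiomarkerMatrix:
    """Outer-join per-platform patient × feature frames into one matrix.

    ``density`` and ``spatial`` are mIF blocks (patients × features); ``ges``
    patients × signatures; ``rppa`` is endpoints × samples (transposed here).
    Patients missing from one platform get NaN for that platform's features.
    Duplicate feature names across platforms are an error.
    """
    blocks: list[tuple[str, pd.DataFrame]] = []
    if density is not None:
        blocks.append(("mIF", density))
    if spatial is not None:
        blocks.append(("mIF", spatial))
    if ges is not None:
        blocks.append(("mRNA", ges))
    if rppa is not None:
        blocks.append(("RPPA", rppa.T))
    if not blocks:
        raise ValueError("no platform blocks to assemble")
    seen: dict[str, str] = {}
    for platform, block in blocks:
        for f in block.columns:
            if f in seen:
                raise ValueError(
                    f"duplicate feature name {f!r} across platforms "
                    f"({seen[f]} and {platform})")
            seen[f] = platform
    values = blocks[0][1]
    for _, block in blocks[1:]:
        values = values.join(block, how="outer")
    platforms = pd.Series(seen).reindex(values.columns)
    matrix = BiomarkerMatrix(values, platforms)
    mif_n = len(matrix.platform_features("mIF"))
    log.info("assembled biomarker matrix: %d patients x %d features "
             "(%d mIF / %d mRNA / %d RPPA)", *values.shape, mif_n,
             len(matrix.platform_features("mRNA")),
             len(matrix.platform_features("RPPA")))
    return matrix
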