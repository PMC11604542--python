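# spatimmune

Spatial immune biomarkers of response to neoadjuvant immune checkpoint
blockade in early-stage breast cancer.

Only a subset of breast cancers responds when an anti-PD-1 antibody
(pembrolizumab) is added to neoadjuvant chemotherapy. Multiplexed
immunofluorescence (mIF) yields per-cell coordinates and phenotypes in
pretreatment biopsies, which makes it possible to ask not only *how many*
immune cells a tumor contains but *where they sit relative to each other* —
in particular, whether PD-1⁺ T cells are spatially colocalized with PD-L1⁺
cells, the very interaction the drug disrupts. `spatimmune` implements that
analysis as a reusable pipeline for cell-level phenotype tables:

- **Density features** — 18 cell-population fractions (percent of total
  cells, pooled over a patient's 15–20 regions of interest per staining
  panel), tumor-infiltrating lymphocytes (TIL = CD3⁺ T cells + CD20⁺ B
  cells), and the clinical PD-L1 scores
  TPS = 100 · |PD-L1⁺ tumor| / |tumor| and
  CPS = 100 · (|PD-L1⁺ tumor| + |PD-L1⁺ immune|) / |tumor|.
- **Morisita–Horn colocalization** — each ROI is divided into non-overlapping
  200 μm × 200 μm quadrat squares; for cell types A and B with per-square
  counts *aᵢ*, *bᵢ* (totals *A*, *B*),

      MH = 2 Σᵢ aᵢbᵢ / [(Σᵢaᵢ²/A² + Σᵢbᵢ²/B²) · A · B]

  ranges from 0 (fully segregated) to 1 (fully colocalized). 21 cell-type
  pairs are evaluated per patient, squares pooled across ROIs.
- **Spatial proximity scores** — the nearest-neighbor distribution function
  G(r), the fraction of type-a cells with a type-b cell within radius r, is
  evaluated from 0 to 20 μm per ROI; the area under G(r) normalized by the
  20 μm horizon, averaged over ROIs, gives a directional SPS ∈ [0, 1] for 20
  ordered pairs (`Tm_T.SPS` = fraction of tumor cells with a T cell nearby).
- **Multi-platform matrix** — the 61 mIF features join 38 gene-expression
  signature scores (mean of member genes, log2 scale) and 27 RPPA
  protein/phosphoprotein endpoints (z-scored against subtype-balanced
  resampling moments) into a 126-feature biomarker matrix per patient.
- **Association screen** — each biomarker is tested against pathologic
  complete response (pCR) with a likelihood-ratio test between nested
  logistic models, per treatment arm and receptor subtype (HR⁺HER2⁻ / TN),
  optionally covariate-adjusted, with Benjamini–Hochberg correction within
  cohort × platform and a biomarker × arm interaction test.
- **Microenvironment classes** — patients are stratified into TIL-low
  (< 12.5% of total cells), TIL-high/colocalization-low, and
  TIL-high/colocalization-high (median cut on the PD1Tc_PDL1 MH index), and
  class–response association is tested with Fisher's exact test (r×c by
  exhaustive enumeration).

A cell-level synthetic-cohort generator with known ground truth (Thomas-type
cluster processes for colocalization, logistic response model on realized,
cohort-standardized features) makes every stage testable without patient
data.

## Worked example

```python
import spatimmune as si

cfg = si.RunConfig(
    outdir="example_out", seed=1, mif_only=True,
    simulation={
        "n_patients": 60,
        "pair_modes": {("PD1Tc", "PDL1"):
                       si.PairMode("colocalized", sigma_range=(10, 150))},
        "response_coefs": {"TIL": 1.5, "PD1Tc_PDL1": 1.0},
    },
)
out = si.run_pipeline(cfg)
```

This simulates 60 patients (15–20 ROIs each, two panels) in which both TIL
level and PD-1⁺Tc/PD-L1⁺ colocalization raise the probability of pCR, then
computes all 61 mIF features, screens them, and stratifies the cohort.
Inspecting the outputs:

```
>>> out["matrix"].values.shape
(60, 61)
>>> out["matrix"].values[["TIL", "CPS", "T_Treg", "PD1Tc_PDL1", "Tm_T.SPS"]].head(3).round(3)
               TIL     CPS  T_Treg  PD1Tc_PDL1  Tm_T.SPS
patient_id
PT0001      27.155   7.319   0.846       0.699     0.079
PT0002      20.094  12.919   0.781       0.569     0.054
PT0003      23.642  27.755   0.777         NaN     0.033
```

`TIL` is percent of panel-1 cells; `PD1Tc_PDL1` is the MH index of PD-1⁺
cytotoxic T cells with PD-L1⁺ cells (NaN where the patient has too few cells
of a type for the index to be meaningful); `Tm_T.SPS` is the fraction-scaled
proximity of tumor cells to T cells. The screen recovers the simulated
signal — TIL-linked densities and spatial metrics lead the pembro-arm
ranking:

```
   feature  direction     lr_p     bh_p
    Tm_TIL          1 0.000021 0.000883
      Tm_T          1 0.000029 0.000883
       T_B          1 0.000105 0.002127
     Tm_Tc          1 0.000207 0.002158
Tm_TIL.SPS          1 0.000216 0.002158
    Tc_Mac          1 0.000231 0.002158
```

and the microenvironment classes show the graded response the generator
encodes (0% pCR in TIL-low tumors, rising with colocalization; class–response
Fisher p = 0.00215, median MH cut 0.577):

```
group           ime_class   n  n_pCR  pcr_rate_pct
  ALL             TIL_low   8      0           0.0
  ALL  TIL_high_coloc_low  21      5          23.8
  ALL TIL_high_coloc_high  25     15          60.0
```

The same run is available from the shell:

```sh
spatimmune all --config run.yaml --seed 1
```

with subcommands `simulate`, `features`, `associate`, `stratify`, `report`,
`all`; every output directory contains a `manifest.json` recording seeds,
cut points and registry counts, and reruns with the same config are
bit-identical.

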