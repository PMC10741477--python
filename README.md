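# gscdsrt

Drug-sensitivity scoring and heterogeneity statistics for multiregional
glioma-stem-cell (GSC) drug screens.

## The problem

Glioblastoma is spatially heterogeneous: GSC cultures established from
different regions of one tumor can respond differently to the same drug.
Functional precision medicine asks whether a single biopsy-derived culture is
representative of its tumor, which requires separating *intratumoral*
variation (between regions of one tumor) from *intertumoral* variation
(between patients). This package implements the complete quantitative
pipeline for that question, for cohorts shaped like: a set of multiregional
GSC cultures from one tumor (default 7) screened alongside a reference
cohort of cultures from other patients (default 14) against a drug panel
(default 115 drugs, five-point dose escalation), plus an RNA-seq TPM matrix
over the multiregional cultures.

Because the patient-derived data of such studies are typically not deposited
in machine-readable form, the package ships a first-class synthetic-data
generator that plants known ground truth (per-culture dose–response curves
with an intra-tumor vs inter-tumor variance structure on the DSS scale, and
a two-component gene-dispersion mixture), so every stage can be validated by
parameter recovery.

## Methods at the core

**Dose–response.** Raw viability signals are scaled to plate controls
(DMSO negative, benzethonium-chloride positive) to percent inhibition
`100·(neg − s)/(neg − pos)`, or to negative controls only. Each drug's
five-point series is fitted with the four-parameter logistic

    y(x) = bottom + (top − bottom) / (1 + 10^(slope·(log10 IC50 − x))),  x = log10(dose µM)

and summarised as the Drug Sensitivity Score: with `A` the closed-form area
of the fitted curve above an activity threshold `t` (default 10%) over the
tested log10 window `[x_min, x_max]`,

    DSS1 = 100·A / ((100 − t)(x_max − x_min)),   DSS2 = DSS1 / log10(top)   (default, 0–50 scale)

The selective DSS subtracts the reference cohort's per-drug mean:
`sDSS[c,d] = DSS[c,d] − mean_ref DSS[·,d]`.

**Heterogeneity statistics.** Per drug, a one-sided F-test of
`var_inter > var_intra` (reference vs multiregional cultures) with
Benjamini–Hochberg FDR; responder filtering at DSS ≥ 10; pairwise Spearman
correlation; the ΔDSS/ΔSD quadrant map (`ΔDSS = mean_tumor − mean_ref`,
`ΔSD = SD_ref − SD_tumor`) separating tumor-specific from shared and
homogeneous from heterogeneous responses; hierarchical clustering (Newick
export) and PCA on `log2(DSS + 0.01)` of complete-case drugs.

**Expression dispersion.** Genes failing QC, all-zero, or with mean TPM < 1
are removed; each gene's cross-sample dispersion is `log SD(TPM)`; a
two-component Gaussian mixture fitted by EM classifies genes as
homogeneously (low dispersion) or heterogeneously expressed when the
posterior reaches 99.8%.

## Worked example

The four numbered scripts under `analysis/` run the whole study on synthetic
data:

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_fit_dose_response.py
python analysis/03_drug_heterogeneity.py
python analysis/04_expression_heterogeneity.py
```

which prints (seed 1):

```
simulated 21 cultures x 115 drugs (1893/2415 culture-drug pairs active)
planted DSS SDs: intra-tumor 2.0, inter-tumor 4.0
...
DSS recovery vs planted truth: median abs error 0.395, 90th pct 2.001
22/115 drugs reach DSS >= 10 in at least one multiregional culture
multiregional profile correlation: Spearman r 0.73 +/- 0.04
27/115 drugs with significantly larger inter-tumor variance (one-sided F, BH-FDR < 0.05)
dDSS/dSD quadrants: {'nonspecific-homogeneous': 73, 'specific-heterogeneous': 3, 'specific-homogeneous': 39}
...
mixture fit: means [-0.06, 3.88], SDs [0.58, 0.68], weights [0.885, 0.115] (26 EM iterations)
classification: {'filtered': 1274, 'heterogeneous': 416, 'homogeneous': 3257, 'unclassified': 53}
planted-label recovery among classified genes: 99.89% (n=3673)
```

Reading: the screen fits recover the planted DSS to a fraction of a score
unit at 5% well noise; the F-tests flag about a quarter of the drugs as more
variable between tumors than within one (planted variance ratio 4, per-drug
power ≈ 0.53); and the dispersion mixture recovers planted gene labels
essentially perfectly at the 99.8% posterior threshold, leaving only genes
near the component boundary unclassified.

The same pipeline runs as one command (`gscdsrt run --seed 1`), or on your
own data by pointing `plates_path` / `expression_path` / `groups_path` in a
YAML config at long-format plate TSVs, a TPM matrix, and a culture→group
map (see `gscdsrt run --config`).

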