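# dielomics

Diurnal multi-omics analysis for synchronized algal photoacclimation
experiments: transcripts, proteins and photophysiology measured over a
12 h light / 12 h dark cycle in populations acclimated to low (LL,
~50 µmol photons m⁻² s⁻¹), moderate (ML, ~200) and high (HL, ~1000)
diurnal light. The package is aimed at researchers who have
feature-by-sample abundance tables (FPKM-like transcript values or raw
counts, TMT reporter intensities, pigment/morphometry tables) from a
three-condition, five-timepoint, replicated diurnal design and want the
full downstream analysis as tested, reusable code — exercisable end to
end on synthetic data with known ground truth.

## What it computes

**Rhythm detection.** Each feature is fit with a fixed-period cosinor
model over all replicate observations at their Zeitgeber times,

y(t) = M + β_c·cos(2πt/24) + β_s·sin(2πt/24) + ε,

giving mesor M, amplitude A = √(β_c² + β_s²), and acrophase φ (the ZT of
the fitted maximum). Significance is the F-test of β_c = β_s = 0, with
Benjamini–Hochberg control per (layer, condition) family; q < 0.05 calls
a feature rhythmic. Phase comparisons (between light regimes, or protein
vs cognate mRNA lags) use minimal signed differences on the 24 h circle.

**Differential abundance.** Transcripts: a simplified negative-binomial
Wald test per timepoint against the ML control (median-of-ratios size
factors, method-of-moments gene-wise dispersion floored at the
across-gene median); a gene is called up/down if |log₂FC| > 1 and BH
p < 0.01. Proteins: replicate-mean log₂ fold changes are scored against
the fold-change distribution of all proteins in the contrast; |Z| > 2
with both group means above the limit of quantitation is a call.

**Light-response classification.** A core HL-specific response is a gene
significantly changed in HL while unchanged or oppositely changed in LL;
core calls are unioned across timepoints and layers with provenance.
Constitutive responses (same-direction calls at all five timepoints) and
mRNA/protein concordance (simultaneous, or protein lagging by the next
4-h-spaced sampled timepoint) are derived from the same call tables.

**Clustering & enrichment.** Per-gene Z-scored state-mean profiles of
both layers are concatenated and clustered with seeded k-means (k = 16
default); gene lists are tested for term enrichment with the exact
upper-tail hypergeometric probability and BH control; PCA (with a
bottom-10%-variance feature filter) and pairwise Pearson correlation
(complete / pairwise-complete) provide sample QC and co-expression.

**Photophysiology.** Closed forms: de-epoxidation state
DES = (0.5·Anthera + Zea)/(Vio + Anthera + Zea); stacking repeat distance
SRD = stack height / membrane layers (stacked membranes only);
Fv/Fm = (Fm − F0)/Fm; NPQ = (Fm − Fm′)/Fm′; and the 77 K PSI/PSII
fluorescence ratio F711/F684 from windowed spectral maxima.

**Synthetic data.** `dielomics.synthetic_data` generates the whole
experiment — rhythmic counts, lagged compressed proteins with
missingness, planted light responses, physiology tables — with a
per-gene truth table, deterministically from a seed.

## Worked example

The numbered drivers under `analysis/` chain the pipeline on a synthetic
experiment (2000 genes, 45 samples, seed 1):

```bash
python analysis/01_simulate_dataset.py --seed 1
python analysis/02_rhythm_analysis.py
python analysis/03_differential_expression.py
python analysis/04_light_response.py
python analysis/05_cluster_enrichment.py
python analysis/06_physiology.py
```

Selected output from that run, and what it means:

```
mrna:  ML nucleus  1720/1884 = 0.91      # 91% of detected nuclear transcripts rhythmic (q < 0.05)
mRNA phase HL vs ML: n=1816, within 2 h: 0.99   # phases maintained across light regimes
mRNA->protein lag (ML): n=1694, median 5.0 h, in [2,8] h: 0.93
core HL-specific genes (union over layers/timepoints): 102
  recovery of planted HL-specific genes: 100/100
  contamination from shared-response genes: 2/100
clustered 1990 dual-detected genes into 16 groups
clusters with >= 1 significantly enriched term (BH p_adj < 0.05): 14/16
HL de-epoxidation state over the day: -2: 0.16  +2: 0.45  +6: 0.51  +10: 0.25
Fv/Fm: HL 0.45 at +2 -> 0.62 at +10 (ML night: 0.73)
```

The generator planted 91% rhythmic genes, protein lags uniform on
[2, 8] h (median 5 h among detectably rhythmic pairs), and 100
HL-specific responders — the pipeline recovers each of these, and the
physiology summaries reproduce the planted midday xanthophyll
de-epoxidation peak and the HL Fv/Fm dip-and-recovery.

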