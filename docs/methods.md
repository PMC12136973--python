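# Methods

## The experimental design being modelled

The analyses assume synchronized photoautotrophic cultures grown under
12 h light / 12 h dark cycles at one of three acclimation intensities
(LL ~50, ML ~200, HL ~1000 µmol photons m⁻² s⁻¹), sampled at five
timepoints labelled relative to the dark-to-light transition: −2, +2,
+6, +10 and −10 h. Labels map to Zeitgeber Time by "+k" → k and
"−k" → 24 − k, so one cycle orders chronologically as ZT 2, 6, 10, 14,
22. Note the −10 sample (ZT14) *precedes* −2 (ZT22) within a night; all
adjacency logic (e.g. the 4-h lag rule) therefore works on ZT, never on
label order. The full factorial with three replicates gives 45 samples
and 15 cellular states. The ML population is always the control in
differential contrasts.

## Cosinor rhythm detection

Per feature, ordinary least squares of
y(t) = M + β_c cos(ωt) + β_s sin(ωt), ω = 2π/24 h⁻¹, over all replicate
observations (replicates enter as independent observations at their ZT;
averaging first is available but not default). Amplitude and acrophase
follow from the rectangular-to-polar identity; acrophase is reported as
the ZT of the fitted maximum in [0, 24). The p-value is the F-test of
the joint zero-amplitude null (2 numerator df, n − 3 denominator df).
BH adjustment is applied within one (layer, condition) family — the
family definition is configurable because analyses of this design have
been published with per-population families. A feature needs ≥ 4 finite
observations spanning ≥ 3 distinct times; otherwise it is excluded and
logged rather than fit. A constant series is a *defined* fit with
amplitude 0 and p = 1.

Double-plotting (duplicating every observation 24 h later) is
implemented for fidelity to common practice in diurnal transcriptomics,
but is **off by default**: duplication leaves the least-squares point
estimates exactly unchanged (proved numerically in the test suite) while
doubling the residual df and hence deflating p-values. Enabling it logs
a warning.

Two fitting paths exist: a vectorized complete-case solve (one `lstsq`
for all features sharing the design) and a per-feature path for series
with missing values. A brute-force acrophase grid search (φ over a 0.1 h
grid, 2-parameter fit at each φ) serves as an independent cross-check of
the closed-form solution; the validation suite requires agreement within
0.2 h on every gene.

Circular statistics: signed phase differences are minimal displacements
in (−12, 12] (the antipode maps to +12 by convention); mRNA-to-protein
lags are mapped to [0, 24) so a 20 h lag is reported as 20 h, not −4 h;
phase concordance between regimes reports the fraction of |Δ| ≤ 2 h and
a Fisher–Lee circular correlation.

## Differential abundance

**Transcripts.** Counts are normalized with median-of-ratios size
factors (library-size ratios as a logged fallback when no gene is
nonzero everywhere). The test is a deliberately simplified NB Wald test:
log₂ fold change of normalized group means with a pseudocount (default
0.5), variance μ + αμ² propagated through the delta method, two-sided
normal p, BH across the genes of one contrast. The gene-wise
method-of-moments dispersion is floored at the across-gene median
dispersion: with three replicates per group the raw per-gene moment
estimator collapses to zero for roughly half the genes, which would make
the Wald statistic strongly anti-conservative; the floor restores null
calibration (measured type-I error at raw p < 0.05 is ~0.05 and the
null BH-at-0.01 call rate is ≪ 1% in the validation suite) at a
negligible cost in sensitivity for the effect sizes of interest. No
shrinkage, outlier refitting, or independent filtering is attempted —
the call contract (|log₂FC| > 1 and BH p < 0.01) is the reproduced
object, not any specific estimator.

**Proteins.** Fold changes are ratios of replicate-mean abundances (not
means of per-replicate ratios), log₂-transformed and standardized
against all finite fold changes of the same contrast; |Z| > 2 is a call.
The limit of quantitation (LOQ) gates *calling only*: proteins with a
group mean at or below LOQ are `not_evaluable`, but their fold changes
still shape the Z distribution, because the LOQ acts as a reporting
filter rather than a distribution trim (a configurable choice). No
numerical LOQ is canonical for reporter intensities, so the default is
the 1st percentile of nonmissing control-layer abundances; it should be
set explicitly when known. Z-scores are computed per (test condition,
timepoint) contrast. Note the caller is intrinsically *relative*: about
2.3% of proteins are called per tail on any null, and a planted effect
near the threshold can flip between contrasts by chance — which is why
end-to-end specificity validation uses the transcript layer.

## Core light responses, constitutive responses, concordance

Core classification is a truth table over the (HL call, LL call) pair:
`core_up` = up in HL and unchanged-or-down in LL; `core_down` its
mirror; everything else `not_core` (shared-direction changes are
attributed to productivity/synchrony differences). By default a
`not_evaluable` input is treated as unchanged (undetected in one arm
does not veto the other); `strict=True` drops such pairs. The gene-level
core list is the union over timepoints and layers, with per-gene
provenance.

The constitutive fraction counts *genes* (not gene × timepoint events)
with same-direction significant calls at all five timepoints, over genes
significant at ≥ 1 timepoint; a direction-free variant is available
because the definition is ambiguous in common usage.

Concordance between layers at a timepoint is `simultaneous`
(same-direction calls at the same timepoint) or `lagged_4h` (protein
call at the next sampled timepoint exactly 4 h later: ZT 22→2, 2→6,
6→10, 10→14; the 14→22 night gap is 8 h and has no 4-h partner, and no
interpolation is attempted). The summary fraction is concordant events
over all events where either layer changed.

## Clustering, enrichment, correlation

State-mean profiles (15 states) are Z-scored per gene within each layer,
concatenated (mRNA block ‖ protein block) for genes detected in both
layers, and clustered with k-means (k = 16, k-means++ with a required
seed, 10 restarts, up to 1000 iterations). Cluster ids are canonicalized
by centroid peak position so runs are comparable; the optimizer's
internal labelling is otherwise arbitrary, and exact cluster boundaries
are expected to differ from other implementations with unstated
initialization. Enrichment is the exact upper-tail hypergeometric
probability per term (validated against rational arithmetic on every
instance with universe ≤ 50), BH across terms, significance at
p_adj < 0.05; the universe defaults to the genes detected in the
analyzed layer(s), and term sets are flat (no ontology-graph
propagation). PCA removes the bottom 10% of features by variance (floor
of n·fraction features), centers (scaling off by default — inputs are
already on comparable log/z scales where PCA is used), and decomposes by
SVD. Pairwise Pearson correlation supports complete-observation and
pairwise-complete-observation missing-data modes, with pairs under 3
shared observations left undefined; replicate QC applies it within each
cellular state.

## Photophysiology indices

All closed forms as in the README. Degenerate inputs are explicit: a
zero xanthophyll pool leaves DES undefined; SRD is undefined for
unstacked membranes (< 2 layers); F0 > Fm and Fm′ > Fm are rejected as
instrument artifacts rather than clipped. The 77 K PSI/PSII ratio uses
windowed maxima (680–690 nm and 705–720 nm, configurable) rather than
fixed wavelengths because instrument calibration shifts peaks; the
spectrum is first normalized to the PSII-window maximum, which makes the
ratio equal to the normalized F711 read-out. The historical post-hoc
battery for physiological group comparisons (Tukey HSD, Games–Howell,
Dunn, repeated-measures designs) is out of scope; the module produces
tidy per-state means/SDs from which effect directions can be asserted.

## The synthetic-data generator

The generator is the package's study-conditions stand-in for the
deposited datasets. Defaults, chosen once: 3 × 5 × 3 design; 91% of
genes rhythmic; phases uniform on [0, 24) (a dawn/dusk-weighted bimodal
option exists, but uniform is the default so phase-recovery tests are
unbiased); log₂ amplitudes uniform on [0.5, 2.5]; mesor log₂ ~ N(7,
1.5²); negative-binomial counts with a single dispersion 0.01 per
simulation (no gene-wise dispersion trend — sufficient for testing call
logic, and stated openly as a simplification) scaled to a ~5 × 10⁶ mean
library; the FPKM-like layer rescales each sample to a common 10⁶
library. Proteins lag their mRNA uniformly on [2, 8] h with amplitude
compressed by a uniform [0.3, 0.7] factor, Gaussian log₂ noise of SD
0.25, left-censoring below a detection floor plus 5% random dropout.
Condition effects are additive on the log₂ scale (matching how fold
changes are defined), effect size 2 by default; responsive genes split
into constitutive vs transient and HL-specific vs shared-with-LL
subpopulations. Physiology tables carry configured state means (midday
HL de-epoxidation, fewer/looser thylakoid stacks in HL, the HL Fv/Fm
dip with late-day recovery, maintained HL NPQ capacity) with
multiplicative lognormal noise; at zero noise every table equals its
configured means exactly. TMT plex structure is not emulated by default.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: gene-wise dispersion trends and outliers,
intensity-dependent protein variance, the empirically bimodal phase
distribution, batch/plex effects on protein detection, and the
substantial real-world discordance between transcript and protein
responses (planted effects hit both layers at the same timepoints, so
synthetic concordance is near-total where real data shows ~tens of
percent). Recovery results certify the pipeline's logic and calibration,
not biological effect sizes.

## Validation experiments and problem sizes

`dielomics.validation` holds the simulate-and-measure experiments used
by the test suite, the analysis drivers and `scripts/acceptance.py`:
type-I error on 2000 flat genes; acrophase recovery on 500 genes at
amplitude/noise 3 (circular MAE ≤ 1 h; grid-oracle agreement ≤ 0.2 h);
4-h lag recovery over ≥ 300 rhythmic genes (median within [3, 5] h);
protein-call oracle equivalence on ~30 random contrasts plus a
5000-protein Gaussian null (call rate in the two-sided 2-SD band); NB
sensitivity ≥ 0.9 at planted 4-fold changes (mean 500, dispersion 0.01,
n = 3) with null BH-at-0.01 rate ≤ 2% over 2000 genes; core-union
recovery of 120 planted HL-specific genes at ≥ 95% with ≤ 5%
contamination from 120 shared-response genes; exact clustering recovery
(ARI = 1) of three planted profile groups; and exhaustive hypergeometric
exactness for universes ≤ 50 (~6 × 10⁵ instances). These sizes keep the
whole battery under a minute on one CPU while leaving the binomial
tolerances comfortably narrower than the asserted bands.

## Numerical choices and known limitations

* Ties and degenerate fits: constant series → amplitude 0, p = 1;
  numerically perfect cosine fits (residual SS below 10⁻¹⁴ of total) →
  p = 0; acrophase of a zero-amplitude fit is NaN.
* BH excludes NaN p-values from the family size and propagates them.
* TSV round-trips write shortest round-tripping float representations
  and are read back with round-trip float parsing, so finite values
  survive bit-exactly; missing entries are empty cells, never zeros.
* The NB test's normal Wald approximation is anti-conservative for very
  low counts; the pseudocount and the dispersion floor mitigate but do
  not remove this. For publication-grade transcript inference on real
  data a full shrinkage estimator is preferable; here the call contract
  and operating characteristics are the target.
* log₂ transforms take an explicit pseudocount (default 1 for FPKM-like
  values) because fold-change behaviour at low abundance depends on it;
  whether FPKMs should be further normalized before fold-change
  computation is left to configuration rather than guessed.
* k-means SSE is reported per run; with a fixed seed results are
  deterministic, but different seeds can find different local optima.
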