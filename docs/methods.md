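# Methods

This note documents the statistical model behind each stage of the
pipeline, the synthetic-data generator's assumptions, the numerical
choices, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. Preprocessing model

Raw fluid intensities are assumed positive, multiplicative in their
nuisance factors, and left-censored at a per-measure detection limit. The
fixed pipeline order is:

1. **Run-day median scaling** — each value is divided by the median of its
   measure on its instrument run-day, removing per-(measure, day) batch
   drift. A (measure, day) group with no observations stays missing.
2. **Osmolality normalisation** (saliva and urine only) — each
   participant's row is divided by that sample's osmolality, correcting
   dilution. Plasma is a no-op (warned). A participant with data but no
   osmolality has the row set missing.
3. **Natural log + z-scoring** — per measure over observed cells, with the
   n−1 sample SD (so results are bit-reproducible across stacks that
   share this convention). Measures with < 2 observations or zero
   variance are dropped.
4. **Outlier removal** — cells with |z| > k (default 4) are set missing.
   Outliers are removed *before* imputation so imputed constants cannot
   distort the SDs used for the cut.
5. **Minimum-value imputation** — every missing cell of a measure is
   filled with the measure's smallest detected raw value, expressed on
   the transformed scale by pushing that raw minimum through the *donor
   cell's own* run-day median and osmolality factors before the log-z
   map. The transformed-column minimum would not be equivalent because
   osmolality is participant-specific. Left-censored values are by
   assumption below the detection limit, so the smallest detected value
   is an upper bound for them. All missing cells are imputed — including
   rows for participants who never gave the fluid — because the network
   stage needs a complete table; measures whose missing fraction exceeds
   the 20 % rule are flagged in the audit report.
6. **Low-detection filter** — measures with fewer than `min_detections`
   (default 50) valid detections (counted before imputation) are dropped.

The `PreprocessReport` records, per measure: detections, imputed cells,
outliers removed, the 20 %-rule flag, and a drop reason; the bookkeeping
identity dropped + retained = input is asserted on construction.

A deliberate scope note: association fits (stage 3 below) use only
participants whose fluid sample truly exists; the fully imputed table —
including whole-fluid-imputed rows — is consumed *only* by the GGM stage,
which needs one complete matrix over all participants.

## 2. Synthetic-cohort generator

The generator emulates a 369-participant case–control study (188 cases /
181 controls by default) with the statistical structure the analysis
assumes. It is first-class, tested code; every stage of the pipeline can
be validated against its ground truth.

**Cohort.** Age, BMI ~ group-specific normals (cases 54 ± 11 y, 30 ± 6
kg/m²; controls 41 ± 12 y, 28 ± 5.5 kg/m², clipped to plausible ranges);
sex and four ethnicity strata (Arab reference, South Asian, Filipino,
Other) drawn from group-specific category probabilities; per-fluid sample
availability 328/369 (saliva), 359/369 (plasma), 356/369 (urine);
enrolment order randomised and run-days (default 12) assigned round-robin
in enrolment order; osmolality log-normal per fluid (saliva ~70, urine
~600 mOsm/kg medians).

**Glycaemic latents.** Three unit-variance Gaussian latents (acute,
short-term, long-term burden) with pairwise correlation 0.4; cases are
shifted (short 1.5, long 2.2 latent SD) and widened (SD 1.3). The acute
shift and the glucosuria detection threshold are **derived in closed
form** from the two target detection prevalences (66/188 cases, 2/181
controls) under the Gaussian model: c = Φ⁻¹(1 − p_ctrl), and
μ_acute = c + s·Φ⁻¹(p_case). Observable markers: HbA1c (%) = 5.5 +
0.55·long + N(0, 0.3²); plasma 1,5-AG log-abundance = −0.8·short +
N(0, 0.5²); glucosuria = (acute latent > c). The urinary glucose measure
is censored exactly where glucosuria is absent, mirroring the use of an
MS detection limit as the glucosuria proxy; the control-group HbA1c
spread is narrower than a clinic population's, a deliberate
simplification (only its monotone link to the long-term latent matters to
the pipeline).

**Network truth.** Support is Bernoulli(density) over the p(p−1)/2 pairs;
requested partial-correlation magnitudes are uniform in a configured
range with random sign. Starting from the unit-diagonal matrix with
−ρ off-diagonals, the diagonal is inflated until the smallest eigenvalue
reaches 0.05 and the matrix is rescaled to unit diagonal. This
*diagonal-inflation repair* preserves the support exactly but shrinks
implied magnitudes uniformly when the requested values were too strong to
be jointly realisable; the recorded truth is always the implied partial
correlation computed from the final matrix. (Strict diagonal dominance
was rejected: it caps each node's summed |pcor| below 1 and cannot reach
the magnitudes the recovery experiments need at realistic degrees.
Partial orthogonalisation is a documented alternative.) The default
density 0.0016 matches a sparse metabolite network at p = 2,178 (~3.8 k
potential edges).

**Effects.** A configurable fraction of measures (default 4.3 %,
mirroring 94/2,178) receives a signed diabetes mean shift with magnitude
uniform in 0.45–1.25 latent SD; 70 % of those additionally load on exactly
one glycaemic latent (0.4–1.0), so their within-case variation tracks one
timescale. Measures flagged null have every effect exactly 0.

**Data model.** Log-abundances are multivariate normal with the
correlation implied by the truth precision matrix, mean-shifted by
diabetes and the latents. Cross-fluid duplication — the same molecule
measured in several fluids — is emulated by shared-latent groups (default
147 triples + 391 pairs, matching the observed multiplicities): member
columns equal √a times the source column plus √(1−a) idiosyncratic noise
(a = 0.7). Intensities are exponentials multiplied by per-(measure,
run-day) log-normal batch factors (SD 0.15) and by the participant's
osmolality relative to the fluid reference, then degraded by log-normal
noise with σ = √log(1 + CV²) so the technical CV of replicate
measurements matches the per-fluid targets (15.3 % / 15.8 % / 9.8 %).
Left-censoring applies per-measure detection quantiles drawn from a
Beta(1.2, 8) bulk plus a 3 % heavily censored component (quantile
0.80–0.98) emulating rarely detected xenobiotics; censoring is monotone
in the quantile by construction.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: chromatography/MS peak shapes, medication
effects, non-Gaussian metabolite distributions, missingness mechanisms
other than left-censoring and absent samples, longitudinal structure, and
real biochemical pathway topology (the truth network is random sparse
plus duplication groups).

## 3. Association scan

OLS of each preprocessed measure on the phenotype with covariates age,
sex (female indicator), ethnicity (three contrasts against the Arab
reference) and BMI; β is the phenotype coefficient, p two-sided from its
t statistic; rows with missing response/covariates dropped listwise;
rank-deficient or constant-phenotype fits are flagged unestimable and
returned with p = 1. All fluids form **one pooled Bonferroni family**
(α/m with m the total measures tested), plus the nominal 0.05 tier.
Thresholds are recomputed per run, never cached.

The production path is vectorised multi-response OLS over the shared
design matrix (one solve for thousands of measures); it is asserted
numerically identical to per-measure statsmodels fits in the test suite.
Adding a constant to any covariate leaves β unchanged (affine invariance,
tested), and the nominal type-I error on null simulations is calibrated
within ±0.01 of 0.05.

## 4. Glycaemic-timescale stratification

Candidates are the Bonferroni-significant diabetes measures; fits use
**cases only**, with the metabolite as response and the marker as
predictor plus the usual covariates (the regression direction is a
convention — association is directionless — chosen to match the diabetes
scan's structure). The family is n_candidates × 3 markers. Self-pairs
(urinary glucose vs the acute marker, plasma 1,5-AG vs the short-term
marker) are skipped and reported untested. HbA1c enters as a continuous
percentage; 1,5-AG as its preprocessed z-score (this affects only the β
scale, not p-values). The primary timescale is the marker with the
largest −log₁₀ p; ties break by larger |β|, then the fixed order acute <
short_term < long_term. The Venn partition over the three per-marker
significant sets is disjoint and exhaustive by construction.

## 5. GGM estimation

**Covariate adjustment** is by residualisation (OLS residuals of every
measure on diabetes, age, sex, ethnicity, BMI) rather than by adding
covariates as nodes — covariates must not appear in the network.

**Estimator.** The residual correlation matrix R is shrunk toward the
identity, R* = (1−λ)R + λI, with the analytic data-driven intensity
λ* = Σ_{i<j} Var̂(r_ij) / Σ_{i<j} r²_ij (clipped to [0, 1]), the standard
variance-over-signal ratio for the identity target. This guarantees
invertibility when measures outnumber samples. Partial correlations come
from the standardised inverse. λ = 0 is allowed only when the sample
correlation is numerically invertible; λ = 1 forces an empty network.

**Edge p-values** use the Fisher z-transform with variance
1/(n_eff − 3 − k_adj), where k_adj = 6 counts the regressed-out covariate
columns (diabetes, age, female, BMI, two further ethnicity contrasts
beyond the first — i.e. all non-intercept design columns). This is an
approximation under shrinkage: shrunk coefficients have *smaller*
sampling variance than unshrunk ones, so the test is conservative — the
simulated family-wise error over null datasets is far below the nominal
0.05 (computed by the acceptance suite). The conservatism grows with λ:
at the full n = 369 ≪ p = 2,178 scale the analytic λ is large (≈ 0.4–0.5
on default synthetic data) and only very strong dependencies (such as
shared-molecule duplicates) can reach the 2.1 × 10⁻⁸ edge threshold; the
default-scale synthetic run therefore calls far fewer edges than a
p ≈ 2,000 study analysed with an empirical-null edge test would report.
This is a property of the chosen test, reported honestly by the
acceptance script, not of the estimator (desk-scale recovery at n = 1,000,
p = 50 reaches precision ≥ 0.9 / recall ≥ 0.8 on strong edges).

`n_effective` is configurable because whole-fluid-imputed rows inflate
the nominal n; the default uses the row count, which is conservative in
every direction the Bonferroni test cares about given the shrinkage
conservatism above.

A numerical note: individual |pcor| entries are *not* monotone in λ for
p > 2 (re-weighting the conditioning set can transiently raise an entry);
the maximum |pcor| contracts monotonically, and for p = 2 the single
partial correlation equals (1−λ)r exactly. The tests assert exactly
these properties.

**Subnetworks.** Edges with p below α/(p(p−1)/2) form the network; the
induced subgraph on nominally diabetes-associated measures (scan
p < 0.05) is split into connected components; components with ≥ 3 nodes
are reported, ordered by descending size then lexically smallest node id
(component numbering is otherwise arbitrary). Nodes carry fluid, β,
direction and per-timescale significance attributes in the GraphML
export; SIF and TSV exports mirror the edge list.

## 6. Orchestration and reproducibility

A single `RunConfig` (YAML) drives simulation and analysis; every stage
writes its table (TSV, one-line header, empty field = missing, floats at
6 significant figures) and the run summary asserts its internal
bookkeeping identities (per-fluid sums equal totals, Venn counts sum to
the candidate count, subnetwork nodes ⊆ nominal set). Rerunning from the
written `run_config.yaml` reproduces outputs byte-for-byte; all
randomness flows from the single seed through `numpy.random.SeedSequence`
spawning.

**Problem sizes.** The acceptance script runs the full default-scale
study (n = 369, p = 2,178; ~15 s) plus desk-scale experiments chosen to
make each property measurable with tight Monte-Carlo error: 5,000 null
fits for type-I error, 200 null datasets (n = 400, p = 50) for
family-wise error, 500 replicates for effect-recovery bias, n = 1,000 /
p = 50 for edge recovery, and n_cases = 500 with 0.8 SD single-latent
effects for timescale classification. The unit-test suite uses smaller
cohorts (150–250 per group, 20–30 measures per fluid) for speed.

## 7. Known limitations

* The Fisher-z edge test under heavy shrinkage is strongly conservative
  (see §5); an empirical-null edge test would be needed to call weak
  edges at n ≪ p and is out of scope.
* The generator's truth network is random sparse; it does not reproduce
  pathway-block topology, so subnetwork *shapes* on synthetic data are
  not biologically meaningful — only the recovery mechanics are tested.
* Minimum-value imputation introduces point masses at the censor bound;
  the scan excludes fabricated whole-fluid rows but keeps imputed
  left-censored cells, which mildly attenuates effect estimates for
  heavily censored measures.
* Alternative normalisations (probabilistic quotient, quantile), FDR
  control, graphical-lasso estimation and network layout are explicit
  non-goals.
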