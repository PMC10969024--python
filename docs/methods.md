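# Methods

This note records the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions that
make results exactly reproducible.

## Data model

The central object is a protein × sample grid of log2 intensities with
an explicit missing marker (NaN). Raw zeros in input tables are treated
as missing at read time — a label-free zero means "not quantified", not
"absent at zero abundance" — and values are log2-transformed before any
statistics if they arrive on the raw scale. Protein identifiers are
gene symbols; sample identifiers map through a sample sheet onto a
3 clinical group (CH, PA, MB) × 3 CSF fraction (Tot, SEV, LEV)
factorial design. Every statistical operation that uses a design cell
requires at least two samples in it.

## Preprocessing

**Presence filtering.** A protein is kept if it is quantified in at
least 70 % (inclusive) of the samples of at least one scope cell. The
default scope is the group × fraction cell (9 cells); a per-fraction
scope is available. The cell scope is the stricter reading and is the
one under which per-group exclusivity bookkeeping (which proteins
appear only in one group's samples) remains derivable from the filtered
matrix. Filtering is idempotent and order-preserving; an empty result
is a warning, not an error, so exploratory thresholds can be scanned.

**Imputation.** Missing values are assumed left-censored: a protein is
unquantified mostly because its abundance sits near the detection
limit. Each missing entry in sample *s* is replaced by a draw from
N(μ_s − downshift·σ_s, (width·σ_s)²) with defaults width = 0.3 and
downshift = 1.8 in sample-SD units — the convention popularized by the
Perseus platform for LFQ data. Per-sample moments are the default
(global moments by option); observed entries are never modified, and
the generator is seeded so imputation is reproducible. A sample with
fewer than two observed values cannot supply moments and is a hard
error naming the sample.

**Quantile normalization.** Every sample is forced onto the common
distribution given by the across-sample mean of order statistics. Ties
within a sample receive the mean of the reference values at their tied
rank positions, which keeps the map rank-preserving and idempotent.
Requires a complete matrix, i.e. runs after imputation.

**Row Z-scores** (for heatmap display of significant panels) use the
population (n) denominator, stated so tests can assert exact values;
zero-variance rows are an error listing the offending proteins.

## Unsupervised structure

The sample–sample similarity is Spearman's ρ, robust to the heavy right
tail of intensity data; the MDS distance is 1 − ρ (Euclidean distance
available). Classical (Torgerson) scaling double-centres the squared
distance matrix and embeds on the top-k eigenvectors scaled by
√eigenvalue; axes are sign-canonicalized (largest-magnitude coordinate
positive) so results are deterministic. Negative eigenvalues from
non-Euclidean inputs are clipped to zero.

The outlier screen flags a sample whose median correlation to its peers
falls below median − k·IQR (k = 1.5 default) across samples; the rule
is a deliberately simple robust fence — the screening goal is fixed,
the rule itself is this package's choice.

k-means uses k-means++ seeding, multiple restarts, and canonicalizes
labels by lexicographic centroid order so identical partitions compare
equal across runs. Hierarchical clustering delegates to scipy
(default: average linkage; correlation distance for protein rows,
Euclidean recommended for sample columns).

## Differential abundance

One-way ANOVA across the nine design cells screens for any change;
Welch t-tests (unequal variances, Satterthwaite df) drive the three
case–control contrasts — PA-vs-CH, PA-vs-MB and PA-vs-nonPA (CH and MB
pooled) — per fraction and with all fractions pooled. Fold changes are
mean differences on the log2 scale, oriented so positive means higher
in PA. Degenerate zero-variance proteins get t = 0 (F = 0), p = 1:
conservative and NaN-free.

Benjamini–Hochberg adjustment is implemented directly
(q_(i) = min_{j≥i} p_(j)·m/j, capped at 1) and cross-checked in the
test suite against both a brute-force threshold-scan oracle and
statsmodels. Volcano significance combines q ≤ α with the hyperbolic
curve y ≥ |c/(x − x₀)| in (log2FC, −log10 q) coordinates; the boundary
is inclusive and x = x₀ is never significant. The default c = −log10
0.05 ≈ 1.301 makes the curve pass through (x₀ ± 1, −log10 0.05), a
symmetric anchor tying the curve to the α level in the absence of a
published constant.

Panel logic intersects the per-fraction comparison results: the
three-set Venn partition per fraction (counts and percentages of the
union, one decimal), the panel significant against both control groups
in a common fraction, and the panel significant in every comparison.
All tables carry comparison and fraction labels so set logic can be
re-derived downstream.

## PLS-DA and VIP

PLS2 by NIPALS: per component, iterate w ∝ Xᵀu (normalized), t = Xw,
q ∝ Yᵀt, u = Yq to convergence, then deflate X by t pᵀ and Y by its
regression on t. X columns are mean-centered and unit-scaled by default
(standard for VIP interpretation); Y is the centered one-hot encoding
of PA/non-PA (three-class labels by option). The per-component
y-variance is SSY_a = b_a²·t_aᵀt_a with b_a the inner-relation slope,
which fixes the VIP variant:
VIP_j = √(P·Σ_a SSY_a w²_aj / Σ_a SSY_a), so mean(VIP²) = 1 exactly.
Two components by default, matching the 2-D score-plane reading of the
model. The test suite checks the first weight vector against the Xᵀy
direction and against scikit-learn's PLS implementation (which is
never used inside the pipeline itself).

**Score-plane clustering.** k-means on the score plane reports a Rand
index against the PA/non-PA partition. Score dimensions are
standardized and weighted by √(SSY share) first: raw PLS score
variances are incommensurate, and a later component can carry large
y-irrelevant variance (in these designs, the fraction effect), which
would otherwise dominate Euclidean k-means and make the cluster
assignment reflect spread instead of the class structure the model
captured. Per-class 95 % confidence ellipses come from the 2×2 sample
covariance scaled by the χ²₂ quantile; fewer than three points or a
singular covariance yields a degenerate flag rather than an error.

## Enrichment

**2D rank score.** For two per-protein statistics on a common universe
(by default mean abundance in PA and in non-PA), proteins are ranked
ascending per dimension and each annotation term receives
s = 2·(mean rank inside − mean rank outside)/n, which is bounded in
[−1, 1] and hits the bounds exactly when the term occupies the extreme
ranks. Each dimension also gets a two-sided Mann–Whitney p (in-term vs
out-of-term values) with BH across terms; terms below the minimum size
(default 5) are dropped, terms disjoint from the universe are skipped
with a warning. Because the statistic is rank-based it is invariant
under any strictly monotone transform of the inputs.

**Diagonal classification.** Terms are called enriched on one side of
the x = y diagonal when |s_x − s_y| exceeds the ci-level quantile of
the same quantity under membership permutation (term sizes preserved,
members redrawn uniformly; seeded). A permutation band was chosen over
an analytic one because the null correlation between s_x and s_y
depends on the empirical coupling of the two dimensions.

**Kinase enrichment.** One-sided Fisher exact over-representation of
each kinase's substrate set (GMT input) within a query set — typically
the significant proteins — over the quantified universe, BH-adjusted
and sorted by q then odds ratio. Substrate libraries are supplied by
the user rather than bundled: database versions drift, and results are
library-dependent by construction.

## Assay validation

**Standard curve.** A direct ELISA in its linear range is modelled as
absorbance linear in log2(dilution factor) of the serial two-fold
dilution series of a reference pool defined as 1 RU/mL. The mean
background absorbance is subtracted from every well, the standards are
fit by least squares, and sample titers are 2^(−log2 d̂) at the
inverted dilution. A four-parameter logistic was deliberately not used:
the relative-quantitation design anchors to the dilution series, not to
a saturating sigmoid. The lower detection limit is mean blank + 3 SD;
samples below it, and samples outside the standard absorbance range,
are flagged rather than dropped. Titers are invariant to a global gain
applied to all wells.

**ROC.** AUC is computed by the Mann–Whitney construction (half credit
for ties), identical to the trapezoid over the empirical curve;
confidence intervals and the p-value against AUC = 0.5 use DeLong's
asymptotic variance from placement values. Orientation is flipped (and
recorded) when AUC < 0.5 so that "higher score ⇒ case" always holds.
The Youden cutoff maximizes J = sens + spec − 1, ties broken toward
higher sensitivity, with the positive call being "score > cutoff";
LR⁺ = sens/(1 − spec) is reported to one decimal and is infinite at
perfect specificity. Qualitative AUC bands use half-open bins:
exactly 0.5 not discriminant, [0.5, 0.6) fail, [0.6, 0.7) poor,
[0.7, 0.8) fair, [0.8, 0.9) good, [0.9, 1] excellent.

**Sample size.** The planner starts from the normal approximation
n = 2(z_{1−α′/2} + z_{power})²/Δ² and then increments n until the exact
noncentral-t power of the two-sample test reaches the target; the
normal formula alone undershoots slightly at small n (at Δ = 1 SD,
α = 0.05, power 0.80 it suggests 16 per group where the exact power is
0.781; the planner returns 17, exact power 0.807). Multiplicity enters
as a Bonferroni-adjusted α′ = α/n_tests — a conservative planning proxy
for FDR-controlled analysis, since BH-aware planning would need an
assumed fraction of true effects. n is floored at 2 per group. A
Monte-Carlo companion (`empirical_power`) estimates achieved power by
simulated Welch tests; being a finite-replicate binomial estimate it
fluctuates around the exact value, so checks against the target are
made within Monte-Carlo error.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with ground truth for recovery tests:

- **Intensities** are Normal on the log2 scale (log-normal LFQ), with
  per-protein baselines drawn once from N(25, 2) — typical MaxQuant
  LFQ magnitudes — and i.i.d. technical noise SD 0.5 per sample.
- **Fraction structure**: each fraction applies a distinct random
  offset vector (SD 2) to a fixed random 30 % of background proteins.
  This is what separates Tot/SEV/LEV in MDS while leaving the clinical
  groups unseparated there, since the offsets are identical across
  groups.
- **Spiked markers**: by default one protein up-regulated (+3 log2)
  and one down-regulated (−3) in PA, mirroring the roles of the
  CPXM2/AQP4 marker pair. Marker baselines are pinned at 27 (one SD
  above the bulk) and markers are excluded from the fraction-offset
  subset: validated biomarkers are, by selection, abundant and
  reliably quantified proteins, and the markers' role in the benchmark
  is to carry a clean group effect. The ±3 magnitude (8-fold) reflects
  a strong, assay-validatable marker; with the per-fraction design
  (n = 8 vs 8) and ~1000 simultaneous BH-corrected tests, per-fraction
  rediscovery of a marker requires p ≲ 10⁻⁴, which is exactly the
  regime a validated biomarker occupies and which substantially weaker
  spikes would not reliably reach.
- **Missingness** is missing-not-at-random: each entry drops with
  logistic probability 1/(1 + exp(steepness·(x − midpoint))), default
  midpoint 20 and steepness 1.5, i.e. dropout concentrated in
  genuinely low-abundance proteins and essentially absent above the
  bulk mean (~2–3 % missing overall). The logistic form (rather than a
  hard threshold) keeps dropout probabilities smooth so expectations
  are testable in closed form.
- **Design**: 8 samples per group × fraction cell (the discovery-scale
  cohort the pipeline targets), 3 groups × 3 fractions, seeded end to
  end — the same spec and seed always yield byte-identical data.

What passing the synthetic recovery tests shows: the pipeline's
filtering, imputation, normalization, testing, multiplicity control,
VIP ranking and unsupervised steps jointly recover planted effects of
realistic size and direction, and do not hallucinate group structure
that is not there (fraction clusters are found, group clusters are
not; all-null data yields a controlled false discovery fraction).
What it does not show: robustness to correlated proteins (covariance
is diagonal here), batch effects, peptide-level artefacts,
non-Gaussian heavy tails, or missingness mechanisms other than the
logistic left-censoring — real-data performance on those axes is not
certified by this benchmark.

## Numerical conventions and degenerate inputs

- All stochastic steps take explicit seeds; the pipeline driver derives
  every stage's randomness from one config seed, so identical
  config + seed gives byte-identical output files.
- Percentages in panel bookkeeping are rounded to one decimal
  (100·count/union).
- Zero-variance proteins: p = 1, never significant. Constant rows are
  errors where a Z-score is requested. Empty filter results warn.
- Boundary policies are inclusive: presence exactly at threshold is
  kept, a volcano point exactly on the curve is significant, AUC
  exactly 0.5 is "not discriminant".
- BH q-values are monotone on the sorted p scale and capped at 1.
- Problem sizes in the test suite are chosen to keep the full suite in
  the seconds-to-a-few-minutes range: oracle equivalences run at small
  n where enumeration is exact; the synthetic recovery scenario uses
  the default 1000 × 72 dataset once; null-calibration uses 200
  replicates of a 300-protein, 4-per-cell design.

## Known limitations

- PLS-DA uses no cross-validated component selection or permutation
  testing of class separation; the VIP list is a ranking, and any
  cutoff on it is the user's choice.
- The moderated-variance (empirical Bayes) family of tests is out of
  scope by design; with n = 8 per cell Welch tests are adequate for
  strong effects but underpowered for subtle ones.
- DeLong inference is asymptotic; for very small validation cohorts a
  bootstrap CI (available by option) may be preferable.
- GO-graph ancestor propagation is not performed; terms are taken as
  given in the GMT input.
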