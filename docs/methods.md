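# Methods

## Statistical model

The unit of analysis is the subject. After QC filtering, every subject is
coded as a binary carrier indicator per gene (≥1 retained variant), and
each gene's carrier counts form a 2×2 table against case/control status.
Enrichment in cases is tested with the one-sided Fisher exact test — the
hypergeometric upper tail P(X ≥ a) at fixed margins — and depletion is
never tested: the alternative is fixed as carriers-enriched-in-cases, and
flipping it would silently halve or double p-values. Effect sizes are
Woolf odds ratios ad/bc with log-normal confidence intervals using
SE = √(1/a+1/b+1/c+1/d) and the exact normal quantile
z = 1.959963984540054 (not 1.96 rounded). The Haldane–Anscombe +0.5
correction is applied only when a cell is zero, and the result is flagged;
with no carriers in either group the odds ratio is undefined (NA). Note
one divergence from the source tables this package is benchmarked
against: a gene carried by cases only (zero control carriers) gets a
corrected, flagged odds ratio here, where the original report printed NA.
Group prevalences carry Wilson score intervals, which have better
small-sample coverage than Wald.

Multiple testing: the family-wise threshold is α/m where m counts genes
with at least one carrier in either group — genes carried by nobody are
untestable and excluded; genes carried only by controls remain testable
(their one-sided p ≈ 1). Benjamini–Hochberg q-values are computed
alongside. 0.05/13,281 = 3.7648×10⁻⁶; the benchmark publication prints
this as 3.77×10⁻⁶, a rounding-up of the correct 3.76 at three
significant figures. Scan output is sorted by ascending p with
lexicographic tie-breaks so results are byte-deterministic.

The observation-inflation diagnostic reports both the raw ratio of case
to control subject–variant observations (143,422/7,565 ≈ 19 at the
benchmark scale) and the ratio-of-ratios against the subject-level 86/30
(≈ 6.6). Both are labelled explicitly because "inflation factor" is
ambiguous between them.

## Variant QC

A call is retained iff QUAL ≥ 30, depth ≥ 10, in-read VAF ≥ 0.20,
strand-bias p > 0.001 (strict, as specified), mapping quality ≥ 40, and
population MAF < 0.2. A missing population frequency is a distinct
*novel* state — never imputed to zero — and novel variants pass the MAF
criterion. Removals are audited against the first failing criterion in
that fixed order, so audit counts partition the removals. Duplicate
(subject, locus, allele) rows are a hard error rather than a silent
dedup, because carrier counting must not be distorted; multi-allelic
rows must be pre-split.

## Damage score

Base scores: stop-gain and frameshift 10, canonical splice 9, missense 5,
all other consequences 0. Add-ons: ClinVar P/LP +4, homozygous +2, novel
+2, rare (MAF < 0.01, present) +1; novelty and rarity are mutually
exclusive. The add-on magnitudes are this package's own calibration
(only the base scores are externally specified): they are chosen so that
no single non-ClinVar add-on can promote a missense variant above a
splice variant, and they are fully configurable through
`DamageWeights`.

## Synthetic cohort generator

Individual-level data from family studies of this kind are protected, so
all testing runs on synthetic cohorts. Design choices:

- **Case–control sampling, not a liability model.** Disease status is
  assigned per subject to match target fractions (default 86/116 cases,
  21/86 pediatric-fracture cases); genotypes are then drawn conditional
  on status. The analysis only consumes status-conditional carrier
  frequencies, and this makes configured odds ratios exact generative
  targets: p₁ = OR·ω₀/(1+OR·ω₀) with ω₀ = p₀/(1−p₀). A per-gene
  fracture odds ratio multiplies the case odds again for
  pediatric-fracture cases, so within-case contrasts are exact targets
  too.
- **Family structure.** 43 families with sizes drawn from a categorical
  distribution on {1,2,3,4} (probabilities 0.15/0.20/0.45/0.20, mean 2.7
  ≈ 116/43, favouring trios). The family composition distribution is a
  modelling choice; only the total cohort shape is externally
  constrained.
- **Transmission mode.** Founders draw carrier status at their group's
  probability; each founder variant is transmitted to each child
  independently with probability 1/2 (children share the founder's exact
  variant alleles, which is what makes parental-origin assignment and
  sib–sib correlation meaningful). The child's carrier status is then
  topped up with an independent draw — or thinned, when inherited
  carriage exceeds the target — so the marginal carrier probability
  equals the group target exactly while within-family correlation is
  preserved. The inheritance probability used for the top-up is computed
  analytically: a carrier parent with 1+Poisson(μ) variants transmits
  none with probability 0.5·e^(−μ/2).
- **Annotations.** Carrier variants are dressed from configurable
  categorical profiles (mostly missense/synonymous, ClinVar mostly
  absent/VUS, ~15% novel, log-uniform allele frequencies below 0.19);
  quality fields pass default QC by construction, with an optional
  contamination fraction that injects known QC failures for filter
  tests. All randomness flows from one integer seed (default 42) through
  a single NumPy generator.

What the generator does **not** emulate: linkage disequilibrium,
realistic site-frequency spectra, sequence context, genotyping error
correlated with coverage, or more than two generations. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not robustness to those real-data features.

The null-calibration condition draws per-gene control prevalences
uniformly on [0.05, 0.40], spanning the per-gene (3–30%) and pathway
(up to 30%) control prevalences of the benchmark tables, and uses
independent mode (the calibration concerns the marginal test, not family
correlation). Pooled over ≥100,000 gene-tests, the fraction of one-sided
p < 0.05 sits near 0.025: below the nominal 0.05 because the exact test
is conservative under discreteness at n = 86/30.

## Family-structure sensitivity analyses

1. **Leave-one-per-family**: one uniformly chosen member is removed from
   every family with ≥2 members (singletons untouched; no family ever
   loses its last member). The number of resamples (default 25, median p
   reported) is this package's choice; a single draw would be noisy.
2. **Within-family permutation**: case/control labels are shuffled only
   inside each family block, preserving each family's label multiset —
   the only reading under which "preserving family structure" constrains
   the null. The permuted statistic is the one-sided Fisher p; "as or
   more extreme" means permuted p ≤ observed p; the empirical p uses the
   add-one rule (b+1)/(B+1) and can never be zero. Default B = 10,000
   for sensitivity runs, 1,000 for quick mode. The tie-counting rule
   makes the empirical p mildly conservative (its null mean sits
   slightly above 0.5), and cohorts whose families are mostly
   label-homogeneous have little permutation support — with fully
   homogeneous families every permutation reproduces the observed
   labelling and p = 1 exactly.
3. **Family random-intercept logistic model**:
   logit P(case) = β₀ + β₁·carrier + u_family, u ~ N(0, τ²), fitted by
   maximum likelihood with 25-point Gauss–Hermite quadrature over the
   random intercept (three τ starts for the Nelder–Mead search), Wald p
   from the full 3-parameter observed information (finite differences);
   when τ collapses to the zero boundary, the information over the fixed
   effects alone is used — there the model is exactly ordinary logistic
   regression, and the fit matches `lme4::glmer` closely in both
   regimes. Perfect or quasi-perfect separation (|β₁| > 15 or a
   non-invertible Hessian) is flagged rather than reported as a
   spuriously tiny p. This fitter is implemented in-package because no
   installed Python library provides maximum-likelihood binomial GLMMs
   with Wald tests; Bayesian MAP alternatives shrink the coefficient
   enough to miss the collapse property.

## Cross-validation scaffolding

Folds are assigned to subjects (stratified by label, per-fold class
balance within one subject of global), and every observation inherits
its subject's fold, so no individual spans the train/test boundary.
Observation-level predicted probabilities are averaged per subject
(probability mean, not vote majority — the aggregation rule is this
package's choice), thresholded at 0.5 with ties predicting control; AUC
uses the subject-level mean probabilities; repeats default to the ten
seeds 42, 123, 456, 789, 1011, 1213, 1415, 1617, 1819, 2021. Bootstrap
CIs resample subjects, never observations, redrawing degenerate
one-class resamples and logging the count. The reference classifier is
L2-regularized logistic regression for determinism; any object with
`fit`/`predict_proba` plugs in.

The leakage demonstration uses a constructed fixture: each subject has a
private Gaussian feature centroid (40 subjects × 8 observations, 40
features, centroid scale 3, noise 0.5) and labels are assigned per
subject independently of the features. Naive observation-level folds let
the classifier memorize subject identity and recall the training label
on held-out observations of the same subject (accuracy ≈ 100%);
subject-stratified folds remove that path (accuracy ≈ chance). The gap
direction is guaranteed by construction; its magnitude (tens of points)
is checked empirically. Absolute classifier accuracies from the
benchmark study are not reproducible without the protected cohort and
are deliberately not targets.

## Power simulation

Carrier counts are simulated directly — cases ~ Binomial(86, p₁),
controls ~ Binomial(30, p₀) — and each table is tested with the same
one-sided exact test as the scan; power is the rejection fraction with
MC SE √(p̂(1−p̂)/n_sim), n_sim = 20,000 by default. Empirical size at
OR = 1 stays below nominal α (conservatism of the exact test). At the
reference design point (p₀ = 0.20, OR = 3.0) this simulation gives ≈67%
power, noticeably below the 80% often quoted for that configuration from
normal-approximation or unconditional methods; the exact-test
recomputation is authoritative here and the discrepancy is expected to
be method-dependent, so no equality is asserted.

## Trio pattern detection

Parental origin is assigned by exact (chrom, pos, ref, alt) match
against each parent's calls — no phasing inference. A variant present in
both parents is ambiguous and satisfies neither side of an inheritance
pattern; de novo variants never satisfy inheritance-based patterns.
Compound heterozygosity requires ≥2 distinct heterozygous child variants
in one gene with ≥1 unambiguously maternal and ≥1 unambiguously
paternal. Trans-heterozygous pathway disruption requires maternal-only
and paternal-only variants in two *different* member genes of a set.
The additive-load detector requires the child's total damage score to
reach a caller-supplied threshold with positive contributions from both
parental sides; the threshold is mandatory because no principled default
exists for where combined mutational load becomes clinically meaningful.
Detection is annotation-agnostic (no minimum deleteriousness is imposed
on compound-het variants beyond zygosity and origin).

## Built-in pathway sets

The five shipped gene sets are the enumerated lists: HLA/adaptive immune
(9 genes), collagen biosynthesis (13), mitochondrially encoded OXPHOS
(13 symbols — the source labels this set "11 genes" but enumerates 13;
the enumerated list is used verbatim), structural/cytoskeletal (13), and
protocadherin gamma (PCDHGA1–12 + PCDHGB1–7 = 19 symbols, similarly
labelled "16"). Enumerated lists are testable; count labels are not.
User GMT files may extend or override the built-ins.

## Problem sizes

Defaults are sized for a laptop-class single CPU: null calibration pools
~100,000 gene-tests from 250-gene null cohorts; parameter recovery uses
200 replicate cohorts per configuration; permutation runs use
B = 10,000; power grids use 20,000 simulations per cell. The full
acceptance recomputation takes about two minutes.
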