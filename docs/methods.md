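# Methods

This note describes the statistical model behind `intgen`, the design
decisions that shape its defaults, and the evidence behind its quantitative
claims. It is the package's own scientific account; every number quoted here
is computed by the code in this repository.

## 1. Scientific question

Mood disorder and anxiety disorder co-occur, share treatments and share
genetic risk. Biobank studies can define each disorder in many ways — a
nurse-interview self-report, current medication, a single help-seeking
question, questionnaire instruments (GAD-7, short-form CIDI), an online
self-report, hospital admission codes, or primary-care codes — and it is not
obvious which definitions best capture common-variant (polygenic score) or
rare-variant (pathogenic CNV carrier) signal, nor whether a combined
*internalising disorder* (mood OR anxiety) phenotype is more informative
than either disorder alone. `intgen` builds a fully synthetic biobank in
which the true generative answer is known, derives all eight phenotype
definitions from realistic raw records, runs the association analyses, and
validates each statistical primitive against an independent oracle.

## 2. Generative model

### 2.1 Liability-threshold phenotypes

Each individual has two latent liabilities,

```
L_mood = sqrt(h2_mood)·G_mood + s(carrier) + beta_age·age_z + sqrt(1 − h2_mood)·E_mood
L_anx  = sqrt(h2_anx) ·G_anx  + s(carrier) + beta_age·age_z + sqrt(1 − h2_anx) ·E_anx
```

where `G_mood, G_anx` are standardised polygenic factors with
`corr(G_mood, G_anx) = r_genetic` (default 0.8), the environments are
correlated at `r_env = 0.3`, and `s(carrier)` adds a fixed liability shift
per carried pathogenic CNV locus. Disorder status is `L > tau_gender`, with
gender-specific thresholds solved numerically (Brent's method) so that the
population prevalence hits its target (mood 20%, anxiety 15%) *and* the
female:male odds ratio on the binary scale equals `female_or = 1.8`.
Internalising disorder is the union of the two.

### 2.2 Genotypes

Variants draw ancestral allele frequencies uniformly from the configured
MAF range; population-specific frequencies follow the Balding–Nichols model
`p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F)` with `F = fst` (default 0.1 across two
populations mixed 90:10). Dosages are imputation-style expected allele
counts with per-variant INFO scores; a small fraction of variants carries
low INFO or high missingness so the QC stage has real work to do. True
per-variant effects for the two disorders are correlated at `r_genetic`;
two *weight tables* are derived from them by adding noise — a low-noise
table standing in for a large discovery GWAS of major depression and a
high-noise table standing in for a smaller anxiety GWAS. This reproduces
the empirical situation in which the depression score is the stronger
instrument for every outcome, including anxiety.

### 2.3 Observation model

Raw records are generated per source *conditional on availability*:
touchscreen and interview for everyone, hospital records for everyone,
primary-care linkage for 40%, and the online mental-health questionnaire
for 31.61% of non-carriers but only 26.16% of CNV carriers (uptake ratio
0.2616/0.3161), encoding the observed participation bias of carriers.
Each (definition, disorder) pair has a configured sensitivity and
specificity with which the truth is transcribed into records: codes at the
interview, medication codes (antidepressants for mood; antidepressants or
non-temazepam benzodiazepines for anxiety — temazepam appears as a pure
hypnotic red herring), ICD-like hospital codes, Read-like primary-care
codes, MHQ self-report codes, GAD-7 items whose total crosses 10 exactly
when the latent flag says so, and CIDI-SF items in which non-cases fail at
least one scoring criterion at random (including the cardinal-symptom
gate). Under a perfect observation model (sensitivity = specificity = 1,
full availability) every definition except the deliberately
cross-contaminated medication one reproduces the latent truth exactly;
this invariance is a test.

### 2.4 CNV calls and kinship

Carrier truth at ten loci (summed carrier frequency ≈ 1.6%) is emitted as
PennCNV-style calls with probe counts, lengths and confidence scores, plus
background calls and deliberate QC failures; per-sample array metrics
(call count, waviness, call rate, log-R-ratio SD) include failing samples.
A small fraction of sample pairs is related (kinship 0.09–0.25), with
sub-threshold pairs retained as negative controls.

## 3. Analysis pipeline

1. **Variant QC** — INFO ≥ 0.9, missingness ≤ 0.05, MAF ≥ 0.01, HWE exact
   p ≥ 1e-6 (full Wigginton enumeration up to n = 1000, chi-square above).
   HWE is computed **within the largest population**, not on the pooled
   cohort: pooling two populations diverged at fst = 0.1 produces a
   heterozygote deficit (Wahlund effect) that would reject nearly every
   variant for population structure rather than genotyping error.
2. **Relatedness** — one random member of each pair with kinship > 0.0884
   is removed (strictly greater; the boundary value is second-degree).
3. **Scoring** — weight tables are reconciled to the genotypes by allele
   (direct match, effect/other flip, strand complement, or drop);
   missing dosages are mean-imputed; flipped variants contribute `2 − d`.
4. **Ancestry adjustment** — variants are LD-pruned (sliding window
   500/step 50/r² > 0.05, greedy, higher-missingness member dropped), a
   reference panel is decomposed by PCA (k = 5, deterministic sign), cohort
   samples are projected with reference standardisation constants, the raw
   score is regressed on the reference PCs, and the residual is divided by
   the residual SD (a residual-variance denominator is available as a
   switch). Adjusted scores are therefore mean-0/SD-1 and free of ancestry
   gradients: on a 50:50 two-population panel the raw between-population
   score gap of ~0.55 SD collapses to per-population |mean| < 0.05 with
   variances within 1 ± 0.1.
5. **Phenotyping** — the eight definitions are derived per disorder from
   the raw records; controls require the defining source to be available;
   internalising is case if either component is a case and control only
   when both are observed controls; individuals with schizophrenia/bipolar
   codes in any source are excluded.
6. **CNV stage** — samples fail QC at ≥ 30 CNVs, |waviness| > 0.03, call
   rate < 0.96 or LRR SD > 0.35; calls fail below 20 probes, probe density
   below 1/20 kb or confidence below 10; loci with fewer than 5 carriers
   after QC are dropped.
7. **Association** — logistic regression (own IRLS; |Δdeviance| < 1e-8,
   Wald inference, explicit separation/non-convergence flags) of each
   definition × disorder on each predictor, adjusting for gender, age and
   ten cohort-derived principal components. Reported per model: OR with
   95% CI, p, Nagelkerke ΔR² (full vs covariates-only), and full-model
   ROC AUC. Families are Bonferroni-corrected: 0.05/16 = 3.125e-3 for the
   PRS family, 0.05/24 ≈ 2.083e-3 for the carrier family. Secondary
   models: anxiety conditioned on mood (carrier effect independent of
   mood), gender × predictor and PRS × carrier interactions.
8. **Effect-size comparison across definitions** — analyses of different
   definitions share subjects, so their log-OR estimates are correlated.
   The correlation is computed analytically from the shared case/control
   counts (Lin–Sullivan):

   ```
   r = [ n11·sqrt(n0_1·n0_2/(n1_1·n1_2)) + n00·sqrt(n1_1·n1_2/(n0_1·n0_2)) ]
       / sqrt(n_1·n_2)
   ```

   and the difference is tested with
   `z = (b1 − b2)/sqrt(se1² + se2² − 2·r·se1·se2)`. Comparing a result
   with itself gives z = 0 by construction; near-identical designs with
   different estimates are reported as non-informative rather than as an
   unstable z.
9. **Descriptives** — per-definition prevalences (by gender) and
   tetrachoric correlations between definitions (1-D maximum likelihood
   over the latent bivariate-normal correlation with thresholds fixed at
   the probit of the margins).

## 4. Validation evidence

All of the following run in the test suite and the acceptance script.

- **Overlap-corrected z-test calibration.** Under a null with equal true
  effects (n = 10 000 per arm, 2 000 replicates), the corrected test
  rejects at 5.1/5.5/5.0/5.3% for overlap fractions 0/0.25/0.5/0.9; the
  naive r = 0 test collapses to 0.3% and 0.0% at 0.5 and 0.9 overlap.
- **Overlap-correlation oracle.** The analytic r at 50% overlap (0.5000)
  matches the empirical correlation of the two estimates over 5 000
  Monte-Carlo replicates within 0.005.
- **Parameter recovery.** The logistic-scale reference effects of the
  standardised polygenic score and of carrier status (from one 10⁶-person
  latent-only run) are covered by the replicate 95% Wald CIs in 96.0% and
  96.5% of 200 full genotype→score→regression replicates.
- **Union-phenotype property.** For a score of the *shared* genetic factor
  (what a depression PRS proxies at high genetic correlation), the union
  phenotype's AUC is at least the maximum of the component AUCs in ≥ 98%
  of 100 replicates of n = 100 000 — the union's controls are screened on
  both liabilities, so they are more depleted of high-score individuals.
  A disorder-specific score instead lands between the two component AUCs;
  both behaviours are documented in `calibration.union_auc_experiment`.
- **Primitive equivalences.** IRLS coefficients match `statsmodels.Logit`
  to 1e-6 and direct BFGS likelihood maximisation to 1e-6; ROC AUC equals
  all-pairs enumeration exactly (ties counted half); the tetrachoric MLE
  matches an independent bounded-search oracle to 1e-3 and recovers a
  known latent correlation of 0.6 to 0.02; the HWE exact test matches the
  chi-square approximation in its large-n regime; every QC boundary
  (≥ / > / < semantics) is pinned by an explicit test.

## 5. Design decisions and limitations

- **HWE within one population.** Standard pooled HWE filtering is invalid
  under strong structure; computing it within the largest population keeps
  the filter aimed at genotyping artefacts. Single-population
  configurations are unaffected.
- **Medication phenotype cross-contamination.** Antidepressants treat both
  disorders, so the medication-based mood and anxiety definitions
  deliberately overlap; the temazepam exception (a benzodiazepine that
  never qualifies for the anxiety definition) is modelled explicitly.
- **Carrier participation bias.** MHQ-based definitions under-sample CNV
  carriers by construction (26.16% vs 31.61% completion), which attenuates
  carrier associations for questionnaire definitions — an intended,
  realistic property, not a bug.
- **Problem sizes.** The default 50 000 individuals × 2 000 variants × 10
  CNV loci are the package's own desk-scale choices; they preserve the
  qualitative structure (definition-dependent prevalence, PRS/CNV signal,
  participation bias) at minutes of runtime rather than biobank scale.
- **Scale of the adjusted score.** The PC-residual is divided by the
  residual SD by default, giving unit-variance scores whose logistic
  coefficients read per-SD; dividing by the residual variance is offered
  as a compatibility switch and changes only the scale of the reported OR.
- **Simplifications.** One chromosome-like variant block; no genotype
  calling from intensities; no longitudinal records; code lists are small
  synthetic stand-ins for licensed clinical code lists; liability-scale
  truth has no closed-form logistic counterpart, so generator recovery is
  benchmarked against a large Monte-Carlo reference rather than an
  analytic value.
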