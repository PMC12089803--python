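# intgen

Synthetic-biobank genetics of **internalising disorders**: how much
common-variant (polygenic score) and rare-variant (pathogenic CNV carrier)
signal do different *definitions* of mood disorder, anxiety disorder and
their union capture?

Biobank studies can define the "same" disorder from a nurse-interview
self-report, current medication, a single help-seeking question,
questionnaire instruments (GAD-7, short-form CIDI), an online self-report,
hospital admission codes, or primary-care codes. These definitions differ
in prevalence, misclassification and participation bias, and analyses of
different definitions share most of their subjects — so comparing effect
sizes across them needs an overlap-aware test. `intgen` simulates a cohort
in which the generative truth is known, derives all eight definitions from
realistic raw records, and runs the full association battery:

- **Generator** — liability-threshold model with correlated mood/anxiety
  genetic factors (Balding–Nichols population structure, gender-specific
  thresholds, pathogenic-CNV liability shifts), an explicit
  sensitivity/specificity observation model per definition, source
  availability (including lower questionnaire uptake for CNV carriers),
  PennCNV-style call/QC data and related pairs.
- **Phenotyping** — eight definitions × three disorders from raw records
  with clinical code lists, GAD-7 and CIDI-SF scoring, union semantics and
  schizophrenia/bipolar exclusions.
- **PRS engine** — variant QC (INFO/missingness/MAF/exact HWE), KING-style
  relatedness pruning, allele-reconciled scoring, LD pruning, reference
  PCA projection and PC-residual ancestry adjustment.
- **Association** — own IRLS logistic regression with Wald inference,
  Nagelkerke ΔR², ROC AUC, tetrachoric correlations, interaction and
  conditional models, Bonferroni families.
- **Overlap-aware comparison** — analytic correlation between effect
  estimates from overlapping case–control analyses and the corrected
  z-test for effect-size differences, with Monte-Carlo calibration
  experiments.

## Quick start

A small end-to-end run with a printed report:

```bash
intgen demo --out demo_run --seed 7
```

The full pipeline at default scale (50 000 individuals, ~5 minutes):

```bash
intgen run --out results/run1 --seed 2026
```

which writes `cohort.tsv`, `prevalence.tsv`, `tetrachoric.tsv`,
`prs_associations.tsv`, `cnv_associations.tsv`,
`conditional_associations.tsv`, `interaction_tests.tsv`,
`pairwise_comparisons.tsv`, `summary_report.txt` and a `manifest.json`
with a SHA-256 per output. Individual stages are exposed as `intgen
simulate / qc / phenotype / prs / cnv / associate`.

From Python:

```python
from intgen import RunConfig, SimulationConfig, run_pipeline, write_results

cfg = RunConfig(
    out_dir="results/run1",
    simulation=SimulationConfig(n_individuals=20_000, n_variants=1_000, seed=1),
)
result = run_pipeline(cfg)
print(result.prs_results[["definition", "disorder", "predictor", "or_", "p", "auc"]])
write_results(result)
```

Runs are byte-deterministic for a given configuration and seed.

## Worked example

```python
import numpy as np
from intgen import SimulationConfig, generate_dataset
from intgen.phenotyping import derive_all, prevalence_report
from intgen.prs import score_prs, variant_qc
from intgen.association import fit_logistic

ds = generate_dataset(SimulationConfig(n_individuals=5_000, n_variants=500, seed=11))

# variant QC, then score the depression weight table
keep, report = variant_qc(ds.genotypes)
gm = ds.genotypes.subset_variants(keep)
raw, _ = score_prs(gm, ds.weights["mdd"])
prs = (raw - raw.mean()) / raw.std()

# derive phenotypes and test one definition
flags = derive_all(ds.records)
print(prevalence_report(flags).head())

sel = flags.query("definition == 'cidi_sf' and disorder == 'internalising'")
y = sel.set_index("id")["status"].map({"case": 1.0, "control": 0.0}).reindex(gm.samples)
res = fit_logistic(y.to_numpy(), prs, outcome="cidi_sf:internalising", predictor="prs_mdd")
print(f"OR {res.or_:.2f}  p {res.p:.2e}  AUC {res.auc:.3f}")
```

## Tests

```bash
python -m pytest -q tests/
```

The suite (≈130 tests, ~2 minutes) covers unit behaviour, property-based
checks (hypothesis) and scientific acceptance tests: calibration of the
overlap-corrected z-test, the analytic-vs-Monte-Carlo overlap correlation,
ancestry-adjustment quality, CI coverage of generator-injected effects, the
union-phenotype prediction property, and oracle equivalences of every
statistical primitive (statsmodels, direct likelihood maximisation,
all-pairs AUC enumeration, brute-force tetrachoric MLE, QC boundary
semantics).

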