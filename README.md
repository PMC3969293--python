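# numbersense

Twin and SNP-based variance decomposition of numerosity-discrimination
phenotypes, with a synthetic-data layer so every stage is testable without
any external data.

The package covers a complete analysis chain for individual differences in
non-symbolic number comparison ("number sense"):

- **`numbersense.numerosity`** — score trial-level dot-comparison sessions:
  accuracy counts, reaction-time outlier trimming by a sample-size-dependent
  moving criterion, and per-subject Weber-fraction estimation by weighted
  least squares against the Gaussian approximate-number-system psychometric
  curve.
- **`numbersense.preprocess`** — phenotype transformation (accuracy squared,
  √Weber), standardization, OLS residualization on age and sex, ±3 SD
  screening, and a descriptives table with a two-way sex × zygosity ANOVA.
- **`numbersense.twin_models`** — intraclass correlations and maximum-
  likelihood twin models (saturated, ACE, AE, E) with full-information
  likelihood over complete pairs and singletons, LRT/AIC/BIC model
  selection, and profile-likelihood confidence intervals.
- **`numbersense.sex_limitation`** — five-group (MZm/MZf/DZm/DZf/DZos)
  Full / Common-Effects / Scalar / Null sex-limitation models, including a
  free opposite-sex genetic correlation in the Full model.
- **`numbersense.gcta_greml`** — genetic relationship matrix from SNP
  dosages, greedy pruning of related pairs at a ±0.025 cutoff, and
  average-information REML SNP-heritability estimation with a delta-method
  standard error. Reads/writes PLINK bed/bim/fam and GCTA binary GRMs.
- **`numbersense.synthetic_data`** — generators with known ground truth:
  ACE-structured twin phenotypes across five zygosity-by-sex groups,
  150-trial comparison sessions driven by a per-subject Weber fraction
  (truncated-lognormal population), and biallelic SNP panels with a chosen
  SNP heritability.
- **`numbersense.pipeline`** — end-to-end orchestration from one YAML
  config with per-stage artifacts and a deterministic JSON summary.

## CLI

```bash
numbersense --version
numbersense simulate twins    --seed 1 --out out/            # twin phenotype TSV
numbersense simulate sessions --seed 1 --n-subjects 50 --out out/
numbersense simulate snps     --seed 1 --out out/            # PLINK triplet
numbersense score    --trials out/trials.csv --out out/scores.tsv
numbersense prep     --pheno out/twin_pheno.tsv --out out/prep --seed 1
numbersense twin-fit --pheno out/twin_pheno.tsv --out out/fits
numbersense sexlim   --pheno out/twin_pheno.tsv --out out/sexlim
numbersense greml    --bfile out/panel --pheno out/pheno.tsv --out out/greml
numbersense run      --config config.yaml                    # full pipeline
```

A minimal pipeline config:

```yaml
out_dir: out/run1
seed: 7
twins:
  a2_m: 0.32
  c2_m: 0.0
  e2_m: 0.68
  a2_f: 0.32
  c2_f: 0.0
  e2_f: 0.68
  n_pairs_by_group: {MZm: 317, MZf: 519, DZm: 335, DZf: 398, DZos: 689}
models: [saturated, ACE, AE, E]
# optional stages:
# sessions: {n_subjects: 100}
# snps: {n_individuals: 1000, n_snps: 5000, h2_snp: 0.0, n_causal: 100}
```

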