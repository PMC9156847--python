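# dnmsuite

Trio-based *de novo* mutation (DNM) analysis on synthetic cohorts: a
simulator for parent–offspring trios with ground truth, consensus DNM
calling, read-backed parent-of-origin phasing, 20-kb cluster detection,
and the cohort statistics of a paternal-age study design.

## Who this is for

Cohort studies of germline mutation sequence father–mother–child trios,
call variants present in the child but absent from both parents, and ask
how the per-child DNM count depends on covariates — classically the
father's age at conception (≈1.1–1.5 extra DNMs per paternal year), and
in reproductive medicine the method of conception (spontaneous vs IVF vs
ICSI-TESE). Real trio genomes are controlled-access; `dnmsuite` provides
the entire downstream analysis plus a calibrated synthetic-cohort
generator, so every stage — calling rules, phasing logic, cluster
detection, statistics — is testable against known truth on a desk.

## The model

Per-child DNM counts are Poisson with mean

```
E[N] = β₀ + β_p · age_father + β_m · age_mother
```

(defaults β₀ = 29.3, β_p = 1.09, β_m = 0.30, giving 71 DNMs at parental
ages 30/30). A fraction of DNMs (default 75%) arises on the paternal
haplotype; ~3% fall in clusters of ≥2 mutations within 20 kb on a single
parental haplotype, with a maternal bias.

The analysis stages mirror a WGS study at 38× with 150-bp paired reads:

* **calling** — Mendelian-violation candidates must pass a binomial
  genotype-likelihood posterior test *and* a heuristic
  depth/allele-balance filter, with ≥10 reads carrying the mutation;
  optionally intersected across two sequencing runs of the same trio;
* **phasing** — a DNM is assigned to a parent when a read fragment (or a
  chain of fragments sharing heterozygous sites) jointly covers the DNM
  and a parentally informative SNP (iSNP) within ±5 kb; majority vote,
  ties unphased;
* **clustering** — single-linkage chaining of a child's DNMs with
  consecutive gaps ≤20 kb;
* **statistics** — group means, OLS of count on conception method +
  parental ages, pooled two-sample *t*, multi-factorial ANOVA with Tukey
  post hocs, negative-binomial regression, and two-sample power
  calculations. A 53-child cohort table (per-child DNM count, parental
  ages, conception method) ships with the package.

## Worked example

```python
from dnmsuite import cohort_stats

df = cohort_stats.load_cohort()          # packaged 53-child table
fit = cohort_stats.ols_regression(df)
print(f"paternal age: +{fit.params['paternal_age']:.2f} DNMs/year "
      f"(t = {fit.tvalues['paternal_age']:.3f}), R^2 = {fit.r_squared:.4f}")
t = cohort_stats.two_sample_t(df)
print(f"young vs old fathers: t = {t.statistic:.1f}")
```

prints

```
paternal age: +1.09 DNMs/year (t = 5.636), R^2 = 0.6113
young vs old fathers: t = -7.9
```

— each additional paternal year adds about one DNM to the child's
genome; children of fathers >45 carry ~23 more DNMs than children of
fathers <35, while the method of conception shows no detectable effect
(ANOVA F = 0.14, p = 0.87).

The end-to-end synthetic pipeline (`examples/06_full_pipeline.py`):

```python
import dataclasses
from dnmsuite.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=11)
cfg.simulation = dataclasses.replace(cfg.simulation, n_trios=10)
summary = run_pipeline(cfg)
```

```
10 trios, 804 DNMs called (mean 80.4/child)
phased 368 (0.46); paternal fraction 0.79
clusters: 6, clustered fraction 0.016, mean size 2.17
regression on simulated cohort: paternal slope 1.24 +- 0.29 (simulated with 1.09)
```

— the pipeline recovers the generating slope and origin fraction within
sampling error; a 10-trio cohort is deliberately small, the test suite
uses 50.

The `examples/` directory holds one short script per capability
(simulation, calling, phasing, clustering, statistics, full pipeline); a
thin CLI exposes the same stages:

```sh
dnmsuite simulate --n-trios 5 --seed 1 --out sim/
dnmsuite call --vcf sim/T001.vcf --out calls/
dnmsuite stats --analysis ols --out stats/
dnmsuite run --seed 1 --out run/
```

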