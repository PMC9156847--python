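# Methods

## The generative model

A cohort is a set of independent father–mother–child trios. For each
trio, parental ages at conception are drawn (defaults: father ~
U(24, 56) years, mother ~ U(23, 42), spanning the ranges typical of
fertility-clinic cohorts) and the child's DNM count is Poisson with mean

    E[N] = β₀ + β_p·age_f + β_m·age_m,

defaults β₀ = 29.3, β_p = 1.09 DNMs per paternal year, β_m = 0.30 per
maternal year. The intercept is chosen so the model yields 71 DNMs at
parental ages (30, 30), the canonical young-parent average; the maternal
slope is the midpoint of the 0.24–0.42/year range reported across large
trio studies. Ages outside [18, 70] are rejected.

**Origin.** `paternal_origin_prob` (default 0.75) is the *marginal*
fraction of DNMs arising on the paternal haplotype. Clustered DNMs carry
their own origin probability (maternal with probability 0.6, reflecting
the maternal bias of clustered mutation events); non-clustered DNMs use a
compensated probability so the cohort-wide marginal equals the configured
value. At the extremes (0 or 1) every DNM, clustered or not, takes that
side so degenerate configurations behave exactly.

**Clusters.** The expected number of clusters per child is
`cluster_fraction·E[N]/cluster_mean_size` (Poisson-distributed); cluster
sizes are 2 + Poisson(cluster_mean_size − 2), i.e. mean 2.2 with minimum
2. Members share one parental haplotype and lie within
`cluster_max_span` (20 kb) of one another, at uniform offsets.

**Genome representation.** Twenty named windows of 125 Mb (2.5 Gb total,
autosome scale), one per chromosome name; DNM positions uniform across
windows; no recombination within a window (each parent transmits one of
its two haplotypes per window). The analysis is position-agnostic except
for two distance scales — the 5-kb phasing window and the 20-kb cluster
gap — and both sit far below the window size. Genome scale matters for
one reason only: the rate of *chance* 20-kb proximity between independent
DNMs grows as n²·gap/L, so a toy-sized genome would drown the 3% of
genuinely clustered mutations in coincidental pairs. At 2.5 Gb the
spurious contribution is ≈0.2% of DNMs, comfortably below the signal.

**Inherited SNPs.** Each parent carries heterozygous SNPs at density
1/1200 bp (human-like); the child inherits each with probability ½.
These matter to the analysis solely as phasing anchors within ±5 kb of a
DNM, so by default they are generated only within 6 kb of each DNM
(`snp_neighborhood`; set to `None` for genome-wide generation, e.g. when
measuring raw coverage). This is an exact economy, not an approximation:
a SNP 100 kb from every DNM can never appear in a phasing window.

**Sequencing observables.** Per site and individual, total depth is
Poisson(coverage) (default 38×) and alt-read counts are binomial with
allele fraction ½ per carried alt allele, perturbed by the base error
rate (default 0.005; a true ref allele is misread as the specific alt
base with probability e/3). Read fragments are paired 150-bp reads with
insert length ~ N(350, 50) clipped to [300, 550] — a typical short-insert
PE150 library. Fragment starts follow a homogeneous Poisson process at
rate coverage/(2·read length) per bp, so mean per-site fragment depth
equals the configured coverage; only fragments overlapping at least one
variant site are materialised (fragments elsewhere carry no information),
and the pipeline simulates child fragments only within DNM ± (5 kb +
insert) neighbourhoods, where phasing lives. Each fragment records the
allele it observes at every covered variant site, with per-base errors,
plus a truth side-channel naming its source haplotype that no caller or
phaser reads.

Allele depths in the genotype table and read fragments are sampled
independently rather than the depths being tallied from the fragments;
both follow the same per-site law, and no downstream computation compares
a site's AD against its fragment count.

## Calling

Candidates are Mendelian violations: the child carries an allele absent
from both parental genotypes. Two independent rules then apply:

* **Rule A (likelihood):** binomial genotype likelihoods per member over
  {0/0, 0/1, 1/1}, Hardy–Weinberg parental priors at allele frequency
  10⁻³, Mendelian transmission with per-allele de novo probability 10⁻⁷;
  the posterior of (0/0, 0/0, 0/1), marginalised over all 27
  configurations, must exceed 0.5. Zero informative depth in any member
  fails the site (without error).
* **Rule B (heuristic):** all three depths ≥10; each parent ≤1 alt read;
  child allele balance in [0.25, 0.75] for het calls (≥0.75 for hom-alt).

A high-confidence DNM passes A ∧ B with ≥10 child alt reads. The
consensus-of-two-callers architecture with a 10-read support floor is the
reproducible content here; the individual rules are deliberately
transparent stand-ins for production callers, and their thresholds are
conventional trio-calling values, all configurable. For replicated
sequencing runs, calls are intersected on (chrom, pos, ref, alt).
Multi-allelic VCF records are decomposed to biallelic rows before
calling. All simulated windows are treated as autosomal; no hemizygous
logic.

## Phasing

An informative SNP (iSNP) is a child-heterozygous site within ±5 kb of
the DNM whose parental genotypes admit exactly one Mendelian transmission
(e.g. father 0/1 × mother 0/0 → the child's alt came from the father);
sites where both parents are heterozygous are discarded. Evidence
accrues from fragments covering the DNM site:

* fragment with DNM-alt + parent-P-attributed iSNP allele → evidence for
  P;
* fragment with DNM-ref + parent-P allele → evidence for the *other*
  parent (optional, on by default);
* with transitive chaining (default on), fragments observing the same
  child-het site with the same allele are merged into haplotype
  components (union–find, deterministic tie-breaking by fragment id);
  a component's parental identity is the majority over its iSNP alleles,
  and every member fragment covering the DNM then votes. Per-site allele
  conflicts within a component drop that site; identity ties drop the
  component.

The verdict is the majority of evidence fragments; ties, or fewer than
`min_supporting_fragments` (default 1) on the winning side, leave the DNM
unphased. Counting is order-free, so assignments are invariant to
fragment order. Sequencing error is absorbed by the majority vote; base
qualities are not simulated and not weighted.

Under the defaults, ~45–48% of DNMs phase. The binding constraint is
paired-end reach: an iSNP must fall within one insert (≤ ~550 bp) of the
DNM, giving 1 − exp(−2·reach·density) ≈ 0.39–0.60 around the measured
value. Real studies phase less (≈28%) mainly because real iSNP spacing is
non-uniform and callable coverage is imperfect; the simulator's uniform
SNP process is the idealisation. Chaining rarely unlocks additional DNMs
here — any stepping-stone child-het site is itself an iSNP — but
increases the evidence depth per DNM.

## Clustering

Per child and chromosome, DNMs are sorted and consecutive gaps ≤ max_gap
(default 20 kb) are linked; components of ≥2 are clusters, so a chain's
span may exceed the gap (single linkage, the standard reading of
"within 20 kb of each other"). A stricter complete-linkage rule (all
pairs within the gap, i.e. span ≤ max_gap, greedy left-to-right) is
available via `linkage="complete"` for sensitivity analysis. A cluster
is "same-allele" when ≥2 members are phased and all phased members agree;
clusters with <2 phased members are excluded from that denominator.
Children never co-cluster.

## Cohort statistics

Model fitting is delegated to statsmodels (OLS, sequential Type I /
partial Type II ANOVA, Tukey HSD via the studentized range,
negative-binomial GLM); this module owns the cohort schema, reported
quantities and conventions:

* the packaged 53-child table treats siblings as independent rows (as
  the study design's residual df implies);
* the paternal-age group (<35 / >45) is derived from paternal age; ages
  in between violate the two-group design and are rejected at load;
* the two-sample *t* is pooled-variance by default (Welch by flag), sign
  convention (<35) − (>45), df = n₁ + n₂ − 2 = 51 for the packaged
  table;
* ANOVA defaults to Type I with factor order (method, age group,
  interaction); a constant response reports F = 0, p = 1 for every term
  rather than 0/0 noise;
* Tukey p-values may additionally be Bonferroni-multiplied
  (`bonferroni=True`), a conservative hybrid some studies report;
* the NB regression estimates dispersion by Cameron–Trivedi moments from
  a Poisson fit, then one NB IRLS fit; non-convergence raises with the
  deviance trace;
* power: n = ⌈2(z₁₋α/₂ + z_power)²/(Δ/σ)²⌉ per group, floored at 2; the
  inverse (minimum detectable effect at given n) is also exposed.

## Numerical and plumbing choices

Coordinates are 1-based closed (VCF convention) everywhere except BED
output (0-based half-open). VCFs are VCF 4.2 with FORMAT GT:AD:DP and
samples `<trio>_father/_mother/_child`, roles resolved by name suffix,
not column order. One root seed drives everything; per-trio streams are
spawned from a `SeedSequence`, and read/replicate streams use derived
keys, so any cohort size is reproducible and outputs are byte-identical
across runs (no timestamps in any file). Configuration is a single YAML
file mirroring the dataclasses; unknown keys are rejected and the
resolved configuration is written next to the outputs.

Default problem sizes (50-trio cohorts for recovery checks, 20 trios for
exact-oracle checks, 10,000 replicates for calibration checks) keep any
single analysis under about a minute on one CPU while leaving Monte
Carlo error well inside the asserted tolerances.

## What passing tests do and do not show

The simulator realises the statistical structure a trio-WGS study
assumes — Poisson counts linear in parental ages, a paternal-origin
majority, maternally biased 20-kb clusters, locally phaseable DNMs — but
idealises everything else: uniform SNP spacing, no recombination within
windows, no mapping artefacts, no indels or CNVs, no base-quality
structure, error-independent sites. Recovery of the generating
parameters therefore validates the *analysis logic* (filters, votes,
linkage, estimators), not performance on real genomes; the calling rules
are transparent stand-ins, and conclusions about production callers or
real phasing rates do not follow. The packaged cohort statistics, by
contrast, are exact reproductions of computations on real published
per-child counts.
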