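# diffgwas

Differential genome-wide association analysis between two traits from
summary statistics, with correction for sample overlap.

Two GWAS of related disorders (the motivating case: schizophrenia and
post-traumatic stress disorder, both from large consortium case-control
studies) often share many loci, but genetic-correlation analyses cannot say
*where* the two architectures diverge. `diffgwas` tests each SNP directly
for a difference in effect size between the traits, working only from the
released per-SNP summaries (effect allele, β, SE, p) — no individual-level
genotypes needed.

## The statistic

For a SNP with harmonized effect estimates β₁ ± se₁ and β₂ ± se₂,

> Z = (β₁ − β₂) / √(se₁² + se₂² − 2·ρ·se₁·se₂)

The −2ρ·se₁·se₂ term corrects for sample overlap: individuals contributing
to both GWAS make the two estimation errors correlated, and for shared
samples under a shared phenotype model ρ = n_overlap/√(n₁·n₂). Since the
contributing cohorts are rarely published in enough detail to compute that
directly, ρ is estimated empirically as the Pearson correlation of the two
studies' z-scores over a quasi-independent SNP subset (pairwise LD R² < 0.1,
or one SNP per 250 kb window when no LD table is available). Raw Z values
are then affinely standardized to genome-wide mean 0 / variance 1 — a
genomic-control-style safeguard against residual bias — and converted to
two-sided normal p-values with full accuracy in the extreme tail.

Candidate SNPs must jointly satisfy: differential p < 5×10⁻⁸, nominal
significance (p < 0.05) in **both** input GWAS, and opposite effect
directions — the signature of antagonistic pleiotropy. Passing SNPs are
clumped into loci (greedy, best differential p first, 1 Mb window) and
optionally triaged against a replication GWAS (replicated: p < 5×10⁻⁸;
attenuated: p ≥ 10⁻³).

The package also ships a synthetic-data generator (`diffgwas.simulate`)
that draws paired summary statistics with known overlap correlation and
known shared-/opposite-direction causal SNPs, so every pipeline stage can be
validated against ground truth.

## Worked example

`examples/02_overlap_correction.py` simulates two 100k-sample GWAS sharing
50k individuals (ρ* = 0.5) with 100,000 null SNPs and compares the
calibration of the corrected and uncorrected tests:

```
estimated rho = 0.498 (generating rho* = 0.5)
type-I error at alpha=0.05, overlap-corrected: 0.0495
type-I error at alpha=0.05, overlap ignored:   0.0055
```

The pruned-SNP estimator recovers the generating overlap correlation, the
corrected test holds its nominal 5% level, and ignoring overlap deflates the
test by an order of magnitude (the same factor is lost as power on real
signal). `examples/03_replication_triage.py` runs the four-locus
schizophrenia-vs-PTSD worked example:

```
replication triage:
  rs62062288: z_rep = +5.631, p_rep = 1.79e-08 -> replicated (direction consistent)
  rs11057189: z_rep = -1.675, p_rep = 0.094 -> attenuated (direction consistent)
  rs58120505: z_rep = -3.224, p_rep = 0.00126 -> attenuated (direction consistent)
  rs12536395: z_rep = +1.557, p_rep = 0.119 -> attenuated (direction consistent)
```

Only the 17q21.31 *MAPT*/*CRHR1* lead rs62062288 stays genome-wide
significant in the trans-ancestry replication study.
`examples/01_simulate_and_run.py` exercises the whole pipeline end to end
on synthetic data with injected antagonistic loci.

## Command line

```bash
diffgwas simulate --n-snps 30000 --n-overlap 60000 --n1 100000 --n2 150000 \
    --n-opposite 6 --n-rep 1000000 --seed 1 --out-dir sim/
diffgwas run --config run.yaml --out-dir out/
```

`run` writes per-SNP differential results, the candidate-locus table, the
replication triage, Manhattan-plot coordinates (−log₁₀ p truncated at 30),
and a YAML run report with ρ, its confidence interval, stage-by-stage SNP
counts and every threshold. Exit codes: 0 success, 2 configuration error,
3 data error.

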