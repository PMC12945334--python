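# Methods

## Model

Each GWAS reports, per SNP, an effect estimate β̂ with standard error se on
a shared additive coding. Under standard large-sample theory β̂ ~
Normal(β, se²), and for two studies

    Var(β̂₁ − β̂₂) = se₁² + se₂² − 2·Cov(β̂₁, β̂₂).

With disjoint samples the covariance is zero and the classical two-sample
z-test applies. When the studies share individuals the errors are
correlated; writing the covariance as ρ·se₁·se₂ gives the adjusted
statistic

    Z = (β̂₁ − β̂₂) / sqrt(se₁² + se₂² − 2·ρ·se₁·se₂).

For n_overlap shared individuals with shared phenotype noise,
ρ = n_overlap/√(n₁·n₂); in general ρ also absorbs phenotype correlation
between the traits in the overlapping subset, which is why it is estimated
empirically rather than computed from cohort bookkeeping.

Assumptions: both tables are on the same genome build, effects are additive
per effect-allele dose, SEs honestly reflect sampling variability
(imputation-quality and structure artifacts are upstream concerns), and ρ
is a single genome-wide scalar — overlap is a property of cohorts, not of
loci.

## Estimating ρ

ρ is the Pearson correlation of z₁ = β̂₁/se₁ and z₂ = β̂₂/se₂ over a
quasi-independent SNP subset; the 95% CI uses the Fisher transform.
Pruning options:

- `distance_thin` (default): keep the lowest-position SNP in each
  non-overlapping 250 kb window per chromosome. Deterministic and
  data-independent, so the retained set is not enriched for significant
  SNPs; a pragmatic LD proxy when no reference panel is at hand.
- `ld_file`: greedy removal, scanning by position, of SNPs with R² ≥ 0.1
  (configurable) against any retained SNP, from a precomputed pairwise-LD
  table (`SNP_A SNP_B R2` columns, the conventional report layout).

An optional `null_zmax` cutoff restricts the estimate to SNPs with
max(|z₁|, |z₂|) below a ceiling, so true shared polygenic signal does not
inflate ρ. It is **off by default**: truncating a bivariate normal at
|z| < 2 attenuates a true correlation of 0.5 to about 0.42 (the restriction
trades signal-contamination bias for truncation bias), and on data where
most SNPs are effectively null the unrestricted estimate is the less biased
one. On heavily polygenic real data a user may prefer the restriction, or a
higher ceiling, accepting the attenuation; both knobs are exposed.

## Standardization and p-values

Raw Z values are affinely mapped to genome-wide mean 0 and sample variance
1 (ddof = 1) before p-value assignment. This is a genomic-control-style
backstop: if the empirical ρ fails to normalize residual between-study
biases — e.g. when either GWAS carries many genome-wide significant SNPs —
the rescaling restores first- and second-moment calibration. A robust
variant (median / normal-consistent MAD) is available for heavy polygenic
tails; the plain mean/SD is the default. Standardization is computed once
over all retained SNPs, never per chromosome or leave-one-out. Because the
location shift could in principle flip a near-zero score's sign, the
pipeline checks sign(z_std) = sign(z_raw) row-wise and flags violations
(`sign_ok=False`) instead of silently passing them.

Note an interaction worth understanding: when the se₁/se₂ ratio is constant
across SNPs, omitting the overlap term scales all Z values uniformly and
standardization undoes the omission entirely. The variance correction is
therefore demonstrated (tests, acceptance script) on the *unstandardized*
test (`standardization="none"`), where ignoring ρ* = 0.5 deflates type-I
error at α = 0.05 from ~0.05 to ~0.006. On real data the se ratio varies
SNP-to-SNP and both mechanisms matter.

Two-sided p-values are 2·Φ(−|z|) via the normal survival function, accurate
to the smallest normal doubles (~1e-308); beyond |z| ≈ 38 they underflow to
exact zero, far below any threshold in use.

## Harmonization rules

Join on (chrom, pos) — not rsid, whose vintages differ across releases —
with an allele-compatibility check; the trait-1 rsid is carried for
display. Same-orientation pairs merge as-is; swapped-allele pairs negate
the trait-1 β and record `flipped=True`; irreconcilable allele pairs are
excluded and counted. Strand-ambiguous (A/T, C/G) SNPs are excluded by
default, since a strand flip is indistinguishable from an allele swap; an
optional frequency mode resolves them by effect-allele-frequency agreement
when both studies report frequencies and the SNP is not near 0.5. Indels
and multi-allelic records are rejected; positions are 1-based; `chr`
prefixes are stripped. The MAF ≥ 0.05 filter applies to the trait-2 table
by default (mirroring procedures where only the second study is
frequency-filtered), extendable to both.

## Selection, clumping, replication triage

Candidates must satisfy p_diff < 5×10⁻⁸, p₁ < 0.05, p₂ < 0.05, and
β₁·β₂ < 0 (the opposite-direction requirement is a flag). Clumping is
greedy: the remaining SNP with smallest p_diff leads a locus and absorbs
all passing SNPs within 1 Mb on its chromosome; ties break by (chrom, pos).
Distance clumping is a deliberate simplification — no LD input is required
at this stage, and at genome-wide significance the 1 Mb window is a
conservative independence proxy.

Replication lookup matches by rsid with a (chrom, pos) fallback, negates z
when the replication alleles are swapped, and treats allele-incompatible or
missing matches as `absent`. Triage uses two explicit cutoffs: replicated
if p < 5×10⁻⁸, attenuated if p ≥ 10⁻³, intermediate between them —
borderline loci are retained and flagged rather than forced into a bin.

## Synthetic data

The generator draws, per SNP, a frequency f ~ U(0.05, 0.5), study SEs
1/√(2·N·f(1−f)) (optionally scaled by 1/√(φ(1−φ)) for case-control studies
with case fraction φ — SE magnitudes at consortium scale come out at the
realistic few-thousandths), and effect estimates from a bivariate normal
with correlation ρ* = n_overlap/√(n₁n₂). Causal SNPs set |β| =
snr·max(se₁, se₂) with snr ~ U(4, 8) by default (degenerate ranges give
fixed signal strength); `shared` SNPs get identical βs in both studies,
`opposite` SNPs equal magnitude with opposite signs. SNPs are laid
round-robin over the 22 autosomes at 300 kb spacing — beyond the default
pruning window, so the (genuinely independent) simulated SNPs survive
thinning. All SNPs are biallelic A/G for transparency; flags inject allele
swaps and strand-ambiguous records to exercise harmonization. Output is
byte-identical under a fixed seed.

What the generator does *not* emulate: LD structure (simulated SNPs are
independent, so pruning is exercised mechanically, not statistically),
ancestry structure or admixture, frequency-dependent architecture, winner's
curse in the input studies, and cross-trait phenotype correlation beyond
what ρ* encodes. Passing tests therefore validate the estimator and the
pipeline's bookkeeping under the stated noise model, not robustness to
those real-data complications. In the full-overlap limit ρ* = 1 assumes the
shared individuals contribute identical phenotype noise to both studies
(same trait measured once).

## Numerical and design choices

- ρ is clipped to [−1, 1] after the correlation call; a Fisher CI is only
  computed for n > 3 and |r| < 1, else the CI is the full interval.
- Adjusted variance ≤ 0 (only possible at |ρ| = 1 with se₁ = se₂) raises a
  degenerate-variance error scalar-wise and drops the rows, with a count,
  table-wise.
- Standardizing a constant vector (e.g. a table harmonized against itself)
  raises rather than returning NaNs.
- Window thinning bins positions by `pos // window` and keeps the earliest
  SNP per bin — idempotent and independent of row order.
- Default problem sizes in the test suite and acceptance script (20k–100k
  SNPs, 10-seed averages) were chosen so every statistical check has
  comfortable Monte-Carlo margins while the whole suite stays in the tens
  of seconds on a single CPU.

## Known limitations

Genome-wide ρ cannot capture locus-specific overlap effects; the test
assumes both βs on comparable scales (two log-odds case-control studies
compare cleanly, a log-odds vs linear-scale pair does not); X-chromosome
records, build liftover and imputation-quality filtering are out of scope;
and the distance-based pruning/clumping proxies should be replaced by
reference-panel LD input (`ld_file`) when fidelity to LD structure matters.
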