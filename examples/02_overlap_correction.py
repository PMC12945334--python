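"""Why the sample-overlap term in the variance matters.

Two studies sharing half their samples have correlated effect-estimate
errors (rho* = 0.5 here).  On pure-null data the differential test using
Var(b1 - b2) = se1^2 + se2^2 - 2*rho*se1*se2 holds its 5% level, while the
classical two-sample test (rho = 0, no standardization) is badly deflated —
it would also lose the same fraction of power on real signal.
"""

from diffgwas import (SyntheticCohortSpec, estimate_rho, harmonize, prune,
                      run_diff_gwas, simulate_pair)

spec = SyntheticCohortSpec(n1=100_000, n2=100_000, n_overlap=50_000,
                           n_snps=100_000, seed=5)
s1, s2, _ = simulate_pair(spec)
h = harmonize(s1, s2)
rho = estimate_rho(prune(h)).rho
print(f"estimated rho = {rho:.3f} (generating rho* = {spec.rho_star})")

corrected = run_diff_gwas(h, rho=rho)
naive = run_diff_gwas(h, rho=0.0, standardization="none")
print(f"type-I error at alpha=0.05, overlap-corrected: "
      f"{(corrected['p_diff'] < 0.05).mean():.4f}")
print(f"type-I error at alpha=0.05, overlap ignored:   "
      f"{(naive['p_diff'] < 0.05).mean():.4f}")
# ~0.05 vs ~0.006: ignoring overlap overstates the variance of the
# difference by a factor 1/(1-rho*) and hides genuinely differential SNPs.
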