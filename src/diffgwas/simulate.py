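"""Synthetic paired GWAS summary statistics with known ground truth.

Sample overlap is induced analytically: for n_overlap individuals shared
between studies of sizes n1 and n2 (same trait, shared phenotype noise), the
per-SNP estimation errors are bivariate normal with correlation

    rho* = n_overlap / sqrt(n1 * n2)

which is exactly the quantity the overlap estimator targets, with no need to
simulate individual-level genotypes.  Standard errors follow the large-sample
formula for an additively coded variant with allele frequency f:
se = 1/sqrt(2*N*f*(1-f)) for a unit-variance quantitative trait, scaled by
1/sqrt(phi*(1-phi)) for a case-control study with case fraction phi
(log-odds effects).

Causal SNPs come in two classes: ``shared`` (identical true effect in both
studies) and ``opposite`` (equal magnitude, opposite sign — the antagonistic
signal the differential test is built to find).  Effect magnitudes are set
on the signal-to-noise scale, |beta| = snr * max(se1, se2), so power is
controlled directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError


@dataclass
class SyntheticCohortSpec:
    """Generating conditions for one pair of GWAS.

    n1, n2, n_overlap
        Study sample sizes and the number of shared individuals
        (0 <= n_overlap <= min(n1, n2)); the implied noise correlation is
        rho* = n_overlap/sqrt(n1*n2).
    n_snps, n_shared, n_opposite
        Total SNP count and the number of causal SNPs of each class; the
        remainder are null.
    maf_range
        Effect-allele frequencies are drawn uniformly on this interval.
    snr_range
        Causal |beta|/max(se1, se2) drawn uniformly on this interval; pass a
        degenerate interval (x, x) for fixed signal strength.
    spacing_bp
        Distance between consecutive simulated SNPs on a chromosome.  The
        default exceeds the default 250 kb pruning window, so the generator's
        (LD-free) SNPs all survive distance thinning — matching their actual
        independence.
    case_fraction1, case_fraction2
        If set, the study is case-control with this case proportion and
        betas are on the log-odds scale; None means quantitative trait.
    swap_fraction, ambiguous_fraction
        Fractions of SNPs emitted with study-1 alleles swapped (beta and eaf
        re-oriented accordingly — harmonization must undo this) and with
        strand-ambiguous A/T alleles, to exercise harmonization edge cases.
    """

    n1: int = 100_000
    n2: int = 100_000
    n_overlap: int = 0
    n_snps: int = 50_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_shared: int = 0
    n_opposite: int = 0
    snr_range: tuple[float, float] = (4.0, 8.0)
    spacing_bp: int = 300_000
    case_fraction1: float | None = None
    case_fraction2: float | None = None
    swap_fraction: float = 0.0
    ambiguous_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n1, self.n2) <= 0 or self.n_snps <= 0:
            raise ConfigError("sample sizes and SNP count must be positive")
        if not 0 <= self.n_overlap <= min(self.n1, self.n2):
            raise ConfigError("need 0 <= n_overlap <= min(n1, n2)")
        if self.n_shared + self.n_opposite > self.n_snps:
            raise ConfigError("more causal SNPs than SNPs")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ConfigError("maf_range must lie in (0, 0.5]")
        if not 0 < self.snr_range[0] <= self.snr_range[1]:
            raise ConfigError("snr_range must be positive and ordered")
        for phi in (self.case_fraction1, self.case_fraction2):
            if phi is not None and not 0 < phi < 1:
                raise ConfigError("case fractions must be in (0, 1)")

    @property
    def rho_star(self) -> float:
        """Overlap correlation implied by the shared samples."""
        return self.n_overlap / np.sqrt(self.n1 * self.n2)


def _se(n: int, f: np.ndarray, case_fraction: float | None) -> np.ndarray:
    se = 1.0 / np.sqrt(2.0 * n * f * (1.0 - f))
    if case_fraction is not None:
        se /= np.sqrt(case_fraction * (1.0 - case_fraction))
    return se


def _positions(n_snps: int, spacing_bp: int) -> tuple[np.ndarray, np.ndarray]:
    """Round-robin layout over autosomes 1..22 with fixed spacing."""
    chrom_idx = np.arange(n_snps) % 22 + 1
    pos = (np.arange(n_snps) // 22 + 1) * spacing_bp
    return chrom_idx.astype(str), pos


def simulate_pair(spec: SyntheticCohortSpec
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw one pair of GWAS summary-statistics tables plus the truth table.

    Returns ``(study1, study2, truth)``.  The study tables use the package's
    summary-statistics schema; ``truth`` records each SNP's class
    (null/shared/opposite), true effects, frequency and the generating
    rho*.  Deterministic under a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_snps
    chrom, pos = _positions(n, spec.spacing_bp)
    rsid = np.array([f"rs{i + 1:07d}" for i in range(n)])
    f = rng.uniform(*spec.maf_range, size=n)
    se1 = _se(spec.n1, f, spec.case_fraction1)
    se2 = _se(spec.n2, f, spec.case_fraction2)

    klass = np.full(n, "null", dtype=object)
    causal = rng.choice(n, size=spec.n_shared + spec.n_opposite, replace=False)
    klass[causal[:spec.n_shared]] = "shared"
    klass[causal[spec.n_shared:]] = "opposite"

    snr = rng.uniform(*spec.snr_range, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    mag = snr * np.maximum(se1, se2)
    beta1_true = np.where(klass != "null", sign * mag, 0.0)
    beta2_true = np.where(klass == "shared", beta1_true,
                          np.where(klass == "opposite", -beta1_true, 0.0))

    rho = spec.rho_star
    e1 = rng.standard_normal(n)
    e2 = rho * e1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    beta1_hat = beta1_true + se1 * e1
    beta2_hat = beta2_true + se2 * e2
    p1 = 2.0 * stats.norm.sf(np.abs(beta1_hat / se1))
    p2 = 2.0 * stats.norm.sf(np.abs(beta2_hat / se2))

    def study(beta, se, p, nsamp):
        return pd.DataFrame({
            "chrom": chrom, "rsid": rsid, "pos": pos,
            "a1": "A", "a2": "G", "eaf": f,
            "beta": beta, "se": se, "p": np.clip(p, 1e-320, 1.0),
            "n": nsamp,
        })

    s1 = study(beta1_hat, se1, p1, spec.n1)
    s2 = study(beta2_hat, se2, p2, spec.n2)

    if spec.ambiguous_fraction > 0:
        amb = rng.random(n) < spec.ambiguous_fraction
        for s in (s1, s2):
            s.loc[amb, ["a1", "a2"]] = ["A", "T"]
    if spec.swap_fraction > 0:
        # emit some study-1 records on the opposite allele: swap alleles,
        # negate beta, complement eaf; harmonization must restore them
        swap = rng.random(n) < spec.swap_fraction
        a1_old = s1.loc[swap, "a1"].to_numpy()
        s1.loc[swap, "a1"] = s1.loc[swap, "a2"].to_numpy()
        s1.loc[swap, "a2"] = a1_old
        s1.loc[swap, "beta"] = -s1.loc[swap, "beta"]
        s1.loc[swap, "eaf"] = 1.0 - s1.loc[swap, "eaf"]

    truth = pd.DataFrame({
        "chrom": chrom, "rsid": rsid, "pos": pos, "eaf": f,
        "class": klass, "beta1_true": beta1_true, "beta2_true": beta2_true,
        "rho_star": rho,
    })
    return s1, s2, truth


def simulate_replication(truth: pd.DataFrame, n_rep: int,
                         seed: int | None = None) -> pd.DataFrame:
    """Replication GWAS (z and p only) drawn from the trait-2 true effects at
    sample size ``n_rep`` — a stand-in for an independent, larger study.

    Null SNPs yield uniform p-values; causal SNPs replicate in direction
    with probability approaching 1 as ``n_rep`` grows.
    """
    if n_rep <= 0:
        raise ConfigError("n_rep must be positive")
    rng = np.random.default_rng(seed)
    f = truth["eaf"].to_numpy(float)
    se = 1.0 / np.sqrt(2.0 * n_rep * f * (1.0 - f))
    z = truth["beta2_true"].to_numpy(float) / se + rng.standard_normal(len(truth))
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-320, 1.0)
    return pd.DataFrame({
        "chrom": truth["chrom"], "rsid": truth["rsid"], "pos": truth["pos"],
        "a1": "A", "a2": "G", "z": z, "p": p,
    })
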