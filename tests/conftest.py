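"""Shared fixtures: tiny hand-built summary-statistics tables and the
four-locus SCZ-vs-PTSD worked example (discovery statistics plus
trans-ancestry PTSD replication z/p) used across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

# Worked example: four lead SNPs with genome-wide significant differential
# effects between schizophrenia (trait 1) and PTSD (trait 2), opposite
# effect directions, and their printed differential z-scores/p-values.
LEAD_SNPS = pd.DataFrame(
    [
        ("17", "rs62062288", "A", "G", -0.068, 0.011, 1.65e-09, 0.023, 0.006, 7.14e-05, -5.46, 4.87e-08),
        ("12", "rs11057189", "T", "G", 0.073, 0.010, 5.67e-14, -0.019, 0.005, 4.30e-04, 6.33, 2.42e-10),
        ("7", "rs58120505", "T", "C", 0.090, 0.009, 2.24e-24, -0.013, 0.004, 1.70e-03, 7.99, 1.30e-15),
        ("7", "rs12536395", "A", "G", -0.063, 0.009, 1.13e-11, 0.013, 0.005, 3.49e-03, -5.58, 2.40e-08),
    ],
    columns=["chrom", "rsid", "a1", "a2", "beta1", "se1", "p1",
             "beta2", "se2", "p2", "z_diff", "p_diff"],
)

# The same four SNPs in a trans-ancestry quantitative-PTSD GWAS (z, p only).
TRANS_ANCESTRY = pd.DataFrame(
    [
        ("17", "rs62062288", "A", "G", 5.631, 1.79e-08),
        ("12", "rs11057189", "T", "G", -1.675, 0.09403),
        ("7", "rs58120505", "T", "C", -3.224, 0.001264),
        ("7", "rs12536395", "A", "G", 1.557, 0.1195),
    ],
    columns=["chrom", "rsid", "a1", "a2", "z", "p"],
)


def make_sumstats(rows) -> pd.DataFrame:
    """Build a summary-statistics table from (chrom, rsid, pos, a1, a2, eaf,
    beta, se, p) tuples in the package's schema."""
    df = pd.DataFrame(
        rows, columns=["chrom", "rsid", "pos", "a1", "a2", "eaf", "beta", "se", "p"]
    )
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = np.nan
    return df


@pytest.fixture
def toy_pair():
    """Five-SNP pair covering same-orientation, swapped-allele,
    allele-incompatible, palindromic and position-unmatched cases."""
    t1 = make_sumstats([
        ("1", "rs1", 1000, "A", "G", 0.30, 0.10, 0.02, 1e-4),   # same orientation
        ("1", "rs2", 2000, "G", "A", 0.70, 0.10, 0.02, 1e-4),   # swapped vs t2
        ("2", "rs3", 3000, "A", "C", 0.20, 0.05, 0.02, 1e-3),   # incompatible in t2
        ("2", "rs4", 4000, "A", "T", 0.10, 0.04, 0.02, 1e-2),   # palindromic
        ("3", "rs5", 5000, "A", "G", 0.40, 0.02, 0.02, 0.3),    # absent from t2
    ])
    t2 = make_sumstats([
        ("1", "rs1", 1000, "A", "G", 0.31, 0.20, 0.02, 1e-6),
        ("1", "rs2", 2000, "A", "G", 0.29, -0.05, 0.02, 1e-2),
        ("2", "rs3", 3000, "A", "G", 0.20, 0.01, 0.02, 0.5),
        ("2", "rs4", 4000, "A", "T", 0.11, 0.03, 0.02, 0.1),
        ("3", "rs6", 9000, "A", "G", 0.40, 0.00, 0.02, 1.0),
    ])
    return t1, t2


@pytest.fixture
def harmonized_null():
    """A 2,000-SNP harmonized null table with known overlap correlation 0.3,
    built directly (no file round trip) for differential-test unit tests."""
    rng = np.random.default_rng(7)
    n = 2000
    rho = 0.3
    se1 = rng.uniform(0.004, 0.012, n)
    se2 = rng.uniform(0.004, 0.012, n)
    e1 = rng.standard_normal(n)
    e2 = rho * e1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    from scipy import stats as st
    b1, b2 = se1 * e1, se2 * e2
    return pd.DataFrame({
        "chrom": np.repeat([str(c) for c in range(1, 21)], n // 20),
        "pos": np.tile(np.arange(1, n // 20 + 1) * 500_000, 20),
        "rsid": [f"rs{i}" for i in range(n)],
        "a1": "A", "a2": "G",
        "beta1": b1, "se1": se1, "p1": 2 * st.norm.sf(np.abs(b1 / se1)),
        "beta2": b2, "se2": se2, "p2": 2 * st.norm.sf(np.abs(b2 / se2)),
        "eaf1": 0.3, "eaf2": 0.3, "maf": 0.3, "flipped": False,
    })


def write_tsv(df: pd.DataFrame, path) -> str:
    df.to_csv(path, sep="\t", index=False)
    return str(path)
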