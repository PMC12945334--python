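"""Estimation of the cross-study overlap correlation from quasi-independent SNPs.

When two GWAS share samples, the sampling errors of their per-SNP effect
estimates are correlated, and the variance of the effect-size difference must
be reduced by 2*rho*se1*se2.  rho is estimated as the Pearson correlation of
the two studies' z-scores over a set of SNPs thinned to approximate linkage
equilibrium (pairwise LD R^2 below a threshold, or one SNP per genomic
window when no LD table is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, EstimationError

logger = logging.getLogger(__name__)


@dataclass
class PruningConfig:
    """How to select a quasi-independent SNP subset.

    method
        ``"distance_thin"`` keeps the lowest-position SNP in each
        non-overlapping ``window_bp`` window per chromosome — a deterministic,
        data-independent LD proxy that needs no genotypes.  ``"ld_file"``
        greedily removes SNPs in LD (R^2 >= ``r2_threshold``) with any
        already-retained SNP, scanning by position, using a precomputed
        pairwise-LD table at ``ld_path`` (whitespace-separated columns
        SNP_A, SNP_B, R2; extra columns ignored).
    null_zmax
        Optional |z| ceiling on SNPs entering the rho estimate, to keep
        strongly associated SNPs (true shared polygenic signal) from
        inflating the null sampling correlation.  Off by default: truncating
        the z distribution biases a Pearson correlation toward zero, so the
        restriction trades one bias for another and is left to the caller's
        judgement.
    """

    method: str = "distance_thin"
    r2_threshold: float = 0.1
    window_bp: int = 250_000
    ld_path: str | Path | None = None
    null_zmax: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("distance_thin", "ld_file"):
            raise ConfigError(f"unknown pruning method: {self.method!r}")
        if not 0 < self.r2_threshold < 1:
            raise ConfigError("r2_threshold must be in (0, 1)")
        if self.window_bp <= 0:
            raise ConfigError("window_bp must be positive")
        if self.method == "ld_file" and self.ld_path is None:
            raise ConfigError("ld_file pruning requires ld_path")


@dataclass(frozen=True)
class OverlapEstimate:
    """Empirical cross-study correlation of z-scores and its provenance."""

    rho: float
    n_snps: int
    ci95: tuple[float, float]
    method: str = ""

    def __post_init__(self) -> None:
        assert -1.0 <= self.rho <= 1.0
        assert self.ci95[0] <= self.rho <= self.ci95[1]


def prune(table: pd.DataFrame, cfg: PruningConfig | None = None) -> pd.DataFrame:
    """Reduce a harmonized table to a quasi-independent SNP subset."""
    cfg = cfg or PruningConfig()
    if table.empty:
        raise EstimationError("cannot prune an empty table")
    if cfg.method == "distance_thin":
        window = table["pos"] // cfg.window_bp
        idx = (
            table.assign(_w=window)
            .groupby(["chrom", "_w"], sort=False)["pos"]
            .idxmin()
        )
        out = table.loc[np.sort(idx.to_numpy())].reset_index(drop=True)
    else:
        out = _prune_ld(table, cfg)
    logger.info("pruning (%s): %d -> %d SNPs", cfg.method, len(table), len(out))
    return out


def _prune_ld(table: pd.DataFrame, cfg: PruningConfig) -> pd.DataFrame:
    ld = pd.read_csv(cfg.ld_path, sep=r"\s+")
    for col in ("SNP_A", "SNP_B", "R2"):
        if col not in ld.columns:
            raise ConfigError(f"LD table {cfg.ld_path} lacks column {col!r}")
    known = set(table["rsid"])
    unknown = (~ld["SNP_A"].isin(known)) | (~ld["SNP_B"].isin(known))
    if unknown.any():
        logger.warning("%d LD pairs reference SNPs absent from the table",
                       int(unknown.sum()))
    ld = ld[ld["R2"] >= cfg.r2_threshold]
    partners: dict[str, set[str]] = {}
    for a, b in zip(ld["SNP_A"], ld["SNP_B"]):
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)

    ordered = table.sort_values(["chrom", "pos"],
                                key=lambda c: pd.to_numeric(c, errors="coerce")
                                if c.name == "chrom" else c)
    retained: set[str] = set()
    keep_rows = []
    for i, rsid in zip(ordered.index, ordered["rsid"]):
        if partners.get(rsid, frozenset()) & retained:
            continue
        retained.add(rsid)
        keep_rows.append(i)
    return table.loc[keep_rows].reset_index(drop=True)


def estimate_rho(table: pd.DataFrame, null_zmax: float | None = None,
                 method: str = "") -> OverlapEstimate:
    """Pearson correlation of per-SNP z-scores between the two studies.

    Under no true effect-size difference the z-scores of a SNP in the two
    studies are bivariate normal with correlation n_overlap/sqrt(n1*n2); their
    empirical correlation over quasi-independent SNPs estimates that overlap
    correlation.  The 95% confidence interval uses the Fisher z-transform.

    Parameters
    ----------
    null_zmax
        If given, restrict to SNPs with max(|z1|, |z2|) < null_zmax.
    """
    z1 = (table["beta1"] / table["se1"]).to_numpy(float)
    z2 = (table["beta2"] / table["se2"]).to_numpy(float)
    if null_zmax is not None:
        mask = np.maximum(np.abs(z1), np.abs(z2)) < null_zmax
        z1, z2 = z1[mask], z2[mask]
    n = len(z1)
    if n < 2:
        raise EstimationError(f"need >= 2 SNPs to estimate rho, have {n}")
    if np.ptp(z1) == 0 or np.ptp(z2) == 0:
        raise EstimationError("zero variance in a z-score vector")
    r = float(np.corrcoef(z1, z2)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if n > 3 and abs(r) < 1:
        zf = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(np.tanh(zf - half)), float(np.tanh(zf + half)))
    else:
        ci = (-1.0, 1.0)
    est = OverlapEstimate(rho=r, n_snps=n, ci95=ci,
                          method=method or f"pearson, null_zmax={null_zmax}")
    logger.info("rho = %.4f (95%% CI %.4f..%.4f, %d SNPs)", r, *ci, n)
    return est
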