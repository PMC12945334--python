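"""The overlap-adjusted differential effect-size test.

For each SNP shared by two GWAS the statistic is

    z = (beta1 - beta2) / sqrt(se1^2 + se2^2 - 2*rho*se1*se2)

where rho is the empirical cross-study correlation of z-scores induced by
sample overlap (rho = 0 recovers the classical two-sample z-test).  The raw
z-scores are then affinely standardized to genome-wide mean 0 and variance 1
— a genomic-control-style backstop against residual miscalibration when one
or both GWAS carry heavy polygenic tails — and converted to two-sided normal
p-values with survival-function accuracy in the extreme tail.

Candidate SNPs must pass a composite rule: genome-wide significant
differential p, nominal significance in both input GWAS, and opposite effect
directions.  Passing SNPs are grouped into loci by greedy distance clumping
around the best differential p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateVarianceError, StandardizationError

logger = logging.getLogger(__name__)


def delta_variance(se1, se2, rho: float):
    """Variance of beta1 - beta2 under sample overlap:
    ``se1**2 + se2**2 - 2*rho*se1*se2``.

    Accepts scalars or arrays.  Raises :class:`DegenerateVarianceError` if any
    value is non-positive (possible only at |rho| = 1 with se1 = se2).
    """
    se1 = np.asarray(se1, dtype=float)
    se2 = np.asarray(se2, dtype=float)
    if np.any(se1 <= 0) or np.any(se2 <= 0):
        raise ConfigError("standard errors must be positive")
    if not -1.0 <= rho <= 1.0:
        raise ConfigError(f"rho must be in [-1, 1], got {rho}")
    var = se1**2 + se2**2 - 2.0 * rho * se1 * se2
    if np.any(var <= 0):
        raise DegenerateVarianceError(
            "non-positive adjusted variance (|rho| = 1 with equal standard errors)"
        )
    return var if var.ndim else float(var)


def delta_z_raw(beta1, beta2, se1, se2, rho: float):
    """Raw overlap-adjusted differential z-score
    ``(beta1 - beta2) / sqrt(delta_variance(se1, se2, rho))``."""
    var = delta_variance(se1, se2, rho)
    z = (np.asarray(beta1, float) - np.asarray(beta2, float)) / np.sqrt(var)
    return z if np.ndim(z) else float(z)


def standardize(z, robust: bool = False) -> np.ndarray:
    """Affine map of a z-score vector to mean 0, variance 1.

    Uses the sample standard deviation (``ddof=1``), so the output's sample
    variance is exactly 1.  With ``robust=True`` the location is the
    median and the scale is the normal-consistent MAD (1.4826 * MAD), which
    resists inflation by heavy polygenic tails.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 2:
        raise StandardizationError("need >= 2 z-scores to standardize")
    if robust:
        loc = np.median(z)
        scale = 1.4826022185056018 * np.median(np.abs(z - loc))
    else:
        loc = z.mean()
        scale = z.std(ddof=1)
    if scale == 0 or not np.isfinite(scale):
        raise StandardizationError("z-score vector has zero dispersion")
    return (z - loc) / scale


def p_two_sided(z):
    """Two-sided standard-normal p-value, 2*Phi(-|z|).

    Computed through the survival function so values far below 1e-300 keep
    full relative accuracy (no 1 - CDF cancellation).
    """
    p = 2.0 * stats.norm.sf(np.abs(z))
    return p if np.ndim(p) else float(p)


def run_diff_gwas(
    table: pd.DataFrame,
    rho: float,
    standardization: str = "mean_sd",
) -> pd.DataFrame:
    """Per-SNP differential statistics over a harmonized table.

    Adds columns ``delta_beta``, ``var_adj``, ``z_raw``, ``z_std``, ``p_diff``
    and ``sign_ok``.  ``standardization`` is ``"mean_sd"`` (default),
    ``"robust"`` (median/MAD), or ``"none"`` (p-values straight from z_raw —
    the classical unstandardized test).

    Rows whose adjusted variance is non-positive are dropped with a logged
    count.  A standardization whose location shift flips the sign of any
    nonzero raw z is not silently accepted: such rows are flagged
    ``sign_ok=False`` and a warning is emitted.
    """
    if standardization not in ("mean_sd", "robust", "none"):
        raise ConfigError(f"unknown standardization: {standardization!r}")
    if table.empty:
        raise ConfigError("harmonized table is empty")
    se1 = table["se1"].to_numpy(float)
    se2 = table["se2"].to_numpy(float)
    var = se1**2 + se2**2 - 2.0 * rho * se1 * se2
    good = var > 0
    n_bad = int((~good).sum())
    if n_bad:
        logger.warning("dropping %d rows with non-positive adjusted variance", n_bad)
    out = table[good].reset_index(drop=True).copy()
    var = var[good]

    out["delta_beta"] = out["beta1"] - out["beta2"]
    out["var_adj"] = var
    out["z_raw"] = out["delta_beta"] / np.sqrt(var)
    if standardization == "none":
        out["z_std"] = out["z_raw"]
    else:
        out["z_std"] = standardize(out["z_raw"].to_numpy(),
                                   robust=(standardization == "robust"))
    out["p_diff"] = p_two_sided(out["z_std"].to_numpy())

    nonzero = out["delta_beta"] != 0
    out["sign_ok"] = ~nonzero | (np.sign(out["z_std"]) == np.sign(out["z_raw"]))
    n_flagged = int((~out["sign_ok"]).sum())
    if n_flagged:
        logger.warning(
            "standardization shifted %d near-zero z-scores across zero; "
            "rows flagged sign_ok=False", n_flagged,
        )
    out.attrs["n_degenerate_dropped"] = n_bad
    out.attrs["rho"] = rho
    return out


@dataclass
class SelectionConfig:
    """Composite candidate-selection rule and clumping window.

    A SNP qualifies when its differential p is genome-wide significant
    (p_diff < ``p_diff_threshold``), both per-trait p-values are nominally
    significant (< ``p_nominal_threshold``), and — when ``require_opposite``
    — the two effect estimates point in opposite directions.
    """

    p_diff_threshold: float = 5e-8
    p_nominal_threshold: float = 0.05
    require_opposite: bool = True
    clump_window_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if not 0 < self.p_diff_threshold < self.p_nominal_threshold < 1:
            raise ConfigError(
                "need 0 < p_diff_threshold < p_nominal_threshold < 1, got "
                f"{self.p_diff_threshold} and {self.p_nominal_threshold}"
            )
        if self.clump_window_bp <= 0:
            raise ConfigError("clump_window_bp must be positive")


def select_candidates(diff: pd.DataFrame,
                      cfg: SelectionConfig | None = None) -> pd.DataFrame:
    """Apply the composite differential-significance / nominal / opposite-sign
    filter to a differential-results table (which carries p1, p2, beta1, beta2)."""
    cfg = cfg or SelectionConfig()
    keep = (
        (diff["p_diff"] < cfg.p_diff_threshold)
        & (diff["p1"] < cfg.p_nominal_threshold)
        & (diff["p2"] < cfg.p_nominal_threshold)
    )
    if cfg.require_opposite:
        keep &= diff["beta1"] * diff["beta2"] < 0
    out = diff[keep].reset_index(drop=True)
    logger.info("candidate selection: %d of %d SNPs pass", len(out), len(diff))
    return out


@dataclass
class CandidateLocus:
    """A clumped locus: the lead SNP (smallest differential p) plus all
    passing SNPs within the clumping window on the same chromosome."""

    lead: pd.Series
    members: pd.DataFrame
    chrom: str
    span: tuple[int, int]

    @property
    def rsid(self) -> str:
        return str(self.lead["rsid"])


def clump(rows: pd.DataFrame, window_bp: int = 1_000_000) -> list[CandidateLocus]:
    """Greedy distance clumping: repeatedly take the remaining SNP with the
    smallest differential p as a lead (ties broken by chromosome then
    position), absorb remaining SNPs on its chromosome within ``window_bp``,
    and emit a locus."""
    loci: list[CandidateLocus] = []
    remaining = rows.sort_values(
        ["p_diff", "chrom", "pos"],
        key=lambda c: pd.to_numeric(c, errors="coerce") if c.name == "chrom" else c,
    ).reset_index(drop=True)
    while not remaining.empty:
        lead = remaining.iloc[0]
        near = (remaining["chrom"] == lead["chrom"]) & (
            (remaining["pos"] - lead["pos"]).abs() <= window_bp
        )
        members = remaining[near].sort_values("pos").reset_index(drop=True)
        loci.append(CandidateLocus(
            lead=lead,
            members=members,
            chrom=str(lead["chrom"]),
            span=(int(members["pos"].min()), int(members["pos"].max())),
        ))
        remaining = remaining[~near].reset_index(drop=True)
    return loci


def loci_table(loci: list[CandidateLocus]) -> pd.DataFrame:
    """Lead-SNP table for a list of loci, mirroring the per-SNP differential
    columns plus the locus span and member count."""
    cols = ["chrom", "rsid", "pos", "a1", "a2", "beta1", "se1", "p1",
            "beta2", "se2", "p2", "z_std", "p_diff"]
    rows = []
    for loc in loci:
        row = {c: loc.lead[c] for c in cols if c in loc.lead.index}
        row["span_start"], row["span_end"] = loc.span
        row["n_members"] = len(loc.members)
        rows.append(row)
    return pd.DataFrame(rows)
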