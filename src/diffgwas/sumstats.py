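"""Reading, validating, filtering and harmonizing GWAS summary statistics.

A summary-statistics table is a :class:`pandas.DataFrame` with the columns

    chrom  rsid  pos  a1  a2  eaf  beta  se  p  n

where ``a1`` is the effect allele (the allele ``beta`` refers to), ``a2`` the
other allele, and ``eaf`` the effect-allele frequency (may be all-NaN when the
source file carries no frequency column).  Positions are 1-based, chromosome
labels are autosome strings ``"1"``..``"22"`` with any ``chr`` prefix removed.

Harmonization aligns two such tables on genomic position and a shared
effect-allele orientation: records whose alleles are swapped relative to the
second study have their effect size negated and alleles exchanged, records
whose alleles cannot be reconciled at the shared position are excluded.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: semantic column -> default source column name
DEFAULT_DIALECT: dict[str, str] = {
    "chrom": "CHR",
    "pos": "POS",
    "rsid": "SNP",
    "a1": "A1",
    "a2": "A2",
    "eaf": "FRQ",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "n": "N",
}

REQUIRED_FIELDS = ("chrom", "pos", "rsid", "a1", "a2", "beta", "se", "p")
OPTIONAL_FIELDS = ("eaf", "n")

_AUTOSOMES = {str(i) for i in range(1, 23)}
_NUCLEOTIDES = {"A", "C", "G", "T"}
#: allele pairs indistinguishable under strand flip
PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def load_dialect(source: str | Path | Mapping[str, str] | None) -> dict[str, str]:
    """Resolve a column-mapping config: a mapping, a YAML file path, or None
    (the default PGC-style names)."""
    if source is None:
        return dict(DEFAULT_DIALECT)
    if isinstance(source, Mapping):
        return {**DEFAULT_DIALECT, **dict(source)}
    path = Path(source)
    if not path.exists():
        raise ConfigError(f"dialect file not found: {path}")
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, Mapping):
        raise ConfigError(f"dialect file {path} must contain a key: column mapping")
    return {**DEFAULT_DIALECT, **{str(k): str(v) for k, v in mapping.items()}}


def read_sumstats(
    path: str | Path,
    dialect: str | Path | Mapping[str, str] | None = None,
    allow_indels: bool = False,
) -> pd.DataFrame:
    """Read one GWAS summary-statistics table.

    The file is tab- or whitespace-separated text, optionally gzip-compressed.
    ``dialect`` maps semantic names (``chrom``, ``pos``, ``rsid``, ``a1``,
    ``a2``, ``beta``, ``se``, ``p``; optionally ``eaf``, ``n``) to the source
    file's column names.

    Rows failing validation (non-numeric fields, se <= 0, p outside (0, 1],
    non-autosomal chromosome, non-SNP alleles unless ``allow_indels``,
    duplicated variant key) are dropped; the number dropped is logged and
    stored in ``df.attrs["n_dropped"]``.

    Raises
    ------
    ConfigError
        If a required semantic column is missing from the file.
    DataError
        If no valid rows remain.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"summary-statistics file not found: {path}")
    cols = load_dialect(dialect)

    raw = pd.read_csv(path, sep=None, engine="python", compression="infer",
                      dtype=str, comment=None)
    for field in REQUIRED_FIELDS:
        if cols[field] not in raw.columns:
            raise ConfigError(
                f"{path}: required column {cols[field]!r} (mapped from "
                f"{field!r}) not found; available: {list(raw.columns)}"
            )

    df = pd.DataFrame({
        "chrom": raw[cols["chrom"]].astype(str).str.removeprefix("chr"),
        "rsid": raw[cols["rsid"]].astype(str),
        "pos": pd.to_numeric(raw[cols["pos"]], errors="coerce"),
        "a1": raw[cols["a1"]].astype(str).str.upper(),
        "a2": raw[cols["a2"]].astype(str).str.upper(),
        "beta": pd.to_numeric(raw[cols["beta"]], errors="coerce"),
        "se": pd.to_numeric(raw[cols["se"]], errors="coerce"),
        "p": pd.to_numeric(raw[cols["p"]], errors="coerce"),
    })
    df["eaf"] = (pd.to_numeric(raw[cols["eaf"]], errors="coerce")
                 if cols["eaf"] in raw.columns else np.nan)
    df["n"] = (pd.to_numeric(raw[cols["n"]], errors="coerce")
               if cols["n"] in raw.columns else np.nan)

    n_in = len(df)
    ok = (
        df["chrom"].isin(_AUTOSOMES)
        & df["pos"].notna() & (df["pos"] > 0) & (df["pos"] % 1 == 0)
        & df["beta"].notna()
        & (df["se"] > 0)
        & (df["p"] > 0) & (df["p"] <= 1)
        & (df["a1"] != df["a2"])
    )
    if allow_indels:
        ok &= df["a1"].str.fullmatch("[ACGT]+") & df["a2"].str.fullmatch("[ACGT]+")
    else:
        ok &= df["a1"].isin(_NUCLEOTIDES) & df["a2"].isin(_NUCLEOTIDES)
    ok &= df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1))

    df = df[ok].copy()
    df["pos"] = df["pos"].astype(np.int64)

    # unordered allele key must be unique within one table
    key = [df["chrom"], df["pos"],
           np.minimum(df["a1"], df["a2"]), np.maximum(df["a1"], df["a2"])]
    dup = pd.MultiIndex.from_arrays(key).duplicated(keep="first")
    df = df[~dup].reset_index(drop=True)

    n_dropped = n_in - len(df)
    df.attrs["n_input"] = n_in
    df.attrs["n_dropped"] = n_dropped
    if n_dropped:
        logger.info("%s: dropped %d of %d rows failing validation",
                    path.name, n_dropped, n_in)
    if df.empty:
        raise DataError(f"{path}: no valid rows after validation")
    return df


def filter_maf(table: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Retain rows with minor-allele frequency min(eaf, 1-eaf) >= ``threshold``.

    If the table carries no frequencies at all the filter is a no-op with a
    warning (the source file had no frequency column).  Rows whose frequency
    is individually missing are dropped and counted.
    """
    if not 0 <= threshold < 0.5:
        raise ConfigError(f"MAF threshold must be in [0, 0.5), got {threshold}")
    if table["eaf"].isna().all():
        logger.warning("no allele frequencies present; MAF filter skipped")
        return table
    maf = np.minimum(table["eaf"], 1.0 - table["eaf"])
    out = table[maf >= threshold].reset_index(drop=True)
    out.attrs = dict(table.attrs)
    out.attrs["n_maf_dropped"] = len(table) - len(out)
    logger.info("MAF >= %g filter: %d -> %d SNPs", threshold, len(table), len(out))
    return out


def _check_unique_positions(table: pd.DataFrame, name: str) -> None:
    dup = table.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        row = table[dup].iloc[0]
        raise DataError(
            f"{name}: duplicate variants at position {row['chrom']}:{row['pos']}; "
            "harmonization joins on (chrom, pos) and requires one variant per position"
        )


def harmonize(
    t1: pd.DataFrame,
    t2: pd.DataFrame,
    ambiguous: str = "exclude",
) -> pd.DataFrame:
    """Merge two summary-statistics tables onto a shared effect-allele orientation.

    Records are inner-joined on (chrom, pos).  Where study 1's alleles are
    swapped relative to study 2's, study 1's beta is negated and its alleles
    exchanged (``flipped=True``); the output orientation is always study 2's.
    Position matches whose allele pairs cannot be reconciled are excluded.

    Parameters
    ----------
    ambiguous
        Handling of strand-ambiguous (palindromic A/T and C/G) SNPs:
        ``"exclude"`` (default — a strand flip is indistinguishable from an
        allele swap), ``"frequency"`` (resolve by comparing effect-allele
        frequencies when both studies report them; near-0.5 frequencies are
        still excluded), or ``"keep"`` (trust the reported strands).

    Returns
    -------
    DataFrame with columns chrom, pos, rsid, a1, a2, beta1, se1, p1, eaf1,
    beta2, se2, p2, eaf2, maf, flipped.  Merge accounting is stored in
    ``.attrs`` (n_merged, n_flipped, n_excluded_alleles, n_excluded_ambiguous,
    n_unmatched_t1, n_unmatched_t2).
    """
    if ambiguous not in ("exclude", "frequency", "keep"):
        raise ConfigError(f"unknown ambiguous-SNP policy: {ambiguous!r}")
    _check_unique_positions(t1, "trait-1 table")
    _check_unique_positions(t2, "trait-2 table")

    m = t1.merge(t2, on=["chrom", "pos"], how="inner", suffixes=("1", "2"))
    if m.empty:
        raise DataError("no positions shared between the two tables")

    same = (m["a11"] == m["a12"]) & (m["a21"] == m["a22"])
    swapped = (m["a11"] == m["a22"]) & (m["a21"] == m["a12"])
    compatible = same | swapped

    pal = pd.Series(
        list(zip(m["a12"], m["a22"])), index=m.index
    ).isin(PALINDROMIC_PAIRS) & compatible

    n_ambiguous_excluded = 0
    if ambiguous == "exclude":
        n_ambiguous_excluded = int(pal.sum())
        compatible &= ~pal
    elif ambiguous == "frequency":
        has_f = m["eaf1"].notna() & m["eaf2"].notna()
        informative = (np.minimum(m["eaf2"], 1 - m["eaf2"]) < 0.4) & has_f
        # for a palindromic SNP a strand flip mimics a swap: trust frequency
        # agreement instead of the printed alleles
        freq_same = np.abs(m["eaf1"] - m["eaf2"]) <= np.abs(m["eaf1"] - (1 - m["eaf2"]))
        resolvable = pal & informative
        same = np.where(resolvable, freq_same, same)
        swapped = np.where(resolvable, ~freq_same, swapped)
        n_ambiguous_excluded = int((pal & ~informative).sum())
        compatible = (same | swapped) & ~(pal & ~informative)
    # "keep": treat printed alleles at face value

    kept = m[compatible].copy()
    flip = pd.Series(swapped, index=m.index)[compatible].to_numpy(dtype=bool)

    beta1 = np.where(flip, -kept["beta1"], kept["beta1"])
    eaf1 = np.where(flip, 1.0 - kept["eaf1"], kept["eaf1"])

    out = pd.DataFrame({
        "chrom": kept["chrom"].to_numpy(),
        "pos": kept["pos"].to_numpy(),
        "rsid": kept["rsid1"].to_numpy(),  # trait-1 id carried for display
        "a1": kept["a12"].to_numpy(),
        "a2": kept["a22"].to_numpy(),
        "beta1": beta1,
        "se1": kept["se1"].to_numpy(),
        "p1": kept["p1"].to_numpy(),
        "eaf1": eaf1,
        "beta2": kept["beta2"].to_numpy(),
        "se2": kept["se2"].to_numpy(),
        "p2": kept["p2"].to_numpy(),
        "eaf2": kept["eaf2"].to_numpy(),
        "flipped": flip,
    })
    out["maf"] = np.minimum(out["eaf2"], 1.0 - out["eaf2"])

    out.attrs["n_merged"] = len(out)
    out.attrs["n_flipped"] = int(flip.sum())
    out.attrs["n_excluded_alleles"] = int(len(m) - compatible.sum()) - n_ambiguous_excluded
    out.attrs["n_excluded_ambiguous"] = n_ambiguous_excluded
    out.attrs["n_unmatched_t1"] = len(t1) - len(m)
    out.attrs["n_unmatched_t2"] = len(t2) - len(m)
    logger.info(
        "harmonized %d SNPs (%d flipped, %d allele-incompatible, %d ambiguous excluded)",
        len(out), out.attrs["n_flipped"], out.attrs["n_excluded_alleles"],
        n_ambiguous_excluded,
    )
    if out.empty:
        raise DataError("no allele-compatible SNPs shared between the two tables")
    return out.sort_values(["chrom", "pos"], key=_chrom_sort_key).reset_index(drop=True)


def _chrom_sort_key(col: pd.Series) -> pd.Series:
    if col.name == "chrom":
        return pd.to_numeric(col, errors="coerce")
    return col


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write any pipeline table as tab-separated text with a header."""
    table.to_csv(path, sep="\t", index=False)
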