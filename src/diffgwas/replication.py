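"""Replication lookup and triage of candidate loci in an independent GWAS.

Candidate lead SNPs are matched into a replication study (typically a
trans-ancestry GWAS that reports only z-scores and p-values), the replication
z is re-oriented to the candidate's effect allele, and candidates are
partitioned by replication strength into ``replicated`` (genome-wide
significant), ``attenuated`` (clearly non-significant) and ``intermediate``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .difftest import CandidateLocus, p_two_sided
from .errors import ConfigError, DataError
from .sumstats import DEFAULT_DIALECT, load_dialect

logger = logging.getLogger(__name__)

REPLICATION_DIALECT = {**DEFAULT_DIALECT, "z": "Z"}


@dataclass
class ReplicationRecord:
    """One candidate's replication evidence, aligned to its effect allele."""

    rsid: str
    a1: str
    a2: str
    z_rep: float | None
    p_rep: float | None
    direction_consistent: bool | None
    status: str = "unassessed"  # replicated | intermediate | attenuated | absent


def read_replication(path: str | Path,
                     dialect: str | Path | Mapping[str, str] | None = None
                     ) -> pd.DataFrame:
    """Read a replication table carrying rsid, alleles, z and p (chrom/pos
    optional), using the same column-mapping mechanism as summary statistics."""
    cols = load_dialect(dialect)
    cols.setdefault("z", REPLICATION_DIALECT["z"])
    raw = pd.read_csv(path, sep=None, engine="python", compression="infer", dtype=str)
    for fieldname in ("rsid", "a1", "a2", "z", "p"):
        if cols[fieldname] not in raw.columns:
            raise ConfigError(
                f"{path}: replication column {cols[fieldname]!r} "
                f"(mapped from {fieldname!r}) not found"
            )
    out = pd.DataFrame({
        "rsid": raw[cols["rsid"]].astype(str),
        "a1": raw[cols["a1"]].astype(str).str.upper(),
        "a2": raw[cols["a2"]].astype(str).str.upper(),
        "z": pd.to_numeric(raw[cols["z"]], errors="coerce"),
        "p": pd.to_numeric(raw[cols["p"]], errors="coerce"),
    })
    if cols["chrom"] in raw.columns and cols["pos"] in raw.columns:
        out["chrom"] = raw[cols["chrom"]].astype(str).str.removeprefix("chr")
        out["pos"] = pd.to_numeric(raw[cols["pos"]], errors="coerce")
    out = out[out["z"].notna() & (out["p"] > 0) & (out["p"] <= 1)]
    if out.empty:
        raise DataError(f"{path}: no valid replication rows")
    return out.reset_index(drop=True)


def _match_row(lead: pd.Series, rep: pd.DataFrame) -> pd.Series | None:
    hit = rep[rep["rsid"] == str(lead["rsid"])]
    if hit.empty and {"chrom", "pos"}.issubset(rep.columns):
        hit = rep[(rep["chrom"] == str(lead["chrom"]))
                  & (rep["pos"] == lead["pos"])]
    return None if hit.empty else hit.iloc[0]


def align_to_replication(candidates: Sequence[CandidateLocus] | pd.DataFrame,
                         rep: pd.DataFrame) -> list[ReplicationRecord]:
    """Match candidate lead SNPs into the replication table and orient z.

    Matching is by rsid with a (chrom, pos) fallback.  If the replication
    record's alleles are swapped relative to the candidate's orientation the
    z-score is negated; allele-incompatible matches are treated as absent
    with a warning.  Direction consistency compares the aligned replication z
    sign with the candidate's trait-2 effect direction (replication studies
    often publish z and p without betas).
    """
    if isinstance(candidates, pd.DataFrame):
        leads = [row for _, row in candidates.iterrows()]
    else:
        leads = [loc.lead for loc in candidates]

    records: list[ReplicationRecord] = []
    for lead in leads:
        rsid, a1, a2 = str(lead["rsid"]), str(lead["a1"]), str(lead["a2"])
        hit = _match_row(lead, rep)
        if hit is None:
            records.append(ReplicationRecord(rsid, a1, a2, None, None, None,
                                             status="absent"))
            continue
        if (hit["a1"], hit["a2"]) == (a1, a2):
            z = float(hit["z"])
        elif (hit["a1"], hit["a2"]) == (a2, a1):
            z = -float(hit["z"])
        else:
            logger.warning("%s: replication alleles %s/%s incompatible with %s/%s",
                           rsid, hit["a1"], hit["a2"], a1, a2)
            records.append(ReplicationRecord(rsid, a1, a2, None, None, None,
                                             status="absent"))
            continue
        consistent = bool(np.sign(z) == np.sign(lead["beta2"])) \
            if "beta2" in lead.index else None
        records.append(ReplicationRecord(rsid, a1, a2, z, float(hit["p"]),
                                         consistent))
    return records


def prioritize(records: Sequence[ReplicationRecord],
               p_replicate: float = 5e-8,
               p_attenuate: float = 1e-3) -> list[ReplicationRecord]:
    """Assign replication status to each record.

    ``replicated`` if p_rep < ``p_replicate`` (genome-wide significance in the
    replication study), ``attenuated`` if p_rep >= ``p_attenuate``, otherwise
    ``intermediate`` (retained but flagged).  Records without a match stay
    ``absent``.  Returns the same records, statuses filled in.
    """
    if not p_replicate < p_attenuate:
        raise ConfigError("p_replicate must be below p_attenuate")
    for rec in records:
        if rec.p_rep is None:
            rec.status = "absent"
        elif rec.p_rep < p_replicate:
            rec.status = "replicated"
        elif rec.p_rep >= p_attenuate:
            rec.status = "attenuated"
        else:
            rec.status = "intermediate"
    return list(records)


def replication_table(records: Sequence[ReplicationRecord]) -> pd.DataFrame:
    """Flat table of replication records (one row per candidate)."""
    return pd.DataFrame([{
        "rsid": r.rsid, "a1": r.a1, "a2": r.a2, "z_rep": r.z_rep,
        "p_rep": r.p_rep, "direction_consistent": r.direction_consistent,
        "status": r.status,
    } for r in records])
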