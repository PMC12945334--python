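"""End-to-end pipeline: read -> MAF filter -> harmonize -> prune ->
estimate rho -> differential test -> candidate selection -> clumping ->
optional replication triage, with tab-separated artifacts and a run report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import difftest, overlap, replication as repl, sumstats
from .errors import ConfigError
from .overlap import OverlapEstimate, PruningConfig
from .difftest import CandidateLocus, SelectionConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one differential-GWAS run needs.

    Every threshold of the procedure is a named parameter: MAF 0.05 on the
    trait-2 table (``maf_both`` extends it to trait 1), pruning R^2 0.1 /
    250 kb windows, genome-wide differential significance 5e-8, nominal
    per-trait 0.05, clumping 1 Mb, replication triage cutoffs 5e-8 and 1e-3,
    Manhattan truncation at -log10 p = 30.
    """

    trait1_path: str | Path = ""
    trait2_path: str | Path = ""
    replication_path: str | Path | None = None
    dialect1: Mapping[str, str] | str | None = None
    dialect2: Mapping[str, str] | str | None = None
    dialect_rep: Mapping[str, str] | str | None = None
    maf_threshold: float = 0.05
    maf_both: bool = False
    ambiguous: str = "exclude"
    pruning: PruningConfig = field(default_factory=PruningConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    rho_override: float | None = None
    standardization: str = "mean_sd"
    p_replicate: float = 5e-8
    p_attenuate: float = 1e-3
    manhattan_cap: float = 30.0
    out_dir: str | Path | None = None

    def validate(self) -> None:
        for label, path in (("trait-1", self.trait1_path),
                            ("trait-2", self.trait2_path),
                            ("replication", self.replication_path)):
            if label == "replication" and path is None:
                continue
            if not path or not Path(path).exists():
                raise ConfigError(f"{label} input not found: {path}")


@dataclass
class RunResult:
    """In-memory artifacts of one pipeline run."""

    harmonized: pd.DataFrame
    overlap: OverlapEstimate
    diff: pd.DataFrame
    candidates: pd.DataFrame
    loci: list[CandidateLocus]
    loci_table: pd.DataFrame
    replication: pd.DataFrame | None
    report: dict


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full differential-GWAS procedure described above.

    Writes (when ``cfg.out_dir`` is set) ``diff_results.tsv``,
    ``candidate_loci.tsv``, ``replication.tsv``, ``manhattan.tsv`` and
    ``run_report.yaml``; the report records rho with its confidence interval,
    SNP counts at every stage, and every threshold, so a run can be audited.
    """
    cfg.validate()
    report: dict = {"thresholds": {
        "maf": cfg.maf_threshold,
        "p_diff": cfg.selection.p_diff_threshold,
        "p_nominal": cfg.selection.p_nominal_threshold,
        "require_opposite": cfg.selection.require_opposite,
        "clump_window_bp": cfg.selection.clump_window_bp,
        "prune_method": cfg.pruning.method,
        "prune_window_bp": cfg.pruning.window_bp,
        "prune_r2": cfg.pruning.r2_threshold,
        "p_replicate": cfg.p_replicate,
        "p_attenuate": cfg.p_attenuate,
    }, "counts": {}}
    counts = report["counts"]

    t1 = sumstats.read_sumstats(cfg.trait1_path, cfg.dialect1)
    t2 = sumstats.read_sumstats(cfg.trait2_path, cfg.dialect2)
    counts["trait1_read"] = len(t1)
    counts["trait2_read"] = len(t2)

    t2 = sumstats.filter_maf(t2, cfg.maf_threshold)
    if cfg.maf_both:
        t1 = sumstats.filter_maf(t1, cfg.maf_threshold)
    counts["trait1_after_maf"] = len(t1)
    counts["trait2_after_maf"] = len(t2)

    harm = sumstats.harmonize(t1, t2, ambiguous=cfg.ambiguous)
    counts["harmonized"] = len(harm)
    counts.update({k: v for k, v in harm.attrs.items() if k.startswith("n_")})

    pruned = overlap.prune(harm, cfg.pruning)
    counts["pruned"] = len(pruned)
    if cfg.rho_override is not None:
        est = OverlapEstimate(rho=cfg.rho_override, n_snps=0,
                              ci95=(cfg.rho_override, cfg.rho_override),
                              method="override")
    else:
        est = overlap.estimate_rho(pruned, null_zmax=cfg.pruning.null_zmax)
    report["rho"] = {"estimate": est.rho, "ci95": list(est.ci95),
                     "n_snps": est.n_snps, "method": est.method}

    diff = difftest.run_diff_gwas(harm, est.rho,
                                  standardization=cfg.standardization)
    counts["tested"] = len(diff)
    counts["degenerate_dropped"] = diff.attrs.get("n_degenerate_dropped", 0)

    cand = difftest.select_candidates(diff, cfg.selection)
    counts["candidates"] = len(cand)
    loci = difftest.clump(cand, cfg.selection.clump_window_bp)
    counts["loci"] = len(loci)
    ltab = difftest.loci_table(loci)

    rep_table = None
    if cfg.replication_path is not None and loci:
        rep = repl.read_replication(cfg.replication_path, cfg.dialect_rep)
        records = repl.align_to_replication(loci, rep)
        records = repl.prioritize(records, cfg.p_replicate, cfg.p_attenuate)
        rep_table = repl.replication_table(records)
        counts["replicated"] = int((rep_table["status"] == "replicated").sum())
        counts["attenuated"] = int((rep_table["status"] == "attenuated").sum())

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sumstats.write_table(harm, out / "harmonized.tsv")
        sumstats.write_table(diff, out / "diff_results.tsv")
        sumstats.write_table(ltab, out / "candidate_loci.tsv")
        sumstats.write_table(manhattan_export(diff, cfg.manhattan_cap),
                             out / "manhattan.tsv")
        if rep_table is not None:
            sumstats.write_table(rep_table, out / "replication.tsv")
        with open(out / "run_report.yaml", "w") as fh:
            yaml.safe_dump(report, fh, sort_keys=False)

    return RunResult(harmonized=harm, overlap=est, diff=diff, candidates=cand,
                     loci=loci, loci_table=ltab, replication=rep_table,
                     report=report)


def manhattan_export(diff: pd.DataFrame, cap: float = 30.0) -> pd.DataFrame:
    """Plot-ready Manhattan table: cumulative genomic coordinate, -log10
    differential p truncated at ``cap`` (pass ``numpy.inf`` for no
    truncation), and the sign of the standardized z."""
    if diff.empty:
        raise ConfigError("differential results are empty")
    d = diff.copy()
    d["_c"] = pd.to_numeric(d["chrom"], errors="coerce")
    d = d.sort_values(["_c", "pos"])
    offsets = d.groupby("_c")["pos"].max().cumsum().shift(fill_value=0)
    genome_pos = d["pos"] + d["_c"].map(offsets)
    neglog = np.minimum(-np.log10(d["p_diff"]), cap)
    return pd.DataFrame({
        "chrom": d["chrom"], "pos": d["pos"], "rsid": d["rsid"],
        "genome_pos": genome_pos.astype(np.int64),
        "neglog10_p": neglog,
        "z_sign": np.sign(d["z_std"]).astype(int),
    }).reset_index(drop=True)
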