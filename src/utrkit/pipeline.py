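"""End-to-end pipeline: wire the analysis stages from one declarative config.

The run config is a YAML mapping mirroring :class:`RunConfig`; CLI flags
override config keys.  Outputs are deterministic for a fixed config+seed
(timestamps are confined to the run log).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import yaml

from . import io as uio
from .deletions import apply_deletion, deletion_length, motif_delta
from .fecundity import FDR_MAX, LFC_MIN, compare_broods, filter_deg, overlap_sets
from .motifs import (
    PenaltyMatrix,
    ScanConfig,
    affinity_profile,
    consensus_penalty_matrix,
    mex3_consensus,
    parse_consensus,
    scan,
)
from .profiles import anova_lsd_bonferroni, bin_profile, group_summary, per_bin_ttest
from .simulate import (
    SynthBroodSpec,
    SynthProfileSpec,
    SynthUTRSpec,
    synth_broods,
    synth_profiles,
    synth_utr,
)

__all__ = ["RunConfig", "ConfigurationError", "run_pipeline", "load_config"]

log = logging.getLogger("utrkit")


class ConfigurationError(ValueError):
    """The run config is invalid or references missing inputs."""


@dataclass
class RunConfig:
    """Declarative run description; any stage whose inputs are absent is skipped."""

    out_dir: str = "utrkit_out"
    seed: int = 0
    # scan stage
    fasta: str | None = None
    consensus: str | None = None        # degenerate-motif string; MEX-3 MRE if None
    matrix_tsv: str | None = None       # else consensus-derived default matrix
    default_penalty: float = 1.0
    rt: float = 1.0
    max_ddg: float | None = None
    profile_rule: str = "start"
    # deletion stage
    alleles_tsv: str | None = None
    catalog_tsv: str | None = None
    # imaging stage
    line_profiles_tsv: str | None = None
    n_bins: int = 20
    control_condition: str = "control"
    bonferroni_m: int | None = None
    # brood stage
    broods_tsv: str | None = None
    # DEG stage
    deg_a_tsv: str | None = None
    deg_b_tsv: str | None = None
    lfc_min: float = LFC_MIN
    fdr_max: float = FDR_MAX
    # simulate stage
    simulate: bool = False


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _require(path_str: str, what: str) -> Path:
    path = Path(path_str)
    if not path.exists():
        raise ConfigurationError(f"{what} path does not exist: {path}")
    return path


def _stage_scan(cfg: RunConfig, out: Path) -> None:
    records = uio.read_fasta(_require(cfg.fasta, "FASTA"))
    consensus = (
        parse_consensus(cfg.consensus) if cfg.consensus else mex3_consensus()
    )
    matrix = (
        PenaltyMatrix(uio.read_matrix_tsv(_require(cfg.matrix_tsv, "matrix")))
        if cfg.matrix_tsv
        else consensus_penalty_matrix(consensus, cfg.default_penalty)
    )
    scan_cfg = ScanConfig(RT=cfg.rt, max_ddg=cfg.max_ddg, profile_rule=cfg.profile_rule)
    all_sites = []
    for rec in records:
        sites = scan(rec.seq, consensus, matrix, scan_cfg, utr_id=rec.utr_id)
        all_sites.extend(sites)
        profile = affinity_profile(sites, rec.length, rule=scan_cfg.profile_rule)
        prof = profile.__class__(utr_id=rec.utr_id, values=profile.values)
        uio.write_wiggle(prof, out / f"{rec.utr_id}.wig")
        uio.write_profile_tsv(prof, out / f"{rec.utr_id}.profile.tsv")
    uio.write_sites_tsv(all_sites, out / "sites.tsv")
    log.info("scan: %d sites over %d records", len(all_sites), len(records))


def _stage_deletions(cfg: RunConfig, out: Path) -> None:
    records = {r.utr_id: r for r in uio.read_fasta(_require(cfg.fasta, "FASTA"))}
    alleles = uio.read_alleles_tsv(_require(cfg.alleles_tsv, "alleles"))
    catalog = (
        uio.read_catalog_tsv(_require(cfg.catalog_tsv, "catalog"))
        if cfg.catalog_tsv
        else [mex3_consensus()]
    )
    rows = []
    for allele in alleles:
        if allele.parent_id not in records:
            raise ConfigurationError(
                f"allele {allele.name!r}: unknown parent {allele.parent_id!r}"
            )
        parent = records[allele.parent_id]
        delta = motif_delta(parent, allele, catalog)
        uio.write_delta_tsv(delta, out / f"delta_{allele.name}.tsv")
        mutant = apply_deletion(parent, allele)
        rows.append(
            {
                "allele": allele.name, "parent_id": allele.parent_id,
                "start": allele.start, "end": allele.end,
                "deletion_length": deletion_length(allele),
                "mutant_length": mutant.length,
            }
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "alleles_summary.tsv", sep="\t", index=False)
    uio.write_alleles_bed(alleles, out / "alleles.bed")
    log.info("deletions: %d alleles processed", len(alleles))


def _stage_imaging(cfg: RunConfig, out: Path) -> None:
    import pandas as pd

    profiles = uio.read_line_profiles_tsv(_require(cfg.line_profiles_tsv, "profiles"))
    by_condition: dict[str, list] = {}
    for p in profiles:
        by_condition.setdefault(p.condition, []).append(
            bin_profile(p, cfg.n_bins)
        )
    if cfg.control_condition not in by_condition:
        raise ConfigurationError(
            f"control condition {cfg.control_condition!r} absent from profiles"
        )
    summaries = []
    for cond, binned in by_condition.items():
        summ = group_summary(binned)
        summ.insert(0, "condition", cond)
        summaries.append(summ)
    pd.concat(summaries, ignore_index=True).to_csv(
        out / "bin_summary.tsv", sep="\t", index=False
    )
    treated = [c for c in by_condition if c != cfg.control_condition]
    if len(treated) == 1:
        result = per_bin_ttest(
            by_condition[treated[0]], by_condition[cfg.control_condition]
        )
        table = result.table.copy()
        table.insert(0, "condition", treated[0])
        table.to_csv(out / "bin_stats.tsv", sep="\t", index=False)
    elif len(treated) > 1:
        results = anova_lsd_bonferroni(
            by_condition, cfg.control_condition, m=cfg.bonferroni_m
        )
        tables = []
        for cond, res in results.items():
            t = res.table.copy()
            t.insert(0, "condition", cond)
            tables.append(t)
        pd.concat(tables, ignore_index=True).to_csv(
            out / "bin_stats.tsv", sep="\t", index=False
        )
    log.info("imaging: %d conditions, %d bins", len(by_condition), cfg.n_bins)


def _stage_broods(cfg: RunConfig, out: Path) -> None:
    import pandas as pd

    datasets = uio.read_broods_tsv(_require(cfg.broods_tsv, "broods"))
    if cfg.control_condition not in datasets:
        raise ConfigurationError(
            f"control condition {cfg.control_condition!r} absent from broods"
        )
    control = datasets[cfg.control_condition]
    rows = []
    for cond, ds in datasets.items():
        if cond == cfg.control_condition:
            continue
        cmp = compare_broods(ds, control)
        rows.append(cmp.__dict__)
    pd.DataFrame(rows).to_csv(out / "brood_stats.tsv", sep="\t", index=False)
    log.info("broods: %d comparisons", len(rows))


def _stage_deg(cfg: RunConfig, out: Path) -> None:
    import pandas as pd

    table_a = uio.read_deg_tsv(_require(cfg.deg_a_tsv, "DEG table A"))
    sets_a = filter_deg(table_a, cfg.lfc_min, cfg.fdr_max)
    result = {
        "n_up_a": len(sets_a.up),
        "n_down_a": len(sets_a.down),
    }
    rows = [
        {"gene_id": g, "set": "up_a"} for g in sorted(sets_a.up)
    ] + [
        {"gene_id": g, "set": "down_a"} for g in sorted(sets_a.down)
    ]
    if cfg.deg_b_tsv:
        table_b = uio.read_deg_tsv(_require(cfg.deg_b_tsv, "DEG table B"))
        sets_b = filter_deg(table_b, cfg.lfc_min, cfg.fdr_max)
        ov = overlap_sets(sets_a.up, sets_a.down, sets_b.up, sets_b.down)
        result.update(
            n_up_b=ov.n_up_b, n_down_b=ov.n_down_b,
            n_shared_up=ov.n_shared_up, n_shared_down=ov.n_shared_down,
            n_discordant=len(ov.discordant),
        )
        rows += [{"gene_id": g, "set": "shared_up"} for g in sorted(ov.shared_up)]
        rows += [{"gene_id": g, "set": "shared_down"} for g in sorted(ov.shared_down)]
        rows += [{"gene_id": g, "set": "discordant"} for g in sorted(ov.discordant)]
    pd.DataFrame(rows, columns=["gene_id", "set"]).to_csv(
        out / "deg_sets.tsv", sep="\t", index=False
    )
    with open(out / "deg_counts.json", "w") as fh:
        json.dump(result, fh, indent=2)
        fh.write("\n")
    log.info("deg: %s", result)


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    """Emit one synthetic dataset per analysis stage, plus truth files."""
    record, truth_sites = synth_utr(
        SynthUTRSpec(
            planted=((40, 0, "perfect"), (200, 3, "perfect"), (430, 8, "perfect")),
            seed=cfg.seed,
        )
    )
    uio.write_fasta([record], out / "synthetic_utrs.fasta")
    uio.write_truth_json(
        [
            {"start": s.start, "end": s.end, "spacer_len": s.spacer_len}
            for s in truth_sites
        ],
        out / "synthetic_utrs.truth.json",
    )
    groups, effect_bins = synth_profiles(
        SynthProfileSpec(effect_bins=(8, 9, 10, 11, 12), effect_size=3.0, seed=cfg.seed)
    )
    uio.write_line_profiles_tsv(
        [p for profs in groups.values() for p in profs],
        out / "synthetic_profiles.tsv",
    )
    uio.write_truth_json(
        {"effect_bins": list(effect_bins)}, out / "synthetic_profiles.truth.json"
    )
    control, treated, shift = synth_broods(
        SynthBroodSpec(shift=75.0, seed=cfg.seed)
    )
    uio.write_broods_tsv([control, treated], out / "synthetic_broods.tsv")
    uio.write_truth_json({"shift": shift}, out / "synthetic_broods.truth.json")
    log.info("simulate: wrote synthetic UTR, profiles and broods (seed=%d)", cfg.seed)


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage whose inputs are configured; returns the output dir.

    Stage order: simulate → scan → deletions → imaging → broods → DEG.
    A JSON run log records the config, seed and package version.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.time()
    stages_run = []
    if cfg.simulate:
        _stage_simulate(cfg, out)
        stages_run.append("simulate")
        # feed simulated outputs into downstream stages when unset
        if cfg.fasta is None:
            cfg.fasta = str(out / "synthetic_utrs.fasta")
        if cfg.line_profiles_tsv is None:
            cfg.line_profiles_tsv = str(out / "synthetic_profiles.tsv")
        if cfg.broods_tsv is None:
            cfg.broods_tsv = str(out / "synthetic_broods.tsv")
    if cfg.fasta:
        _stage_scan(cfg, out)
        stages_run.append("scan")
    if cfg.fasta and cfg.alleles_tsv:
        _stage_deletions(cfg, out)
        stages_run.append("deletions")
    if cfg.line_profiles_tsv:
        _stage_imaging(cfg, out)
        stages_run.append("imaging")
    if cfg.broods_tsv:
        _stage_broods(cfg, out)
        stages_run.append("broods")
    if cfg.deg_a_tsv:
        _stage_deg(cfg, out)
        stages_run.append("deg")
    try:
        pkg_version = _pkg_version("utrkit")
    except Exception:
        pkg_version = "unknown"
    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {
                "config": {k: v for k, v in cfg.__dict__.items()},
                "seed": cfg.seed,
                "stages": stages_run,
                "utrkit_version": pkg_version,
                "elapsed_s": round(time.time() - started, 3),
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return out
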