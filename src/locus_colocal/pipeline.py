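"""End-to-end orchestration: windows → counts → enrichment → proximity →
subsampling → background odds, with a run manifest.

Every stage draws its randomness from a sub-seed derived deterministically
from the single configured seed and the stage name, so re-running the whole
pipeline — or any single stage — with the same configuration reproduces
byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import locus_colocal
from locus_colocal.annotation_io import (
    extract_window,
    read_feature_table,
    write_windows,
)
from locus_colocal.count_model import build_count_table, write_count_table, PfamCountTable
from locus_colocal.enrichment import (
    fisher_enrichment,
    permutation_null,
    zscore_table,
)
from locus_colocal.errors import ValidationError
from locus_colocal.proximity import (
    DEFAULT_AAA_EXCLUSION,
    background_defence_odds,
    defence_pfam_region_filter,
    locate_in_intervals,
    read_defence_table,
    read_interval_table,
    systems_within,
    IntervalSet,
)
from locus_colocal.subsampling import subsample_trend

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = (
    "pfam", "obs", "m_prime", "s_prime", "z", "log1p_z", "fisher_p", "p_bonf",
    "p_emp", "p_bh", "odds_ratio", "ci_low", "ci_high", "prop_test",
    "prop_control", "prop_diff", "enriched",
)


@dataclass
class RunConfig:
    """Configuration of a full analysis run; defaults follow the study
    design (40 kb windows, 10,000 permutations, Bonferroni α = 0.05, odds
    ratio > 2, 10 kb proximity, 30-CDS × 200-contig background)."""

    features_test: str
    features_control: str
    outdir: str
    systems: str | None = None
    islands: str | None = None
    plasmids: str | None = None
    dialect: str = "feature_tsv"
    anchor_pfam: str = "PF05147"
    control_anchor_pfam: str = "PF00365"
    half_width: int = 20_000
    min_span: int = 0
    permutations: int = 10_000
    alpha: float = 0.05
    min_or: float = 2.0
    pool: str = "combined"  # combined | test | control
    proximity_threshold: int = 10_000
    defence_pfams: list[str] = field(default_factory=list)
    defence_exclusion: list[str] = field(default_factory=lambda: sorted(DEFAULT_AAA_EXCLUSION))
    min_defence_hits: int = 5
    background_k: int = 30
    background_n: int = 200
    subsample_n: int = 100
    subsample_pfams: list[str] = field(default_factory=list)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("half_width", "permutations", "proximity_threshold",
                     "background_k", "background_n", "subsample_n"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.pool not in ("combined", "test", "control"):
            raise ValidationError(f"pool must be combined/test/control, got {self.pool!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage sub-seed: the run seed XOR a CRC32 hash of the stage name."""
    return (seed ^ zlib.crc32(stage.encode())) % 2**31


def _anchor_windows(contigs, anchor_pfam, half_width, min_span, group):
    windows = []
    for contig in contigs:
        anchors = [g for g in contig.features if anchor_pfam in g.pfams]
        if not anchors:
            continue
        w = extract_window(contig, anchors[0].gene_id, half_width, group=group)
        if w.span >= min_span:
            windows.append(w)
    return windows


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write result tables under ``config.outdir``.

    Returns a manifest dict (also written as ``manifest.json``) recording
    the parameter values, per-stage sub-seeds and output paths.
    """
    for name in ("features_test", "features_control", "systems", "islands", "plasmids"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            raise ValidationError(f"configured input {name} does not exist: {path}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(name: str, filename: str) -> Path:
        path = outdir / filename
        outputs[name] = str(path)
        return path

    # -- stage: windows -----------------------------------------------------
    logger.info("[windows] extracting anchored windows")
    contigs_test = read_feature_table(config.features_test, config.dialect)
    contigs_control = read_feature_table(config.features_control, config.dialect)
    windows_test = _anchor_windows(contigs_test, config.anchor_pfam,
                                   config.half_width, config.min_span, "test")
    windows_control = _anchor_windows(contigs_control, config.control_anchor_pfam,
                                      config.half_width, config.min_span, "control")
    if not windows_test or not windows_control:
        raise ValidationError("no anchored windows found in one of the groups")
    write_windows(windows_test + windows_control, emit("windows", "windows.tsv"))

    # -- stage: counts ------------------------------------------------------
    logger.info("[counts] building Pfam occurrence tables")
    counts_test = build_count_table(windows_test)
    counts_control = build_count_table(windows_control)
    write_count_table(counts_test, emit("counts_test", "counts_test.tsv"))
    write_count_table(counts_control, emit("counts_control", "counts_control.tsv"))

    pool_table = {
        "combined": PfamCountTable(
            records=pd.concat([counts_test.records, counts_control.records],
                              ignore_index=True),
            region_ids=counts_test.region_ids + counts_control.region_ids),
        "test": counts_test,
        "control": counts_control,
    }[config.pool]

    # -- stage: enrichment --------------------------------------------------
    logger.info("[enrich] Fisher, permutation and Z-score statistics")
    fisher = fisher_enrichment(counts_test, counts_control,
                               alpha=config.alpha, min_or=config.min_or)
    perm = permutation_null(counts_test, B=config.permutations,
                            seed=stage_seed(config.seed, "enrich"),
                            pool=pool_table)
    zsc = zscore_table(counts_test, pool=pool_table)

    enr = fisher.merge(perm.table[["pfam", "p_emp", "p_bh"]], on="pfam", how="left")
    enr = enr.merge(zsc[["pfam", "obs", "m_prime", "s_prime", "z", "log1p_z"]],
                    on="pfam", how="left")
    enr["obs"] = enr["obs"].fillna(0).astype(int)
    enr["neg_log10_p_bonf"] = -np.log10(enr["p_bonf"].clip(lower=1e-300))
    enr["log2_or"] = np.log2(enr["odds_ratio"])
    enr = enr.sort_values(["p_bonf", "pfam"]).reset_index(drop=True)
    cols = list(ENRICHMENT_COLUMNS) + ["neg_log10_p_bonf", "log2_or", "r_test", "r_control"]
    with open(emit("enrichment", "enrichment.tsv"), "w") as fh:
        fh.write("# per-Pfam enrichment statistics; obs/m_prime/s_prime/z are "
                 "gene-level, fisher/odds-ratio fields are region-level\n")
        enr[cols].to_csv(fh, sep="\t", index=False, float_format="%.6g")

    # -- stage: proximity ---------------------------------------------------
    systems = read_defence_table(config.systems) if config.systems else []
    islands = (read_interval_table(config.islands) if config.islands
               else IntervalSet(label="genomic_island"))
    plasmids: set[str] = set()
    if config.plasmids:
        plasmids = {line.strip() for line in open(config.plasmids) if line.strip()}

    logger.info("[proximity] defence-system distances and interval membership")
    prox_rows, loc_rows = [], []
    windows_with_defence = 0
    for w in windows_test:
        hits = systems_within(w, systems, config.proximity_threshold) if systems else []
        if any(s.activity == "defence" for s, _ in hits):
            windows_with_defence += 1
        for s, d in hits:
            prox_rows.append({
                "region_id": w.region_id, "system_name": s.system_name,
                "activity": s.activity, "distance": d,
            })
        on_plasmid, in_island = locate_in_intervals(w, islands, plasmids)
        loc_rows.append({"region_id": w.region_id,
                         "on_plasmid": int(on_plasmid), "in_island": int(in_island)})
    pd.DataFrame(prox_rows, columns=["region_id", "system_name", "activity", "distance"]) \
        .to_csv(emit("proximity", "proximity.tsv"), sep="\t", index=False)
    pd.DataFrame(loc_rows).to_csv(emit("localisation", "localisation.tsv"),
                                  sep="\t", index=False)

    defence_set = set(config.defence_pfams)
    passing = defence_pfam_region_filter(
        counts_test, defence_set, set(config.defence_exclusion),
        config.min_defence_hits) if defence_set else []
    with open(emit("defence_regions", "defence_regions.tsv"), "w") as fh:
        fh.write("region_id\n")
        for rid in passing:
            fh.write(rid + "\n")

    # -- stage: subsample ---------------------------------------------------
    logger.info("[subsample] sampling-size trend analysis")
    targets = list(config.subsample_pfams)
    if not targets:
        targets = list(enr.loc[enr["enriched"], "pfam"].head(10))
    n_max = min(config.subsample_n, counts_test.n_regions)
    trends = subsample_trend(counts_test, set(targets), n_max=n_max,
                             seed=stage_seed(config.seed, "subsample"))
    pd.DataFrame([{
        "pfam": t.pfam,
        "rho": "" if t.rho is None else f"{t.rho:.6g}",
        "p": "" if t.p is None else f"{t.p:.6g}",
        "n_max": n_max, "seed": t.seed, "flag": t.flag,
    } for t in trends]).to_csv(emit("subsample", "subsample.tsv"), sep="\t", index=False)

    # -- stage: background --------------------------------------------------
    logger.info("[background] consecutive-CDS defence odds")
    background = None
    if systems:
        background = background_defence_odds(
            contigs_control, systems,
            test_presence=(windows_with_defence, len(windows_test)),
            k=config.background_k, n_samples=config.background_n,
            seed=stage_seed(config.seed, "background"))
        with open(emit("background", "background.tsv"), "w") as fh:
            fh.write("test_with\ttest_without\tbg_with\tbg_without\todds_ratio\t"
                     "ci_low\tci_high\tfisher_p\n")
            t = background.table
            fh.write(f"{t[0, 0]}\t{t[0, 1]}\t{t[1, 0]}\t{t[1, 1]}\t"
                     f"{background.odds_ratio:.6g}\t{background.ci_low:.6g}\t"
                     f"{background.ci_high:.6g}\t{background.fisher_p:.6g}\n")

    manifest = {
        "package": "locus-colocal",
        "version": locus_colocal.__version__,
        "config": config.to_dict(),
        "stage_seeds": {s: stage_seed(config.seed, s)
                        for s in ("enrich", "subsample", "background")},
        "n_windows_test": len(windows_test),
        "n_windows_control": len(windows_control),
        "n_enriched": int(enr["enriched"].sum()),
        "n_defence_filter_regions": len(passing),
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
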