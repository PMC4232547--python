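"""End-to-end pipeline orchestration with a single config and run report.

The full run executes, in order and with per-stage TSV outputs under one
output directory:

    simulate (F2 + panel) -> filter -> map-build -> landscape -> scan ->
    sweep -> ld -> report

Each stage can be skipped or resumed from its on-disk intermediates; fixing
the seed reproduces byte-identical outputs.  The configuration is a flat
key=value text file (diffable provenance), overridable from the CLI.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype_io import (
    filter_markers,
    ld_prune,
    read_genotype_tsv,
    read_marker_table,
    write_genotype_tsv,
    write_marker_table,
)
from .ld_analysis import block_gwrr_summary, detect_ld_blocks, ld_decay, ld_pairs
from .linkage_map import build_skeleton_map, count_recombination_events
from .popgen_stats import call_selective_sweep, diversity_contrast, sliding_window_scan
from .recomb_landscape import collinearity_check, compute_gwrr, detect_hotspots
from .synthetic_data import (
    F2SimConfig,
    PanelSimConfig,
    simulate_diversity_panel,
    simulate_f2_population,
)

log = logging.getLogger("sweepmap")


@dataclass
class RunConfig:
    """All stage thresholds with defaults matching the study conventions:
    MAF 0.01 (0.05 for the diversity panel), call rate 0.85 (strict), HWE
    p 0.01, LD pruning r^2 0.05, 100-kb scan windows, hotspot GWRR 2-4."""

    outdir: str = "sweepmap_run"
    seed: int = 0
    # simulation sizes (demo scale)
    f2_progeny: int = 113
    f2_markers_per_chrom: int = 100
    f2_chromosomes: int = 3
    f2_chrom_length_cm: float = 100.0
    f2_chrom_length_bp: int = 85_000_000
    f2_twin_rate: float = 0.2
    f2_error_rate: float = 0.01
    f2_missing_rate: float = 0.1
    panel_markers: int = 2000
    # filtering
    maf_min: float = 0.01
    panel_maf_min: float = 0.05
    call_rate_min: float = 0.85
    hwe_p_min: float = 0.01
    ld_prune_r2: float = 0.05
    # map building
    lod_min: float = 6.0
    r_max: float = 0.4
    mapping_function: str = "haldane"
    jackknife_reps: int = 100
    # landscape / scan / sweep / ld
    window_bp: int = 100_000
    gwrr_window_bp: int = 1_000_000
    hotspot_gwrr_min: float = 2.0
    hotspot_gwrr_max: float = 4.0
    sweep_min_run: int = 2
    ld_block_r2_min: float = 0.5
    ld_block_max_gap: int = 0
    # optional external inputs (instead of simulation)
    f2_genotypes: str = ""
    f2_markers: str = ""
    panel_genotypes: str = ""
    panel_markers_file: str = ""
    panel_labels: str = ""

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, value = line.split("=", 1)
            key = key.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            kwargs[key] = type(current)(value.strip())
        return cls(**kwargs)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_full(config: RunConfig, stages: list[str] | None = None, resume: bool = False) -> dict:
    """Execute the pipeline; returns a run-report dict (also written as JSON).

    ``stages`` restricts execution; ``resume`` skips stages whose outputs
    already exist.  External input paths, when set, must exist before any
    stage runs.
    """
    out = Path(config.outdir)
    for attr in ("f2_genotypes", "f2_markers", "panel_genotypes",
                 "panel_markers_file", "panel_labels"):
        path = getattr(config, attr)
        if path and not Path(path).exists():
            raise FileNotFoundError(f"configured input {attr}={path} does not exist")
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "run_config.txt")
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seeds]
    all_stages = ["simulate", "filter", "map-build", "landscape", "scan", "sweep", "ld",
                  "report"]
    run_stages = stages or all_stages

    def _want(name):
        return name in run_stages

    def _done(*files):
        return resume and all((out / f).exists() for f in files)

    # --- simulate -----------------------------------------------------------
    if _want("simulate") and not _done("f2_genotypes.tsv", "panel_genotypes.tsv"):
        try:
            if config.f2_genotypes:
                f2_matrix = read_genotype_tsv(config.f2_genotypes)
                f2_table = read_marker_table(config.f2_markers)
            else:
                chroms = [
                    (f"chr{i + 1}", config.f2_chrom_length_cm, config.f2_chrom_length_bp)
                    for i in range(config.f2_chromosomes)
                ]
                f2_cfg = F2SimConfig(
                    n_progeny=config.f2_progeny, chromosomes=chroms,
                    n_markers_per_chrom=config.f2_markers_per_chrom,
                    twin_cluster_rate=config.f2_twin_rate,
                    genotype_error_rate=config.f2_error_rate,
                    missing_rate=config.f2_missing_rate, seed=stage_seeds[0],
                )
                f2_matrix, f2_truth = simulate_f2_population(f2_cfg)
                f2_table = f2_truth.marker_table
                f2_truth.write(out / "truth_f2")
            write_genotype_tsv(f2_matrix, out / "f2_genotypes.tsv")
            write_marker_table(f2_table, out / "f2_markers.tsv")

            if config.panel_genotypes:
                panel_matrix = read_genotype_tsv(config.panel_genotypes)
                panel_table = read_marker_table(config.panel_markers_file)
                labels = pd.read_csv(config.panel_labels, sep="\t", index_col=0)["subpop"]
            else:
                panel_cfg = PanelSimConfig(n_markers=config.panel_markers,
                                           seed=stage_seeds[1])
                panel_matrix, panel_truth = simulate_diversity_panel(panel_cfg)
                panel_table = panel_truth.marker_table
                labels = panel_truth.subpop_labels
                panel_truth.write(out / "truth_panel")
            write_genotype_tsv(panel_matrix, out / "panel_genotypes.tsv")
            write_marker_table(panel_table, out / "panel_markers.tsv")
            labels.rename("subpop").to_csv(out / "panel_labels.tsv", sep="\t",
                                           index_label="sample_id")
            report["stages"]["simulate"] = {
                "f2_markers": f2_matrix.n_markers, "f2_samples": f2_matrix.n_samples,
                "panel_markers": panel_matrix.n_markers,
                "panel_samples": panel_matrix.n_samples,
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("simulate", e) from e

    def _load_panel():
        matrix = read_genotype_tsv(out / "panel_genotypes.tsv")
        table = read_marker_table(out / "panel_markers.tsv")
        labels = pd.read_csv(out / "panel_labels.tsv", sep="\t", index_col=0)["subpop"]
        return matrix, table, labels

    # --- filter (panel branch) ---------------------------------------------
    if _want("filter") and not _done("panel_filtered_genotypes.tsv"):
        try:
            matrix, table, labels = _load_panel()
            matrix, table, rep1 = filter_markers(
                matrix, table, maf_min=config.panel_maf_min,
                call_rate_min=config.call_rate_min, hwe_p_min=config.hwe_p_min,
            )
            matrix, table, rep2 = ld_prune(matrix, table, r2_threshold=config.ld_prune_r2)
            pd.concat([rep1.to_dataframe(), rep2.to_dataframe()]).to_csv(
                out / "panel_filter_report.tsv", sep="\t", index=False
            )
            write_genotype_tsv(matrix, out / "panel_filtered_genotypes.tsv")
            write_marker_table(table, out / "panel_filtered_markers.tsv")
            report["stages"]["filter"] = {"retained": matrix.n_markers}
        except Exception as e:  # noqa: BLE001
            raise StageError("filter", e) from e

    # --- map-build (F2 branch) ---------------------------------------------
    skeleton = None
    if _want("map-build") and not _done("skeleton_map.tsv"):
        try:
            matrix = read_genotype_tsv(out / "f2_genotypes.tsv")
            table = read_marker_table(out / "f2_markers.tsv")
            skeleton = build_skeleton_map(
                matrix, table, lod_min=config.lod_min, r_max=config.r_max,
                mapping_function=config.mapping_function,
                n_reps=config.jackknife_reps, seed=stage_seeds[2],
            )
            skeleton.write_tsv(out / "skeleton_map.tsv")
            pd.DataFrame(skeleton.removed, columns=["marker_id", "reason"]).to_csv(
                out / "removed_markers.tsv", sep="\t", index=False
            )
            events = count_recombination_events(skeleton, matrix)
            events.to_csv(out / "recombination_events.tsv", sep="\t",
                          index_label="sample_id")
            report["stages"]["map-build"] = {
                "linkage_groups": len(skeleton.groups),
                "skeletal_markers": len(skeleton.skeletal_ids()),
                "addon_markers": len(skeleton.addon_ids()),
                "total_length_cm": round(skeleton.total_length_cm, 2),
                "recombination_events": int(events.loc["TOTAL"].sum()),
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("map-build", e) from e

    def _load_skeleton():
        # rebuild the lightweight skeleton container from its TSV
        from .linkage_map import SkeletonGroup, SkeletonMap

        df = pd.read_csv(out / "skeleton_map.tsv", sep="\t")
        groups = []
        for name, sub in df[df["role"] == "skeletal"].groupby("linkage_group", sort=False):
            groups.append(SkeletonGroup(name, list(sub["marker_id"]),
                                        sub["position_cM"].to_numpy()))
        return SkeletonMap(groups=groups)

    # --- landscape ----------------------------------------------------------
    profile = None
    if _want("landscape") and not _done("gwrr_profile.tsv"):
        try:
            skeleton = skeleton or _load_skeleton()
            table = read_marker_table(out / "f2_markers.tsv")
            profile = compute_gwrr(skeleton, table, window_bp=config.gwrr_window_bp)
            profile.write_tsv(out / "gwrr_profile.tsv")
            hotspots = detect_hotspots(profile, config.hotspot_gwrr_min,
                                       config.hotspot_gwrr_max)
            hotspots.to_csv(out / "hotspots.tsv", sep="\t", index=False)
            _write_bed(hotspots, out / "hotspots.bed")
            coll = collinearity_check(skeleton, table)
            coll.per_group.to_csv(out / "collinearity.tsv", sep="\t", index=False)
            report["stages"]["landscape"] = {
                "intervals": len(profile.intervals), "hotspots": len(hotspots),
                "mean_gwrr": round(float(profile.chromosome_mean_gwrr().mean()), 3),
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("landscape", e) from e

    # --- scan + sweep (panel branch) ----------------------------------------
    windows = None
    if _want("scan") and not _done("window_stats.tsv"):
        try:
            matrix = read_genotype_tsv(out / "panel_genotypes.tsv")
            table = read_marker_table(out / "panel_markers.tsv")
            labels = pd.read_csv(out / "panel_labels.tsv", sep="\t", index_col=0)["subpop"]
            windows = sliding_window_scan(matrix, table, labels, config.window_bp)
            windows.to_csv(out / "window_stats.tsv", sep="\t", index=False)
            report["stages"]["scan"] = {"windows": len(windows)}
        except Exception as e:  # noqa: BLE001
            raise StageError("scan", e) from e

    if _want("sweep") and not _done("sweep_calls.tsv"):
        try:
            if windows is None:
                windows = pd.read_csv(out / "window_stats.tsv", sep="\t")
            sweeps = call_selective_sweep(windows, min_run=config.sweep_min_run)
            sweeps.to_csv(out / "sweep_calls.tsv", sep="\t", index=False)
            _write_bed(sweeps.rename(columns={"start": "start_bp", "end": "end_bp"}),
                       out / "sweep_calls.bed")
            contrast = diversity_contrast(windows)
            contrast.to_csv(out / "diversity_contrast.tsv", sep="\t", index=False)
            report["stages"]["sweep"] = {"sweep_runs": len(sweeps)}
        except Exception as e:  # noqa: BLE001
            raise StageError("sweep", e) from e

    # --- ld ------------------------------------------------------------------
    if _want("ld") and not _done("ld_decay.tsv"):
        try:
            matrix = read_genotype_tsv(out / "panel_filtered_genotypes.tsv")
            table = read_marker_table(out / "panel_filtered_markers.tsv")
            pairs = ld_pairs(matrix, table)
            top = int(table["pos_bp"].max())
            edges = np.unique(np.linspace(0, max(top, 1), 11, dtype=np.int64))
            decay = ld_decay(pairs, edges)
            decay.to_csv(out / "ld_decay.tsv", sep="\t", index=False)
            blocks = detect_ld_blocks(matrix, table, r2_min=config.ld_block_r2_min,
                                      max_gap_markers=config.ld_block_max_gap)
            blocks.to_csv(out / "ld_blocks.tsv", sep="\t", index=False)
            if profile is not None and len(blocks):
                shared = set(blocks["chrom"]) & set(profile.intervals["chrom"])
                if shared:
                    summary = block_gwrr_summary(blocks, profile)
                    summary.to_csv(out / "ld_block_gwrr.tsv", sep="\t", index=False)
            report["stages"]["ld"] = {"pairs": len(pairs), "blocks": len(blocks)}
        except Exception as e:  # noqa: BLE001
            raise StageError("ld", e) from e

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    if _want("report"):
        make_report(out)
    return report


def _write_bed(df: pd.DataFrame, path) -> None:
    """BED (0-based half-open) from 1-based inclusive start/end_bp columns."""
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{max(int(row.start_bp) - 1, 0)}\t{int(row.end_bp)}\n")


def make_report(run_dir) -> str:
    """Plain-text + TSV per-chromosome summary of a (possibly partial) run."""
    run_dir = Path(run_dir)
    lines = [f"sweepmap {__version__} run report", "=" * 34]
    if not run_dir.exists() or not any(run_dir.iterdir()):
        lines.append("WARNING: empty run directory")
        text = "\n".join(lines) + "\n"
        run_dir.mkdir(parents=True, exist_ok=True)
        (run_dir / "report.txt").write_text(text)
        return text

    def _read(name):
        path = run_dir / name
        return pd.read_csv(path, sep="\t") if path.exists() else None

    skel = _read("skeleton_map.tsv")
    rows = {}
    if skel is not None:
        markers = _read("f2_markers.tsv")
        chrom_of = dict(zip(markers["marker_id"], markers["chrom"])) if markers is not None else {}
        for lg, sub in skel.groupby("linkage_group", sort=False):
            sk = sub[sub["role"] == "skeletal"]
            chroms = pd.Series([chrom_of.get(m, lg) for m in sk["marker_id"]])
            chrom = chroms.mode().iloc[0] if len(chroms) else lg
            rows[chrom] = {
                "chrom": chrom, "linkage_group": lg,
                "markers": len(sub), "skeletal": len(sk),
                "map_length_cm": round(float(sk["position_cM"].max()), 2),
            }
    else:
        lines.append("map-build: not run")
    events = _read("recombination_events.tsv")
    if events is not None and rows:
        total_row = events[events["sample_id"] == "TOTAL"]
        for chrom, row in rows.items():
            lg = row["linkage_group"]
            if lg in total_row.columns:
                row["recomb_events"] = int(total_row[lg].iloc[0])
    profile = _read("gwrr_profile.tsv")
    if profile is not None and rows:
        mean = profile.groupby("chrom").apply(
            lambda d: d["cm"].sum() / d["mb"].sum(), include_groups=False
        )
        for chrom, row in rows.items():
            if chrom in mean.index:
                row["mean_gwrr"] = round(float(mean[chrom]), 3)
    else:
        lines.append("landscape: not run")
    blocks = _read("ld_blocks.tsv")
    sweeps = _read("sweep_calls.tsv")
    for name, df in (("ld", blocks), ("sweep", sweeps)):
        if df is None:
            lines.append(f"{name}: not run")
    table = pd.DataFrame(list(rows.values()))
    if len(table):
        lines.append(table.to_string(index=False))
    if blocks is not None:
        lines.append(f"LD blocks: {len(blocks)}")
    if sweeps is not None:
        lines.append(f"sweep runs: {len(sweeps)}")
        for row in sweeps.itertuples(index=False):
            lines.append(f"  {row.chrom}:{row.start}-{row.end} ({row.n_windows} windows)")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    if len(table):
        table.to_csv(run_dir / "report_per_chromosome.tsv", sep="\t", index=False)
    return text
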