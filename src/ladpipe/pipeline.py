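"""Config-driven orchestration of the full differential-occupancy analysis.

Stages: deduplicate -> equalize depth within each compared pair (by
downsampling to the smaller library) -> island calling per condition
(lamin, optionally H3K9me3) -> peak calling per condition (TF) -> Venn
classification -> overlap enrichment of condition-B-exclusive TF peaks in
condition-A LADs -> site-anchored coverage statistics -> optional
nearest-gene assignment and direct-target calling. All outputs are
plain-text BED/TSV/JSON; two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .core import (
    GenomeLayout,
    Interval,
    merge_intervals,
    intersect_any,
    read_chrom_sizes,
    write_bed,
)
from .tags import TagLibrary, deduplicate, downsample, binned_coverage
from .domains import IslandParams, call_domains, islands_to_intervals, write_islands_bed, write_islands_tsv
from .peaks import PeakParams, call_peaks, peaks_to_intervals, write_peaks_bed
from .cooccupancy import classify_shared_exclusive, overlap_enrichment
from .covstats import (
    profile_matrix,
    average_profile,
    windowed_sum_comparison,
    site_flank_coverage,
    write_summaries_tsv,
)
from .genes import TssTable, ExpressionTable, assign_nearest_gene, tss_distance_bins, direct_targets

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass
class PipelineConfig:
    chrom_sizes: str
    lamin_A: str
    lamin_B: str
    input: str
    tf_A: str | None = None
    tf_B: str | None = None
    h3k9me3_A: str | None = None
    h3k9me3_B: str | None = None
    tss: str | None = None
    expression: str | None = None
    outdir: str = "ladpipe_out"
    seed: int = 0
    n_draws: int = 1
    island_params: dict = field(default_factory=dict)
    peak_params: dict = field(default_factory=dict)
    lamin_window: int = 10_000
    het_window: int = 5_000
    profile_flank: int = 5_000
    profile_nbins: int = 50
    coverage_bin_width: int = 100

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate_paths(self) -> None:
        required = {"chrom_sizes": self.chrom_sizes, "lamin_A": self.lamin_A,
                    "lamin_B": self.lamin_B, "input": self.input}
        optional = {"tf_A": self.tf_A, "tf_B": self.tf_B, "h3k9me3_A": self.h3k9me3_A,
                    "h3k9me3_B": self.h3k9me3_B, "tss": self.tss,
                    "expression": self.expression}
        for name, p in required.items():
            if not p or not Path(p).exists():
                raise PipelineError(f"config: required path {name}={p!r} does not exist")
        for name, p in optional.items():
            if p and not Path(p).exists():
                raise PipelineError(f"config: optional path {name}={p!r} does not exist")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and writes) the summary dict."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "parameters": {
            "seed": config.seed,
            "n_draws": config.n_draws,
            "island_params": config.island_params,
            "peak_params": config.peak_params,
            "lamin_window": config.lamin_window,
            "het_window": config.het_window,
        },
        "warnings": [],
    }

    layout = _load_layout(config)
    libs = _load_libraries(config, layout, summary)
    lads = _domain_stage(config, libs, outdir, summary)
    peaks = _peak_stage(config, libs, outdir, summary)
    _compare_stage(config, layout, lads, peaks, libs, outdir, summary)
    _gene_stage(config, peaks, outdir, summary)

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


@_stage("load_layout")
def _load_layout(config: PipelineConfig) -> GenomeLayout:
    return read_chrom_sizes(config.chrom_sizes)


@_stage("load_libraries")
def _load_libraries(config, layout, summary) -> dict[str, TagLibrary]:
    names = ["lamin_A", "lamin_B", "input", "tf_A", "tf_B", "h3k9me3_A", "h3k9me3_B"]
    libs: dict[str, TagLibrary] = {}
    for name in names:
        path = getattr(config, name)
        if path:
            libs[name] = deduplicate(TagLibrary.from_bed(path, layout, name))
    # depth equalization within each compared pair
    depth_info = {}
    for a, b, s in (("lamin_A", "lamin_B", 11), ("tf_A", "tf_B", 13),
                    ("h3k9me3_A", "h3k9me3_B", 17)):
        if a in libs and b in libs:
            target = min(libs[a].total_tags, libs[b].total_tags)
            libs[a] = downsample(libs[a], target, seed=config.seed + s)
            libs[b] = downsample(libs[b], target, seed=config.seed + s + 1)
            depth_info[f"{a}/{b}"] = target
    summary["libraries"] = {k: v.total_tags for k, v in libs.items()}
    summary["equalized_depth"] = depth_info
    return libs


@_stage("domain_calling")
def _domain_stage(config, libs, outdir, summary) -> dict[str, list[Interval]]:
    params = IslandParams(**config.island_params)
    lads: dict[str, list[Interval]] = {}
    summary["domains"] = {}
    for cond in ("A", "B"):
        for assay in ("lamin", "h3k9me3"):
            key = f"{assay}_{cond}"
            if key not in libs:
                continue
            islands = call_domains(libs[key], libs["input"], params)
            write_islands_bed(islands, outdir / f"islands_{key}.bed")
            write_islands_tsv(islands, outdir / f"islands_{key}.tsv")
            lads[key] = islands_to_intervals(islands)
            summary["domains"][key] = len(islands)
    return lads


@_stage("peak_calling")
def _peak_stage(config, libs, outdir, summary) -> dict[str, list[Interval]]:
    peaks: dict[str, list[Interval]] = {}
    summary["peaks"] = {}
    if "tf_A" not in libs or "tf_B" not in libs:
        summary["warnings"].append("TF libraries absent; peak stage skipped")
        return peaks
    params = PeakParams(**config.peak_params)
    for key in ("tf_A", "tf_B"):
        called = call_peaks(libs[key], libs["input"], params)
        write_peaks_bed(called, outdir / f"peaks_{key}.bed")
        peaks[key] = peaks_to_intervals(called)
        summary["peaks"][key] = len(called)
    return peaks


@_stage("comparison")
def _compare_stage(config, layout, lads, peaks, libs, outdir, summary) -> None:
    summary["venn"] = {}
    if "lamin_A" in lads and "lamin_B" in lads:
        venn = classify_shared_exclusive(lads["lamin_A"], lads["lamin_B"])
        summary["venn"]["lads"] = venn.to_dict()
    if "h3k9me3_A" in lads and "h3k9me3_B" in lads:
        venn = classify_shared_exclusive(lads["h3k9me3_A"], lads["h3k9me3_B"])
        summary["venn"]["h3k9me3"] = venn.to_dict()
    if "tf_A" in peaks and "tf_B" in peaks:
        venn = classify_shared_exclusive(peaks["tf_A"], peaks["tf_B"])
        summary["venn"]["tf_peaks"] = venn.to_dict()

    # condition-B-exclusive TF peaks vs condition-A LADs
    if "tf_B" in peaks and "lamin_A" in lads and peaks["tf_B"]:
        gained = [
            p for p, hit in zip(
                peaks["tf_B"], intersect_any(peaks["tf_B"], peaks.get("tf_A", []))
            )
            if not hit
        ]
        write_bed(gained, outdir / "tf_B_exclusive.bed")
        summary["tf_B_exclusive"] = len(gained)
        if gained and lads["lamin_A"]:
            enr = overlap_enrichment(
                gained, merge_intervals(lads["lamin_A"], layout=layout), layout,
                seed=config.seed, n_draws=config.n_draws,
            )
            summary["enrichment_tfB_exclusive_in_ladsA"] = enr.to_dict()
            _coverage_stage(config, layout, gained, libs, outdir, summary)
        else:
            summary["warnings"].append(
                "no condition-B-exclusive peaks or no LADs; enrichment skipped"
            )


def _coverage_stage(config, layout, gained, libs, outdir, summary) -> None:
    cov_A = binned_coverage(libs["lamin_A"], config.coverage_bin_width, normalize=True)
    cov_B = binned_coverage(libs["lamin_B"], config.coverage_bin_width, normalize=True)
    summaries, frac = windowed_sum_comparison(gained, cov_A, cov_B, window=config.lamin_window)
    write_summaries_tsv(summaries, outdir / "lamin_window_sums.tsv")
    summary["lamin_fraction_higher_A"] = frac
    mat_A = profile_matrix(gained, cov_A, config.profile_flank, config.profile_nbins)
    mat_B = profile_matrix(gained, cov_B, config.profile_flank, config.profile_nbins)
    mat_A.write_tsv(outdir / "lamin_profile_A.tsv")
    mat_B.write_tsv(outdir / "lamin_profile_B.tsv")
    (outdir / "lamin_average_profile.tsv").write_text(
        "bin\tmean_A\tmean_B\n"
        + "".join(
            f"{j}\t{a:.6g}\t{b:.6g}\n"
            for j, (a, b) in enumerate(zip(average_profile(mat_A), average_profile(mat_B)))
        )
    )
    if "h3k9me3_A" in libs and "h3k9me3_B" in libs:
        het_A = binned_coverage(libs["h3k9me3_A"], config.coverage_bin_width, normalize=True)
        het_B = binned_coverage(libs["h3k9me3_B"], config.coverage_bin_width, normalize=True)
        vals_A = site_flank_coverage(gained, het_A, window=config.het_window)
        vals_B = site_flank_coverage(gained, het_B, window=config.het_window)
        with open(outdir / "h3k9me3_site_coverage.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\th3k9me3_A\th3k9me3_B\n")
            for site, a, b in zip(gained, vals_A, vals_B):
                fh.write(f"{site.chrom}\t{site.start}\t{site.end}\t{a:.6g}\t{b:.6g}\n")
        summary["h3k9me3_mean_at_exclusive_sites"] = {
            "A": float(vals_A.mean()), "B": float(vals_B.mean()),
        }


@_stage("gene_assignment")
def _gene_stage(config, peaks, outdir, summary) -> None:
    if not config.tss:
        summary["warnings"].append("no TSS table; gene stage skipped")
        summary["genes"] = None
        return
    tss = TssTable.from_tsv(config.tss)
    sites = peaks.get("tf_B") or []
    if not sites:
        summary["warnings"].append("no TF peaks; gene stage skipped")
        summary["genes"] = None
        return
    assignment = assign_nearest_gene(sites, tss)
    bins = tss_distance_bins(sites, tss)
    summary["genes"] = {
        "assigned_sites": len(assignment),
        "tss_distance_bins": bins,
    }
    with open(outdir / "site_gene_map.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tgene_id\n")
        for site in sites:
            if site in assignment:
                fh.write(f"{site.chrom}\t{site.start}\t{site.end}\t{assignment[site]}\n")
    if config.expression:
        expr = ExpressionTable.from_tsv(config.expression)
        up, down = direct_targets(assignment, expr)
        (outdir / "direct_targets_up.tsv").write_text("".join(g + "\n" for g in up))
        (outdir / "direct_targets_down.tsv").write_text("".join(g + "\n" for g in down))
        summary["genes"]["direct_targets_up"] = len(up)
        summary["genes"]["direct_targets_down"] = len(down)
    else:
        summary["warnings"].append("no expression table; direct-target stage skipped")
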