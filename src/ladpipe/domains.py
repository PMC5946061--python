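"""SICER-style broad-domain ("island") calling for lamin B1 and H3K9 marks.

The genome is tiled with non-overlapping windows (default 10 kb). Windows
whose tag count clears a Poisson-background eligibility threshold are
assembled into islands, bridging runs of up to ``gap_size`` ineligible
windows (the gap is counted in windows, matching SICER/Epic semantics, so
the default gap of 3 spans 30 kb). Candidate islands are then scored
against a control (input-chromatin) library with a Poisson upper-tail test
on the library-size-scaled control expectation, and filtered by
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .core import GenomeLayout, Interval
from .tags import TagLibrary

__all__ = [
    "IslandParams",
    "Island",
    "window_counts",
    "eligibility_threshold",
    "assemble_islands",
    "score_islands",
    "call_domains",
    "write_islands_bed",
    "write_islands_tsv",
]


@dataclass(frozen=True)
class IslandParams:
    """Knobs of the island caller.

    window_size
        Tiling window in bases (10 kb as used for LAD detection).
    gap_size
        Maximum run of ineligible windows bridged inside an island,
        counted in windows.
    window_p0
        Poisson tail probability below which a window count makes the
        window eligible (SICER's documented default 0.2).
    effective_genome_fraction
        Mappable fraction of the genome used for the background rate.
    fdr
        BH FDR cutoff for island significance against the control.
    fragment_length
        Library insert size; recorded for provenance (window counting
        anchors tags at their 5' position and does not extend them).
    """

    window_size: int = 10_000
    gap_size: int = 3
    window_p0: float = 0.2
    effective_genome_fraction: float = 0.8
    fdr: float = 0.05
    fragment_length: int = 150
    control_pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.gap_size < 0:
            raise ValueError("gap_size must be >= 0")
        if not 0 < self.window_p0 < 1:
            raise ValueError("window_p0 must be in (0, 1)")
        if not 0 < self.effective_genome_fraction <= 1:
            raise ValueError("effective_genome_fraction must be in (0, 1]")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")


@dataclass(frozen=True)
class Island:
    """A called broad domain, aligned to window boundaries."""

    chrom: str
    start: int
    end: int
    eligible_window_count: int
    chip_tags: int
    control_tags: int
    score: float
    p: float
    q: float


def window_counts(lib: TagLibrary, window_size: int) -> dict[str, np.ndarray]:
    """Tag 5' counts per non-overlapping window tiling each chromosome."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    counts: dict[str, np.ndarray] = {}
    for chrom in lib.layout:
        nwin = -(-lib.layout[chrom] // window_size)
        counts[chrom] = np.zeros(nwin, dtype=np.int64)
    fp = lib.five_prime()
    chroms = lib.frame["chrom"].to_numpy()
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        counts[chrom] += np.bincount(fp[mask] // window_size, minlength=len(counts[chrom]))
    return counts


def eligibility_threshold(lambda_bg: float, window_p0: float) -> int:
    """Smallest count c >= 1 with P(X >= c | Poisson(lambda_bg)) < window_p0."""
    if lambda_bg <= 0:
        raise ValueError(f"background rate must be > 0, got {lambda_bg}")
    if not 0 < window_p0 < 1:
        raise ValueError("window_p0 must be in (0, 1)")
    c = 1
    # sf(c-1) = P(X >= c)
    while stats.poisson.sf(c - 1, lambda_bg) >= window_p0:
        c += 1
    return c


def assemble_islands(eligible: np.ndarray, gap_size: int) -> list[tuple[int, int]]:
    """Join eligible windows separated by <= gap_size ineligible windows.

    Returns (first, last) eligible-window indices of each island, in order.
    Islands start and end on eligible windows; they never span chromosomes
    because the flag vector is per-chromosome.
    """
    if gap_size < 0:
        raise ValueError("gap_size must be >= 0")
    idx = np.flatnonzero(np.asarray(eligible, dtype=bool))
    if idx.size == 0:
        return []
    islands: list[tuple[int, int]] = []
    first = last = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i - last - 1 <= gap_size:
            last = i
        else:
            islands.append((first, last))
            first = last = i
    islands.append((first, last))
    return islands


def _island_score(counts: np.ndarray, lambda_bg: float, threshold: int) -> float:
    """SICER-style island score: sum over eligible windows of
    -ln P_Poisson(count; lambda_bg), clipped below at 0."""
    eligible = counts[counts >= threshold]
    if eligible.size == 0:
        return 0.0
    logp = stats.poisson.logpmf(eligible, lambda_bg)
    return float(np.clip(-logp, 0.0, None).sum())


def score_islands(
    island_spans: dict[str, list[tuple[int, int]]],
    chip_counts: dict[str, np.ndarray],
    control_counts: dict[str, np.ndarray],
    layout: GenomeLayout,
    params: IslandParams,
    lambda_bg: float,
    threshold: int,
) -> list[Island]:
    """Score candidate islands against the scaled control and keep q < fdr.

    Expected chip count = control island count (floored at
    ``control_pseudocount`` to avoid p = 0 on empty control) times the
    chip/control library-size ratio.
    """
    chip_total = sum(int(a.sum()) for a in chip_counts.values())
    control_total = sum(int(a.sum()) for a in control_counts.values())
    if control_total <= 0:
        raise ValueError("control library is empty; an input library is required")
    ratio = chip_total / control_total
    cand: list[tuple[str, int, int, int, int, float]] = []
    for chrom in layout:
        for first, last in island_spans.get(chrom, []):
            chip = int(chip_counts[chrom][first : last + 1].sum())
            ctrl = int(control_counts[chrom][first : last + 1].sum())
            expected = max(ctrl, params.control_pseudocount) * ratio
            score = _island_score(chip_counts[chrom][first : last + 1], lambda_bg, threshold)
            cand.append((chrom, first, last, chip, ctrl, expected, score))
    if not cand:
        return []
    pvals = np.array(
        [stats.poisson.sf(chip - 1, expected) for _, _, _, chip, _, expected, _ in cand]
    )
    qvals = stats.false_discovery_control(pvals, method="bh")
    out: list[Island] = []
    ws = params.window_size
    for (chrom, first, last, chip, ctrl, _exp, score), p, q in zip(cand, pvals, qvals):
        if q < params.fdr:
            end = min((last + 1) * ws, layout[chrom])
            out.append(
                Island(
                    chrom=chrom,
                    start=first * ws,
                    end=end,
                    eligible_window_count=int(
                        (chip_counts[chrom][first : last + 1] >= threshold).sum()
                    ),
                    chip_tags=chip,
                    control_tags=ctrl,
                    score=score,
                    p=float(p),
                    q=float(q),
                )
            )
    order = layout.chrom_order()
    out.sort(key=lambda isl: (order[isl.chrom], isl.start))
    return out


def call_domains(
    chip_lib: TagLibrary, control_lib: TagLibrary, params: IslandParams | None = None
) -> list[Island]:
    """Full island-calling pipeline: window counts -> eligibility ->
    assembly -> control-based scoring. Deterministic."""
    params = params or IslandParams()
    if chip_lib.total_tags == 0:
        return []
    chip_counts = window_counts(chip_lib, params.window_size)
    control_counts = window_counts(control_lib, params.window_size)
    lambda_bg = (
        chip_lib.total_tags
        * params.window_size
        / (chip_lib.layout.total_length * params.effective_genome_fraction)
    )
    threshold = eligibility_threshold(lambda_bg, params.window_p0)
    spans = {
        chrom: assemble_islands(chip_counts[chrom] >= threshold, params.gap_size)
        for chrom in chip_lib.layout
    }
    return score_islands(
        spans, chip_counts, control_counts, chip_lib.layout, params, lambda_bg, threshold
    )


def islands_to_intervals(islands: Sequence[Island]) -> list[Interval]:
    return [Interval(i.chrom, i.start, i.end) for i in islands]


def write_islands_bed(islands: Sequence[Island], path: str | Path) -> None:
    """BED6: name island_k, score = -10 log10 q capped at 1000, strand '.'"""
    with open(path, "w") as fh:
        for k, isl in enumerate(islands, start=1):
            score = 1000.0 if isl.q <= 0 else min(-10.0 * np.log10(isl.q), 1000.0)
            fh.write(f"{isl.chrom}\t{isl.start}\t{isl.end}\tisland_{k}\t{score:.1f}\t.\n")


def write_islands_tsv(islands: Sequence[Island], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\teligible_windows\tchip_tags\tcontrol_tags\tscore\tp\tq\n"
        )
        for isl in islands:
            fh.write(
                f"{isl.chrom}\t{isl.start}\t{isl.end}\t{isl.eligible_window_count}\t"
                f"{isl.chip_tags}\t{isl.control_tags}\t{isl.score:.4f}\t{isl.p:.6g}\t{isl.q:.6g}\n"
            )
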