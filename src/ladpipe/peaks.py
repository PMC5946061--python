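"""Punctate peak calling for pioneer-factor (Foxa2-style) ChIP-seq.

A deliberately simple two-stage caller in the candidate-then-compare mold:
tags are extended to the library insert size and piled into small bins;
bins clearing a genome-wide Poisson tail threshold seed candidate regions,
which are then tested against the input library with a binomial
chip-vs-control test and filtered by BH FDR. The design trades the
simulated-background machinery of heavier callers for determinism and
oracle-testability; every stage is a closed-form count statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .core import GenomeLayout, Interval
from .tags import TagLibrary, extend_tags, extended_coverage

__all__ = [
    "PeakParams",
    "Peak",
    "call_peaks",
    "coverage_filter",
    "write_peaks_bed",
]


@dataclass(frozen=True)
class PeakParams:
    fragment_length: int = 150
    bin_width: int = 50
    candidate_p0: float = 1e-4
    fdr: float = 0.05
    min_peak_width: int = 100
    merge_gap: int = 100

    def __post_init__(self) -> None:
        for name in ("fragment_length", "bin_width", "min_peak_width", "merge_gap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.candidate_p0 < 1:
            raise ValueError("candidate_p0 must be in (0, 1)")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit: int  # absolute position of max extended-fragment coverage
    chip_tags: int
    control_tags: int
    enrichment: float
    p: float
    q: float


def _fragment_overlap_counts(
    lib: TagLibrary, fragment_length: int, regions: Sequence[tuple[str, int, int]]
) -> np.ndarray:
    """Number of extended fragments overlapping each (chrom, start, end)."""
    ext = extend_tags(lib, fragment_length)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    f = ext.frame
    chroms = f["chrom"].to_numpy()
    starts = f["start"].to_numpy()
    ends = f["end"].to_numpy()
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        by_chrom[chrom] = (np.sort(starts[mask]), np.sort(ends[mask]))
    out = np.zeros(len(regions), dtype=np.int64)
    for i, (chrom, s, e) in enumerate(regions):
        entry = by_chrom.get(chrom)
        if entry is None:
            continue
        st, en = entry
        # overlap iff start < e and end > s
        out[i] = np.searchsorted(st, e, side="left") - np.searchsorted(en, s, side="right")
    return out


def call_peaks(
    chip_lib: TagLibrary, control_lib: TagLibrary, params: PeakParams | None = None
) -> list[Peak]:
    """Call punctate peaks in chip vs an input control.

    Stages: (1) extend tags to the insert size; (2) binned fragment-pileup
    coverage; (3) candidate bins where the pooled chip+control count
    clears the genome-wide Poisson tail at candidate_p0 — selecting on
    the pooled total keeps the subsequent conditional test unbiased;
    (4) merge candidate bins within merge_gap bases, drop regions
    narrower than min_peak_width; (5) per region, binomial test of chip
    vs control fragment counts at theta =
    chip_total/(chip_total+control_total); (6) BH over candidates, keep
    q < fdr. Summit = center of the maximum chip-coverage bin.
    Cross-condition comparability (equal depth) is the caller's
    responsibility via downsampling beforehand.
    """
    params = params or PeakParams()
    if control_lib.total_tags == 0:
        raise ValueError("peak calling requires a non-empty input control library")
    layout = chip_lib.layout
    cov = extended_coverage(chip_lib, params.fragment_length, params.bin_width)
    cov_ctrl = extended_coverage(control_lib, params.fragment_length, params.bin_width)
    pooled = {ch: cov.data[ch] + cov_ctrl.data[ch] for ch in cov.data}
    n_bins = sum(len(a) for a in pooled.values())
    lam = sum(float(a.sum()) for a in pooled.values()) / n_bins
    if cov.total() <= 0:
        return []
    c = 1
    while stats.poisson.sf(c - 1, lam) >= params.candidate_p0:
        c += 1
    # candidate regions: merge above-threshold bins within merge_gap
    regions: list[tuple[str, int, int]] = []
    gap_bins = params.merge_gap // params.bin_width
    for chrom in layout:
        arr = pooled[chrom]
        hot = np.flatnonzero(arr >= c)
        if hot.size == 0:
            continue
        first = last = int(hot[0])
        spans: list[tuple[int, int]] = []
        for b in hot[1:]:
            b = int(b)
            if b - last - 1 <= gap_bins:
                last = b
            else:
                spans.append((first, last))
                first = last = b
        spans.append((first, last))
        for f0, l0 in spans:
            s = f0 * params.bin_width
            e = min((l0 + 1) * params.bin_width, layout[chrom])
            if e - s >= params.min_peak_width:
                regions.append((chrom, s, e))
    if not regions:
        return []
    chip_n = _fragment_overlap_counts(chip_lib, params.fragment_length, regions)
    ctrl_n = _fragment_overlap_counts(control_lib, params.fragment_length, regions)
    theta = chip_lib.total_tags / (chip_lib.total_tags + control_lib.total_tags)
    n_trials = chip_n + ctrl_n
    pvals = stats.binom.sf(chip_n - 1, n_trials, theta)
    qvals = stats.false_discovery_control(pvals, method="bh")
    peaks: list[Peak] = []
    for (chrom, s, e), kc, kb, p, q in zip(regions, chip_n, ctrl_n, pvals, qvals):
        expected = int(kc + kb) * theta
        if q >= params.fdr or expected <= 0 or kc <= expected:
            continue
        arr = cov.data[chrom]
        b0, b1 = s // params.bin_width, (e - 1) // params.bin_width
        rel = int(np.argmax(arr[b0 : b1 + 1]))
        summit = min((b0 + rel) * params.bin_width + params.bin_width // 2, e - 1)
        peaks.append(
            Peak(
                chrom=chrom,
                start=s,
                end=e,
                summit=summit,
                chip_tags=int(kc),
                control_tags=int(kb),
                enrichment=float(kc / expected),
                p=float(p),
                q=float(q),
            )
        )
    order = layout.chrom_order()
    peaks.sort(key=lambda pk: (order[pk.chrom], pk.start))
    return peaks


def coverage_filter(
    sites: Sequence[Interval],
    lib: TagLibrary,
    base_cutoff: int = 400,
    read_length: int = 75,
) -> tuple[list[Interval], float]:
    """Keep sites whose summed per-base tag coverage reaches ``base_cutoff``.

    A site's base coverage is the total number of tag bases falling inside
    it (sum over tags of the overlap length). Returns the kept sites and
    the read-equivalent threshold base_cutoff / read_length rounded to one
    decimal (400 bases at 75 bp reads = 5.3 reads per region).
    """
    if read_length <= 0:
        raise ValueError("read_length must be > 0")
    f = lib.frame
    chroms = f["chrom"].to_numpy()
    starts = f["start"].to_numpy()
    ends = f["end"].to_numpy()
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        order = np.argsort(starts[mask], kind="stable")
        by_chrom[chrom] = (starts[mask][order], ends[mask][order])
    kept: list[Interval] = []
    for site in sites:
        entry = by_chrom.get(site.chrom)
        bases = 0
        if entry is not None:
            st, en = entry
            # candidate tags: any with start < site.end; filter by end > start
            hi = np.searchsorted(st, site.end, side="left")
            s_sub, e_sub = st[:hi], en[:hi]
            ov = np.minimum(e_sub, site.end) - np.maximum(s_sub, site.start)
            bases = int(ov[ov > 0].sum())
        if bases >= base_cutoff:
            kept.append(site)
    return kept, round(base_cutoff / read_length, 1)


def peaks_to_intervals(peaks: Sequence[Peak]) -> list[Interval]:
    return [Interval(p.chrom, p.start, p.end) for p in peaks]


def write_peaks_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """narrowPeak-like: chrom start end name int(-10log10 q) . enrichment
    -log10 p -log10 q summit-offset."""
    with open(path, "w") as fh:
        for k, pk in enumerate(peaks, start=1):
            q10 = 1000 if pk.q <= 0 else min(int(round(-10 * np.log10(pk.q))), 1000)
            lp = 320.0 if pk.p <= 0 else -np.log10(pk.p)
            lq = 320.0 if pk.q <= 0 else -np.log10(pk.q)
            fh.write(
                f"{pk.chrom}\t{pk.start}\t{pk.end}\tpeak_{k}\t{q10}\t.\t"
                f"{pk.enrichment:.4f}\t{lp:.4f}\t{lq:.4f}\t{pk.summit - pk.start}\n"
            )
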