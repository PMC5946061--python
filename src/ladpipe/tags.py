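"""Tag-level preprocessing: dedup, downsampling, fragment extension, binned
coverage, per-million normalization, and replicate correlation.

A :class:`TagLibrary` holds mapped-read footprints ("tags") as a vectorized
table; each tag's counting anchor is its 5' position (start on +, end-1 on -).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeLayout, Interval, TagRecord, read_tags

__all__ = [
    "TagLibrary",
    "CoverageVector",
    "deduplicate",
    "downsample",
    "extend_tags",
    "binned_coverage",
    "replicate_correlation",
]

_COLS = ["chrom", "start", "end", "strand"]


@dataclass
class TagLibrary:
    """A labelled collection of tags on a shared genome layout."""

    frame: pd.DataFrame
    layout: GenomeLayout
    label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in _COLS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"tag frame missing columns {missing}")
        self.frame = self.frame[_COLS].reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Iterable[TagRecord], layout: GenomeLayout, label: str = ""
    ) -> "TagLibrary":
        recs = list(records)
        frame = pd.DataFrame(
            {
                "chrom": [r.chrom for r in recs],
                "start": np.asarray([r.start for r in recs], dtype=np.int64),
                "end": np.asarray([r.end for r in recs], dtype=np.int64),
                "strand": [r.strand for r in recs],
            }
        )
        lib = cls(frame, layout, label)
        lib.validate()
        return lib

    @classmethod
    def from_bed(cls, path: str | Path, layout: GenomeLayout, label: str = "") -> "TagLibrary":
        """Vectorized BED6 reader for large tag files; strand defaults to +.

        Delegates to :func:`ladpipe.core.read_tags` (with its line-numbered
        errors) when the fast path cannot parse the file.
        """
        try:
            frame = pd.read_csv(
                path, sep="\t", header=None, comment="#",
                usecols=[0, 1, 2, 5], names=["chrom", "start", "end", "strand"],
                dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
            )
        except Exception:
            return cls.from_records(read_tags(path, layout), layout, label or Path(path).stem)
        frame.loc[~frame["strand"].isin(["+", "-"]), "strand"] = "+"
        lib = cls(frame, layout, label or Path(path).stem)
        lib.validate()
        return lib

    def to_records(self) -> list[TagRecord]:
        return [
            TagRecord(c, int(s), int(e), strand=t)
            for c, s, e, t in self.frame.itertuples(index=False)
        ]

    @property
    def total_tags(self) -> int:
        return len(self.frame)

    def validate(self) -> None:
        f = self.frame
        if len(f) == 0:
            return
        for chrom, sub in f.groupby("chrom", sort=False):
            if chrom not in self.layout:
                raise ValueError(f"chromosome {chrom!r} not in layout")
            if (sub["start"].to_numpy() < 0).any() or (
                sub["end"].to_numpy() > self.layout[chrom]
            ).any():
                raise ValueError(f"tags out of bounds on {chrom}")
        if (f["end"].to_numpy() - f["start"].to_numpy() < 1).any():
            raise ValueError("tags must span at least 1 base")

    def five_prime(self) -> np.ndarray:
        """Strand-aware 5' positions of all tags."""
        s = self.frame["start"].to_numpy()
        e = self.frame["end"].to_numpy()
        minus = self.frame["strand"].to_numpy() == "-"
        return np.where(minus, e - 1, s)

    def write_bed(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["name"] = [f"tag_{i + 1}" for i in range(len(out))]
        out["score"] = 0
        out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class CoverageVector:
    """Per-chromosome fixed-bin tag counts, optionally per-million normalized.

    ``data[chrom][i]`` counts the tags anchored in bin ``i`` (or, after
    normalization, that count times 1e6 / total mapped tags).
    """

    data: dict[str, np.ndarray]
    bin_width: int
    layout: GenomeLayout
    normalized: bool = False
    scale: float = 1.0  # divisor applied: total tags when normalized

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Coverage summed over [start, end), weighting edge bins by the
        fraction of the bin inside the window; out-of-bounds bases count 0."""
        if chrom not in self.data:
            return 0.0
        arr = self.data[chrom]
        bw = self.bin_width
        start = max(start, 0)
        end = min(end, len(arr) * bw)
        if end <= start:
            return 0.0
        b0, b1 = start // bw, (end - 1) // bw
        if b0 == b1:
            return float(arr[b0]) * (end - start) / bw
        total = float(arr[b0]) * ((b0 + 1) * bw - start) / bw
        total += float(arr[b1]) * (end - b1 * bw) / bw
        if b1 - b0 > 1:
            total += float(arr[b0 + 1 : b1].sum())
        return total

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.layout:
                arr = self.data.get(chrom)
                if arr is None:
                    continue
                clen = self.layout[chrom]
                for i, v in enumerate(arr):
                    if v:
                        s = i * self.bin_width
                        fh.write(f"{chrom}\t{s}\t{min(s + self.bin_width, clen)}\t{v:g}\n")


def deduplicate(lib: TagLibrary) -> TagLibrary:
    """Keep at most one tag per (chrom, start, strand), first occurrence wins.

    This is the coordinate-level analogue of duplicate-read removal done on
    alignments; it is idempotent.
    """
    frame = lib.frame.drop_duplicates(subset=["chrom", "start", "strand"], keep="first")
    return TagLibrary(frame.reset_index(drop=True), lib.layout, lib.label)


def downsample(lib: TagLibrary, n: int, seed: int) -> TagLibrary:
    """Uniform sample of min(n, total) tags without replacement.

    Deterministic given ``seed``; selected tags keep their original order.
    """
    if n < 0:
        raise ValueError(f"downsample size must be >= 0, got {n}")
    total = lib.total_tags
    if n >= total:
        return TagLibrary(lib.frame.copy(), lib.layout, lib.label)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(total, size=n, replace=False))
    return TagLibrary(lib.frame.iloc[idx].reset_index(drop=True), lib.layout, lib.label)


def extend_tags(lib: TagLibrary, fragment_length: int) -> TagLibrary:
    """Extend each tag from its 5' end to the library insert size.

    A + tag [s, e) becomes [s, s+L); a - tag becomes [e-L, e); both clipped
    to chromosome bounds.
    """
    if fragment_length < 1:
        raise ValueError(f"fragment_length must be >= 1, got {fragment_length}")
    f = lib.frame.copy()
    start = f["start"].to_numpy(copy=True)
    end = f["end"].to_numpy(copy=True)
    minus = f["strand"].to_numpy() == "-"
    new_start = np.where(minus, end - fragment_length, start)
    new_end = np.where(minus, end, start + fragment_length)
    # clip per chromosome
    lens = np.asarray([lib.layout[c] for c in f["chrom"]], dtype=np.int64) if len(f) else np.array([], dtype=np.int64)
    new_start = np.maximum(new_start, 0)
    new_end = np.minimum(new_end, lens) if len(f) else new_end
    f["start"], f["end"] = new_start, new_end
    return TagLibrary(f, lib.layout, lib.label)


def binned_coverage(
    lib: TagLibrary, bin_width: int, normalize: bool = False
) -> CoverageVector:
    """Count each tag once in the bin holding its 5' position.

    With ``normalize`` each count is scaled by 1e6 / total_tags (CPM).
    The unnormalized bin sum equals the library's tag total.
    """
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    data: dict[str, np.ndarray] = {}
    for chrom in lib.layout:
        nbins = -(-lib.layout[chrom] // bin_width)
        data[chrom] = np.zeros(nbins, dtype=np.float64)
    fp = lib.five_prime()
    chroms = lib.frame["chrom"].to_numpy()
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        counts = np.bincount(fp[mask] // bin_width, minlength=len(data[chrom]))
        data[chrom] += counts
    scale = 1.0
    if normalize:
        if lib.total_tags == 0:
            raise ValueError("cannot normalize an empty library")
        scale = float(lib.total_tags)
        for chrom in data:
            data[chrom] *= 1e6 / scale
    return CoverageVector(data, bin_width, lib.layout, normalized=normalize, scale=scale)


def extended_coverage(
    lib: TagLibrary, fragment_length: int, bin_width: int, normalize: bool = False
) -> CoverageVector:
    """Fragment-pileup coverage: each tag extended to ``fragment_length``
    contributes to every bin its fragment overlaps."""
    ext = extend_tags(lib, fragment_length)
    data: dict[str, np.ndarray] = {}
    for chrom in lib.layout:
        nbins = -(-lib.layout[chrom] // bin_width)
        data[chrom] = np.zeros(nbins, dtype=np.float64)
    f = ext.frame
    chroms = f["chrom"].to_numpy()
    starts = f["start"].to_numpy()
    ends = f["end"].to_numpy()
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        b0 = starts[mask] // bin_width
        b1 = (ends[mask] - 1) // bin_width
        nbins = len(data[chrom])
        delta = np.zeros(nbins + 1, dtype=np.float64)
        np.add.at(delta, b0, 1.0)
        np.add.at(delta, b1 + 1, -1.0)
        data[chrom] += np.cumsum(delta[:-1])
    if normalize:
        if lib.total_tags == 0:
            raise ValueError("cannot normalize an empty library")
        for chrom in data:
            data[chrom] *= 1e6 / lib.total_tags
    return CoverageVector(
        data, bin_width, lib.layout, normalized=normalize,
        scale=float(lib.total_tags) if normalize else 1.0,
    )


def replicate_correlation(
    covA: CoverageVector,
    covB: CoverageVector,
    regions: Sequence[Interval],
    min_len: int = 50,
) -> float:
    """Pearson r between per-region summed coverages of two samples.

    Regions shorter than ``min_len`` bases are dropped first. Raises
    ``ValueError`` when fewer than two regions remain or either vector of
    region sums has zero variance (r undefined).
    """
    if covA.bin_width != covB.bin_width:
        raise ValueError("coverage vectors must share a bin width")
    kept = [r for r in regions if r.length >= min_len]
    if len(kept) < 2:
        raise ValueError(
            f"need >= 2 regions of length >= {min_len} for a correlation, got {len(kept)}"
        )
    sums_a = np.array([covA.window_sum(r.chrom, r.start, r.end) for r in kept])
    sums_b = np.array([covB.window_sum(r.chrom, r.start, r.end) for r in kept])
    if np.ptp(sums_a) == 0 or np.ptp(sums_b) == 0:
        raise ValueError("zero variance in region sums; correlation undefined")
    r, _ = stats.pearsonr(sums_a, sums_b)
    return float(r)
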