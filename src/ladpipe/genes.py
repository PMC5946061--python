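"""Nearest-gene assignment of binding sites, TSS-distance binning, and
direct-target calling by expression fold change.

Assignment is "single closest gene": each site maps to the gene whose TSS
is nearest its midpoint (strand-ignored), unassigned beyond ``max_dist``
(default 10,000 kb). Fold changes follow the signed linear convention
(+2 = twofold up, -2 = twofold down); a switch accepts log2 values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenomeLayout, Interval

__all__ = [
    "TssTable",
    "ExpressionTable",
    "assign_nearest_gene",
    "tss_distance_bins",
    "direct_targets",
    "TSS_BIN_EDGES",
    "TSS_BIN_LABELS",
]

logger = logging.getLogger(__name__)

TSS_BIN_EDGES = (0, 5_000, 50_000, 500_000)
TSS_BIN_LABELS = ("0-5kb", "5-50kb", "50-500kb", ">500kb")


@dataclass
class TssTable:
    """gene_id -> (chrom, tss position, strand)."""

    frame: pd.DataFrame  # columns: gene_id, chrom, tss, strand

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "tss", "strand"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"TSS table needs columns {sorted(required)}")
        if self.frame["gene_id"].duplicated().any():
            dups = self.frame.loc[self.frame["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids in TSS table: {dups[:5]}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_bed(cls, path: str | Path) -> "TssTable":
        """BED6 with the TSS as a 1-bp interval and gene_id in the name column."""
        from .core import read_tags, read_bed

        rows = []
        for rec in read_bed(path):
            rows.append((rec.name or f"gene_{len(rows) + 1}", rec.chrom, rec.start, "+"))
        return cls(pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"]))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TssTable":
        """Four-column TSV: gene_id, chrom, tss, strand (header optional)."""
        frame = pd.read_csv(path, sep="\t")
        if "gene_id" not in frame.columns:
            frame = pd.read_csv(
                path, sep="\t", header=None, names=["gene_id", "chrom", "tss", "strand"]
            )
        return cls(frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionTable:
    """gene_id -> fold_change (signed linear by default)."""

    frame: pd.DataFrame  # columns: gene_id, fold_change
    log2: bool = False

    def __post_init__(self) -> None:
        required = {"gene_id", "fold_change"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"expression table needs columns {sorted(required)}")
        if (self.frame["fold_change"] == 0).any():
            raise ValueError("fold_change values must be nonzero")
        self.frame = self.frame.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path, log2: bool = False) -> "ExpressionTable":
        return cls(pd.read_csv(path, sep="\t"), log2=log2)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def lookup(self) -> dict[str, float]:
        return dict(zip(self.frame["gene_id"], self.frame["fold_change"]))


def assign_nearest_gene(
    sites: Sequence[Interval], tss_table: TssTable, max_dist: int = 10_000_000
) -> dict[Interval, str]:
    """Map each site to the gene with the nearest TSS (by site midpoint).

    Sites farther than ``max_dist`` from every TSS on their chromosome are
    left unassigned; equidistant genes tie-break lexicographically.
    """
    if len(tss_table) == 0:
        raise ValueError("TSS table is empty")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in tss_table.frame.groupby("chrom", sort=False):
        # sort by (tss, gene_id) so the lexicographic tie-break is a stable scan
        sub = sub.sort_values(["tss", "gene_id"], kind="stable")
        by_chrom[chrom] = (sub["tss"].to_numpy(np.int64), sub["gene_id"].to_numpy(object))
    assignment: dict[Interval, str] = {}
    for site in sites:
        entry = by_chrom.get(site.chrom)
        if entry is None:
            continue
        tss, genes = entry
        mid = site.midpoint
        dist = np.abs(tss - mid)
        best = dist.min()
        if best > max_dist:
            continue
        winners = [genes[i] for i in np.flatnonzero(dist == best)]
        assignment[site] = min(winners)
    return assignment


def tss_distance_bins(
    sites: Sequence[Interval],
    tss_table: TssTable,
    max_dist: int = 10_000_000,
) -> dict[str, int]:
    """Count assigned sites per TSS-distance bin.

    Bins are half-open, lower-inclusive: [0,5kb), [5,50kb), [50,500kb),
    >=500kb; counts sum to the number of assigned sites.
    """
    assignment = assign_nearest_gene(sites, tss_table, max_dist=max_dist)
    tss_pos = dict(zip(tss_table.frame["gene_id"], tss_table.frame["tss"]))
    tss_chrom = dict(zip(tss_table.frame["gene_id"], tss_table.frame["chrom"]))
    counts = {label: 0 for label in TSS_BIN_LABELS}
    for site, gene in assignment.items():
        assert tss_chrom[gene] == site.chrom
        d = abs(site.midpoint - tss_pos[gene])
        idx = int(np.searchsorted(TSS_BIN_EDGES, d, side="right")) - 1
        counts[TSS_BIN_LABELS[idx]] += 1
    return counts


def direct_targets(
    site_gene_map: dict[Interval, str],
    expression: ExpressionTable,
    up_threshold: float = 2.0,
    down_threshold: float = -2.0,
) -> tuple[list[str], list[str]]:
    """Split bound genes into up/down direct targets by fold change.

    With signed linear fold changes, up = fold_change > up_threshold and
    down = fold_change < down_threshold; with ``expression.log2`` the
    thresholds are log2(up_threshold) and -log2(|down_threshold|). Genes
    bound by several sites count once; bound genes missing from the
    expression table are excluded and logged.
    """
    if expression.log2:
        up_t = float(np.log2(up_threshold))
        down_t = float(-np.log2(abs(down_threshold)))
    else:
        if abs(up_threshold) <= 1 or abs(down_threshold) <= 1:
            raise ValueError("linear fold-change thresholds must exceed 1 in magnitude")
        up_t, down_t = up_threshold, down_threshold
    fc = expression.lookup()
    bound = sorted(set(site_gene_map.values()))
    up: list[str] = []
    down: list[str] = []
    for gene in bound:
        if gene not in fc:
            logger.warning("bound gene %s missing from expression table; excluded", gene)
            continue
        v = fc[gene]
        if v > up_t:
            up.append(gene)
        elif v < down_t:
            down.append(gene)
    return up, down
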