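"""Comparative occupancy statistics: shared/exclusive (Venn) classification
of two region sets and overlap enrichment of sites in domains against a
random-placement background, tested with Fisher's exact test.

The background construction mirrors the common "random genomic regions of
the same size" control: each site is replaced by a region of identical
length placed uniformly at random on the same chromosome, optionally
rejecting placements that cross an exclusion set (e.g. assembly gaps).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .core import GenomeLayout, Interval, intersect_any, is_merged

__all__ = [
    "VennResult",
    "EnrichmentResult",
    "classify_shared_exclusive",
    "random_background",
    "overlap_enrichment",
]


@dataclass(frozen=True)
class VennResult:
    """Two-set overlap classification by >= 1 shared bp.

    A-side and B-side overlap counts can differ (one A region may span
    several B regions); both are reported, with the A-side count as the
    conventional Venn center.
    """

    n_A: int
    n_B: int
    A_overlapping_B: int
    B_overlapping_A: int

    @property
    def A_only(self) -> int:
        return self.n_A - self.A_overlapping_B

    @property
    def B_only(self) -> int:
        return self.n_B - self.B_overlapping_A

    @property
    def venn_center(self) -> int:
        return self.A_overlapping_B

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(
            A_only=self.A_only,
            B_only=self.B_only,
            venn_center=self.venn_center,
            center_discrepancy=self.B_overlapping_A - self.A_overlapping_B,
        )
        return d


@dataclass(frozen=True)
class EnrichmentResult:
    n_sites: int
    k_observed: int
    k_background: int
    n_background: int
    odds_ratio: float
    fisher_p: float
    seed: int
    n_draws: int

    @property
    def table(self) -> list[list[int]]:
        return [
            [self.k_observed, self.n_sites - self.k_observed],
            [self.k_background, self.n_background - self.k_background],
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["table"] = self.table
        return d


def fisher_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table of counts.

    The p-value is the total hypergeometric probability of all tables with
    the observed margins that are no more probable than the observed one.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p)


def classify_shared_exclusive(
    setA: Sequence[Interval], setB: Sequence[Interval]
) -> VennResult:
    """Classify each region of two merged sets as shared or exclusive.

    Each input set must be internally non-overlapping (merge first);
    sharing means >= 1 bp of overlap with any region of the other set.
    """
    for label, regions in (("A", setA), ("B", setB)):
        if not is_merged(regions):
            raise ValueError(
                f"set {label} contains internally overlapping regions; "
                "merge it first (ladpipe.core.merge_intervals)"
            )
    a_hits = intersect_any(setA, setB)
    b_hits = intersect_any(setB, setA)
    return VennResult(
        n_A=len(setA),
        n_B=len(setB),
        A_overlapping_B=int(a_hits.sum()),
        B_overlapping_A=int(b_hits.sum()),
    )


def random_background(
    sites: Sequence[Interval],
    layout: GenomeLayout,
    seed: int,
    n_draws: int = 1,
    exclusion: Sequence[Interval] | None = None,
    max_tries: int = 1000,
) -> list[list[Interval]]:
    """Draw background sets of length-matched random regions.

    For each site, one region of identical length is placed uniformly at
    random on the same chromosome, rejecting placements crossing the
    chromosome end or any exclusion interval. Deterministic per seed;
    returns one list per draw.
    """
    rng = np.random.default_rng(seed)
    excl_by_chrom: dict[str, list[Interval]] = {}
    for iv in exclusion or []:
        excl_by_chrom.setdefault(iv.chrom, []).append(iv)
    draws: list[list[Interval]] = []
    for _ in range(n_draws):
        regions: list[Interval] = []
        for site in sites:
            clen = layout[site.chrom]
            span = site.length
            if span > clen:
                raise ValueError(
                    f"site of length {span} cannot be placed on {site.chrom} "
                    f"(length {clen})"
                )
            excl = excl_by_chrom.get(site.chrom, [])
            placed = None
            for _try in range(max_tries):
                start = int(rng.integers(0, clen - span + 1))
                cand = Interval(site.chrom, start, start + span)
                if not any(cand.overlaps(e) for e in excl):
                    placed = cand
                    break
            if placed is None:
                raise ValueError(
                    f"could not place a background region of length {span} on "
                    f"{site.chrom} outside the exclusion set after {max_tries} tries"
                )
            regions.append(placed)
        draws.append(regions)
    return draws


def overlap_enrichment(
    sites: Sequence[Interval],
    domains: Sequence[Interval],
    layout: GenomeLayout,
    seed: int,
    n_draws: int = 1,
    exclusion: Sequence[Interval] | None = None,
) -> EnrichmentResult:
    """Overlap of sites with domains vs a length-matched random background.

    k_observed counts sites sharing >= 1 bp with the merged domain set;
    k_background is the mean (rounded) over ``n_draws`` background sets.
    The 2x2 table [[k_obs, n-k_obs], [k_bg, n-k_bg]] is tested two-sided
    with Fisher's exact test; the odds ratio uses a 0.5 continuity
    substitution on zero cells.
    """
    n = len(sites)
    if n == 0:
        raise ValueError("overlap_enrichment requires at least one site")
    if not is_merged(domains):
        raise ValueError("domain set must be merged (non-overlapping) first")
    k_obs = int(intersect_any(sites, domains).sum())
    bg_sets = random_background(sites, layout, seed, n_draws=n_draws, exclusion=exclusion)
    k_bg = int(round(float(np.mean([intersect_any(bg, domains).sum() for bg in bg_sets]))))
    table = np.array([[k_obs, n - k_obs], [k_bg, n - k_bg]], dtype=np.int64)
    p = fisher_two_sided(table)
    a, b, c, d = (float(x) for x in table.ravel())
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return EnrichmentResult(
        n_sites=n,
        k_observed=k_obs,
        k_background=k_bg,
        n_background=n,
        odds_ratio=float(odds),
        fisher_p=float(p),
        seed=seed,
        n_draws=n_draws,
    )
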