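"""Ground-truth generator for two-condition lamina/pioneer-factor ChIP-seq.

The generator emulates the statistical structure of an aging-liver style
experiment on a desk-scale genome (default 2 x 20 Mb): condition A
("young") and condition B ("old") share a set of lamina-associated domains
(LADs); some LADs are exclusive to each condition (B has lost the A-only
ones); heterochromatin (H3K9me3-like) domains nest inside LADs; pioneer
transcription-factor sites gained in B concentrate where lamina contact
was lost; a flat input library provides the null; and an expression table
couples fold changes to genes near gained sites. Tags are sampled from a
homogeneous Poisson background with multiplicative enrichment inside the
relevant truth domains — no sequence, G/C, or mappability structure.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenomeLayout, Interval, merge_intervals
from .genes import TssTable, ExpressionTable, assign_nearest_gene
from .tags import TagLibrary

__all__ = ["SimConfig", "TruthSet", "simulate_experiment", "write_fixture"]

LIBRARY_NAMES = ("lamin_A", "lamin_B", "h3k9me3_A", "h3k9me3_B", "tf_A", "tf_B", "input")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic experiment.

    Defaults give a 40 Mb genome, 3x LAD enrichment over a uniform
    background, 2e5 reads per library, 100 gained TF sites of which 90%
    sit in LADs that condition B has lost entirely (the rest sit in
    retained shared LADs and act as the lamina-retained control class).
    """

    chrom_lengths: tuple[int, ...] = (20_000_000, 20_000_000)
    n_shared_lads: int = 8
    n_A_only: int = 4
    n_B_only: int = 4
    lad_length_range: tuple[int, int] = (200_000, 1_000_000)
    min_domain_gap: int = 50_000
    lad_enrichment_fold: float = 3.0
    het_fraction_of_lad: float = 0.5
    n_tf_sites: int = 100  # gained (condition-B) sites
    n_tf_shared: int = 50  # sites bound in both conditions, outside LADs
    tf_in_lost_lad_fraction: float = 0.9
    tf_enrichment_fold: float = 10.0
    tf_site_width: int = 200
    local_erosion_fold: float = 1.0  # >1 erodes old lamin signal at retained gained sites
    local_erosion_span: int = 10_000
    reads_per_library: int = 200_000
    read_length: int = 75
    fragment_length: int = 150
    n_genes: int = 200
    p_up: float = 0.8  # P(fold change > 2) for genes nearest a gained site
    p_down_background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.chrom_lengths) < 1:
            raise ValueError("chromosome lengths must be positive")
        for name in ("n_shared_lads", "n_A_only", "n_B_only", "n_tf_sites", "n_tf_shared"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lad_enrichment_fold <= 1 or self.tf_enrichment_fold <= 1:
            raise ValueError("enrichment folds must exceed 1")
        if not 0 <= self.tf_in_lost_lad_fraction <= 1:
            raise ValueError("tf_in_lost_lad_fraction must be in [0, 1]")
        if self.lad_length_range[0] > self.lad_length_range[1]:
            raise ValueError("lad_length_range must be (lo, hi) with lo <= hi")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout(
            {f"chr{i + 1}": int(n) for i, n in enumerate(self.chrom_lengths)}
        )


@dataclass
class TruthSet:
    """Everything the generator knows, for oracle comparisons downstream."""

    config: SimConfig
    lads_A: list[Interval]
    lads_B: list[Interval]
    het_A: list[Interval]
    het_B: list[Interval]
    tf_shared: list[Interval]
    tf_gained: list[Interval]
    lost_lamina: np.ndarray  # per gained site: inside a LAD lost in B
    tss_table: TssTable
    expression: ExpressionTable

    @property
    def tf_sites_A(self) -> list[Interval]:
        return list(self.tf_shared)

    @property
    def tf_sites_B(self) -> list[Interval]:
        return self.tf_shared + self.tf_gained

    @property
    def expected_fraction_higher_young(self) -> float:
        """Analytic expectation of the fraction of gained sites whose young
        lamin window sum is strictly higher: lamina-lost sites are higher
        essentially always, lamina-retained sites half the time."""
        n = len(self.tf_gained)
        if n == 0:
            return 0.0
        n_lost = int(self.lost_lamina.sum())
        return (n_lost + 0.5 * (n - n_lost)) / n


def _place_domains(
    rng: np.random.Generator,
    layout: GenomeLayout,
    n: int,
    length_range: tuple[int, int],
    occupied: dict[str, list[tuple[int, int]]],
    min_gap: int,
    max_tries: int = 5000,
) -> list[Interval]:
    """Place n non-overlapping domains, >= min_gap from anything occupied."""
    chroms = layout.chroms
    lens = np.array([layout[c] for c in chroms], dtype=np.float64)
    placed: list[Interval] = []
    for _ in range(n):
        ok = None
        for _try in range(max_tries):
            ci = int(rng.choice(len(chroms), p=lens / lens.sum()))
            chrom = chroms[ci]
            span = int(rng.integers(length_range[0], length_range[1] + 1))
            if span >= layout[chrom]:
                continue
            start = int(rng.integers(0, layout[chrom] - span + 1))
            end = start + span
            clash = any(
                start - min_gap < e and s < end + min_gap
                for s, e in occupied.get(chrom, [])
            )
            if not clash:
                ok = Interval(chrom, start, end)
                break
        if ok is None:
            raise ValueError(
                f"could not place domain {len(placed) + 1}/{n} without overlap; "
                "genome too crowded for the requested configuration"
            )
        occupied.setdefault(ok.chrom, []).append((ok.start, ok.end))
        placed.append(ok)
    order = layout.chrom_order()
    placed.sort(key=lambda iv: (order[iv.chrom], iv.start))
    return placed


def _sample_tags(
    rng: np.random.Generator,
    layout: GenomeLayout,
    n_reads: int,
    read_length: int,
    segments: list[tuple[str, int, int, float]],
) -> pd.DataFrame:
    """Sample tag records from piecewise-constant rates (chrom, s, e, mult)."""
    if n_reads == 0 or not segments:
        return pd.DataFrame({"chrom": [], "start": [], "end": [], "strand": []})
    seg_chrom = np.array([s[0] for s in segments], dtype=object)
    seg_start = np.array([s[1] for s in segments], dtype=np.int64)
    seg_len = np.array([s[2] - s[1] for s in segments], dtype=np.float64)
    weights = seg_len * np.array([s[3] for s in segments], dtype=np.float64)
    idx = rng.choice(len(segments), size=n_reads, p=weights / weights.sum())
    offs = np.floor(rng.random(n_reads) * seg_len[idx]).astype(np.int64)
    start = seg_start[idx] + offs
    chrom = seg_chrom[idx]
    clen = np.array([layout[c] for c in chrom], dtype=np.int64)
    end = np.minimum(start + read_length, clen)
    strand = np.where(rng.random(n_reads) < 0.5, "+", "-")
    return pd.DataFrame({"chrom": chrom, "start": start, "end": end, "strand": strand})


def _genome_segments(
    layout: GenomeLayout,
    enriched: Sequence[Interval],
    fold: float,
    carve: Sequence[tuple[Interval, float]] = (),
) -> list[tuple[str, int, int, float]]:
    """Partition the genome into constant-rate segments: background 1x,
    ``enriched`` at ``fold``, with optional (interval, mult) carve-outs
    overriding the enriched rate."""
    marks: dict[str, list[tuple[int, int, float]]] = {c: [] for c in layout}
    for iv in enriched:
        marks[iv.chrom].append((iv.start, iv.end, fold))
    for iv, mult in carve:
        marks[iv.chrom].append((iv.start, iv.end, mult))
    segments: list[tuple[str, int, int, float]] = []
    for chrom in layout:
        clen = layout[chrom]
        # later marks override earlier ones (carve-outs override domains)
        cuts = sorted({0, clen} | {x for s, e, _ in marks[chrom] for x in (s, e)})
        for s, e in zip(cuts, cuts[1:]):
            mult = 1.0
            for ms, me, m in marks[chrom]:
                if ms <= s and e <= me:
                    mult = m
            if e > s:
                segments.append((chrom, s, e, mult))
    return segments


def _sample_tf_library(
    rng: np.random.Generator,
    config: SimConfig,
    layout: GenomeLayout,
    sites: Sequence[Interval],
) -> pd.DataFrame:
    """Uniform background plus point sources at site centers.

    The expected extra read mass at each site equals the multiplicative
    rate model (site_width x (fold - 1) background-equivalents); the extra
    reads are laid down as fragments jittered around the site center so
    extended coverage piles where a real binding event would.
    """
    n_total = int(rng.poisson(config.reads_per_library))
    extra_mass = len(sites) * config.tf_site_width * (config.tf_enrichment_fold - 1.0)
    p_site = extra_mass / (layout.total_length + extra_mass) if sites else 0.0
    n_site = int(rng.binomial(n_total, p_site)) if p_site > 0 else 0
    n_bg = n_total - n_site
    bg = _sample_tags(
        rng, layout, n_bg, config.read_length,
        [(c, 0, layout[c], 1.0) for c in layout],
    )
    if n_site == 0:
        return bg
    site_idx = rng.integers(0, len(sites), size=n_site)
    centers = np.array([sites[i].midpoint for i in site_idx], dtype=np.int64)
    jitter = rng.normal(0.0, config.fragment_length / 2.0, size=n_site).astype(np.int64)
    frag_center = centers + jitter
    strand = np.where(rng.random(n_site) < 0.5, "+", "-")
    L = config.fragment_length
    frag_start = frag_center - L // 2
    frag_end = frag_start + L
    start = np.where(strand == "+", frag_start, frag_end - config.read_length)
    clen = np.array([layout[sites[i].chrom] for i in site_idx], dtype=np.int64)
    start = np.clip(start, 0, clen - 1)
    end = np.minimum(start + config.read_length, clen)
    site_tags = pd.DataFrame(
        {
            "chrom": np.array([sites[i].chrom for i in site_idx], dtype=object),
            "start": start,
            "end": end,
            "strand": strand,
        }
    )
    out = pd.concat([bg, site_tags], ignore_index=True)
    return out


def simulate_experiment(config: SimConfig) -> tuple[TruthSet, dict[str, TagLibrary]]:
    """Generate the full truth set and the seven tag libraries.

    Deterministic per ``config.seed``: the same config yields bit-identical
    truth and tags. Libraries: lamin_A/lamin_B (LAD enrichment), h3k9me3_A/
    h3k9me3_B (nested heterochromatin), tf_A/tf_B (point sources; B carries
    the gained sites), and a flat input.
    """
    layout = config.layout
    root = np.random.SeedSequence(config.seed)
    keys = (
        "placement", "tf_placement", "genes", "expression",
        "lamin_A", "lamin_B", "h3k9me3_A", "h3k9me3_B", "tf_A", "tf_B", "input",
    )
    rngs = {k: np.random.default_rng(s) for k, s in zip(keys, root.spawn(len(keys)))}

    # --- domain truth -----------------------------------------------------
    rng = rngs["placement"]
    occupied: dict[str, list[tuple[int, int]]] = {}
    shared = _place_domains(
        rng, layout, config.n_shared_lads, config.lad_length_range, occupied,
        config.min_domain_gap,
    )
    a_only = _place_domains(
        rng, layout, config.n_A_only, config.lad_length_range, occupied,
        config.min_domain_gap,
    )
    b_only = _place_domains(
        rng, layout, config.n_B_only, config.lad_length_range, occupied,
        config.min_domain_gap,
    )
    order = layout.chrom_order()
    key = lambda iv: (order[iv.chrom], iv.start)
    lads_A = sorted(shared + a_only, key=key)
    lads_B = sorted(shared + b_only, key=key)

    def nested_het(lads: list[Interval]) -> list[Interval]:
        out = []
        for lad in lads:
            span = int(lad.length * config.het_fraction_of_lad)
            if span >= 1:
                mid = lad.midpoint
                out.append(Interval(lad.chrom, mid - span // 2, mid - span // 2 + span))
        return out

    het_A = nested_het(lads_A)
    het_B = nested_het(lads_B)

    # --- TF site truth ----------------------------------------------------
    rng = rngs["tf_placement"]
    n_lost = int(round(config.n_tf_sites * config.tf_in_lost_lad_fraction))
    n_retained = config.n_tf_sites - n_lost

    def place_sites_in(domains: list[Interval], n: int, margin: int) -> list[Interval]:
        if n > 0 and not domains:
            raise ValueError("no host domains available for TF site placement")
        sites = []
        for _ in range(n):
            lad = domains[int(rng.integers(0, len(domains)))]
            lo = lad.start + margin
            hi = lad.end - margin - config.tf_site_width
            if hi <= lo:
                lo, hi = lad.start, max(lad.start + 1, lad.end - config.tf_site_width)
            s = int(rng.integers(lo, hi + 1))
            sites.append(Interval(lad.chrom, s, s + config.tf_site_width))
        return sites

    # keep the comparison window inside the host domain
    margin = max(config.local_erosion_span, 10_000) // 2
    lost_sites = place_sites_in(a_only, n_lost, margin) if n_lost else []
    retained_sites = place_sites_in(shared, n_retained, margin) if n_retained else []
    tf_gained = lost_sites + retained_sites
    lost_flags = np.array([True] * len(lost_sites) + [False] * len(retained_sites))

    # shared TF sites live outside LADs (open chromatin)
    all_lads = merge_intervals(lads_A + lads_B, layout=layout)
    tf_shared: list[Interval] = []
    for _ in range(config.n_tf_shared):
        for _try in range(1000):
            ci = int(rng.integers(0, len(layout.chroms)))
            chrom = layout.chroms[ci]
            s = int(rng.integers(0, layout[chrom] - config.tf_site_width))
            cand = Interval(chrom, s, s + config.tf_site_width)
            if not any(cand.overlaps(l) for l in all_lads):
                tf_shared.append(cand)
                break
        else:
            raise ValueError("could not place a shared TF site outside LADs")

    # --- genes and expression --------------------------------------------
    rng = rngs["genes"]
    rows = []
    for i in range(config.n_genes):
        chrom = layout.chroms[int(rng.integers(0, len(layout.chroms)))]
        rows.append(
            (f"gene_{i + 1:04d}", chrom, int(rng.integers(0, layout[chrom])),
             "+" if rng.random() < 0.5 else "-")
        )
    tss = TssTable(pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"]))

    rng = rngs["expression"]
    target_genes = set(assign_nearest_gene(tf_gained, tss).values()) if tf_gained else set()
    fc = {}
    for gene in tss.frame["gene_id"]:
        if gene in target_genes and rng.random() < config.p_up:
            fc[gene] = float(rng.uniform(2.5, 6.0))
        elif rng.random() < config.p_down_background:
            fc[gene] = float(-rng.uniform(2.5, 6.0))
        else:
            mag = float(rng.uniform(1.05, 1.9))
            fc[gene] = mag if rng.random() < 0.5 else -mag
    expression = ExpressionTable(
        pd.DataFrame({"gene_id": list(fc), "fold_change": list(fc.values())})
    )

    truth = TruthSet(
        config=config,
        lads_A=lads_A,
        lads_B=lads_B,
        het_A=het_A,
        het_B=het_B,
        tf_shared=tf_shared,
        tf_gained=tf_gained,
        lost_lamina=lost_flags,
        tss_table=tss,
        expression=expression,
    )

    # --- tag libraries ----------------------------------------------------
    fold = config.lad_enrichment_fold
    carve_B: list[tuple[Interval, float]] = []
    if config.local_erosion_fold > 1.0:
        half = config.local_erosion_span // 2
        for site, lost in zip(tf_gained, lost_flags):
            if not lost:
                mid = site.midpoint
                carve_B.append(
                    (Interval(site.chrom, mid - half, mid - half + config.local_erosion_span),
                     max(1.0, fold / config.local_erosion_fold))
                )

    def domain_library(rkey: str, domains: list[Interval], carve=()) -> TagLibrary:
        rng = rngs[rkey]
        n = int(rng.poisson(config.reads_per_library))
        frame = _sample_tags(
            rng, layout, n, config.read_length,
            _genome_segments(layout, domains, fold, carve),
        )
        return TagLibrary(frame, layout, rkey)

    libraries = {
        "lamin_A": domain_library("lamin_A", lads_A),
        "lamin_B": domain_library("lamin_B", lads_B, carve_B),
        "h3k9me3_A": domain_library("h3k9me3_A", het_A),
        "h3k9me3_B": domain_library("h3k9me3_B", het_B),
        "tf_A": TagLibrary(
            _sample_tf_library(rngs["tf_A"], config, layout, truth.tf_sites_A),
            layout, "tf_A",
        ),
        "tf_B": TagLibrary(
            _sample_tf_library(rngs["tf_B"], config, layout, truth.tf_sites_B),
            layout, "tf_B",
        ),
        "input": domain_library("input", []),
    }
    return truth, libraries


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture(
    truth: TruthSet, libraries: dict[str, TagLibrary], directory: str | Path
) -> dict:
    """Write the fixture as plain-text files and return the manifest.

    Layout: ``tags/<name>.bed`` (BED6 tag libraries), ``truth/*.bed``,
    ``chrom.sizes``, ``tss.tsv``, ``expression.tsv``, ``manifest.json``
    (config, seed, per-file sha256).
    """
    directory = Path(directory)
    (directory / "tags").mkdir(parents=True, exist_ok=True)
    (directory / "truth").mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    layout = truth.config.layout
    sizes = directory / "chrom.sizes"
    sizes.write_text("".join(f"{c}\t{layout[c]}\n" for c in layout))
    files["chrom.sizes"] = _sha256(sizes)

    for name, lib in libraries.items():
        p = directory / "tags" / f"{name}.bed"
        lib.write_bed(p)
        files[f"tags/{name}.bed"] = _sha256(p)

    truth_beds = {
        "lads_A": truth.lads_A,
        "lads_B": truth.lads_B,
        "het_A": truth.het_A,
        "het_B": truth.het_B,
        "tf_shared": truth.tf_shared,
        "tf_gained": truth.tf_gained,
    }
    for name, regions in truth_beds.items():
        p = directory / "truth" / f"{name}.bed"
        with open(p, "w") as fh:
            for i, iv in enumerate(regions):
                flag = ""
                if name == "tf_gained":
                    flag = "lost_lamina" if truth.lost_lamina[i] else "retained_lamina"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{flag or name}_{i + 1}\t0\t.\n")
        files[f"truth/{name}.bed"] = _sha256(p)

    tss_p = directory / "tss.tsv"
    truth.tss_table.to_tsv(tss_p)
    files["tss.tsv"] = _sha256(tss_p)
    expr_p = directory / "expression.tsv"
    truth.expression.to_tsv(expr_p)
    files["expression.tsv"] = _sha256(expr_p)

    manifest = {
        "config": asdict(truth.config),
        "seed": truth.config.seed,
        "files": files,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
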