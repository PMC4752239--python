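"""Motif clustering in non-coding DNA — the replication-origin signature.

Bacterial and archaeal origins of replication carry dense clusters of
methyltransferase target motifs (e.g. GATC at the E. coli oriC).  For every
non-coding region (the complement of CDS and RNA annotations) we compare the
observed motif count with a binomial expectation under the locally estimated
motif density (pooled over the 100 flanking non-coding regions) and flag
regions whose Bonferroni-corrected upper-tail p-value falls below 1e-5.
Density profiles (motif counts in 500 bp windows, 50 bp step, over a 50 kb
span) visualise and compare the signature across genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import binom

from .io_formats import GeneAnnotation, GenomeRecord, PipelineConfig
from .motifs import MotifInstance
from .regulatory import Region, RegionSet


@dataclass
class NoncodingRegionStat:
    region: Region
    observed: int
    local_density: float
    expected: float
    fold: float
    p_raw: float
    p_bonferroni: float
    significant: bool
    n_flanking_used: int = 0


@dataclass
class DensityProfile:
    anchor: int
    window_bp: int
    step_bp: int
    span_bp: int
    window_starts: np.ndarray
    densities: np.ndarray  # motif count per window


def extract_noncoding_regions(genes: list[GeneAnnotation],
                              genome: GenomeRecord) -> RegionSet:
    """Complement of the union of CDS and RNA intervals over the contig."""
    intervals = sorted(
        (g.start0, g.end0) for g in genes
        if g.contig_id == genome.contig_id and g.feature_type in ("CDS", "RNA")
    )
    merged: list[list[int]] = []
    for lo, hi in intervals:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    out = RegionSet()
    prev = 0
    idx = 0
    for lo, hi in merged:
        if lo > prev:
            out.add(Region(genome.contig_id, prev, lo, label=f"nc{idx}"))
            idx += 1
        prev = max(prev, hi)
    if prev < genome.length:
        out.add(Region(genome.contig_id, prev, genome.length, label=f"nc{idx}"))
    return out


def _region_instance_counts(regions: list[Region],
                            instances: list[MotifInstance]) -> np.ndarray:
    """Instances whose footprint overlaps each region (sorted regions)."""
    starts = np.array([i.start for i in instances], dtype=np.int64)
    ends = np.array([i.end for i in instances], dtype=np.int64)
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    counts = np.zeros(len(regions), dtype=np.int64)
    for j, r in enumerate(regions):
        # overlap iff instance.start < r.end and instance.end > r.start;
        # footprints share a fixed length so both bounds follow from starts.
        lo = np.searchsorted(ends, r.start, side="right")  # first with end > r.start
        hi = np.searchsorted(starts, r.end, side="left")  # first with start >= r.end
        counts[j] = max(0, hi - lo)
    return counts


def local_motif_density(region_index: int, noncoding: RegionSet,
                        instances: list[MotifInstance],
                        cfg: PipelineConfig | None = None):
    """Motifs per bp over the flanking non-coding regions (focal excluded).

    Up to ``flank_regions`` regions are pooled, half from each side in region
    order; when one side runs short, whatever exists is used.
    Returns (density, n_flanking_used).
    """
    cfg = cfg or PipelineConfig()
    regions = sorted(noncoding, key=lambda r: r.start)
    counts = _region_instance_counts(regions, instances) if instances else \
        np.zeros(len(regions), dtype=np.int64)
    return _local_density_from_counts(region_index, regions, counts, cfg)


def _local_density_from_counts(region_index: int, regions: list[Region],
                               counts: np.ndarray, cfg: PipelineConfig):
    half = cfg.flank_regions // 2
    left = list(range(max(0, region_index - half), region_index))
    right = list(range(region_index + 1, min(len(regions), region_index + 1 + half)))
    flanking = left + right
    if not flanking:
        raise ValueError("no flanking non-coding regions")
    total_len = sum(regions[j].length for j in flanking)
    if total_len == 0:
        raise ValueError("zero total flanking length")
    total_motifs = int(counts[list(flanking)].sum())
    return total_motifs / total_len, len(flanking)


def noncoding_enrichment_scan(noncoding: RegionSet,
                              instances: list[MotifInstance],
                              cfg: PipelineConfig | None = None) -> list[NoncodingRegionStat]:
    """Binomial upper-tail test of motif count per non-coding region.

    p_raw = P(X >= observed) with X ~ Binomial(region length, local density);
    Bonferroni correction by the number of non-coding regions tested;
    significant when corrected p < ``noncoding_alpha``.
    """
    cfg = cfg or PipelineConfig()
    regions = sorted(noncoding, key=lambda r: r.start)
    if not regions:
        return []
    counts = _region_instance_counts(regions, instances) if instances else \
        np.zeros(len(regions), dtype=np.int64)
    n_regions = len(regions)
    out = []
    for j, r in enumerate(regions):
        observed = int(counts[j])
        assert observed <= r.length, "more motif footprints than bases"
        try:
            density, n_flank = _local_density_from_counts(j, regions, counts, cfg)
        except ValueError:
            continue
        p_success = min(density, 1.0)
        expected = r.length * density
        fold = observed / expected if expected > 0 else float("nan")
        if cfg.noncoding_strict_tail:
            p_raw = float(binom.sf(observed, r.length, p_success))
        else:
            p_raw = float(binom.sf(observed - 1, r.length, p_success))
        p_bonf = min(1.0, p_raw * n_regions)
        out.append(
            NoncodingRegionStat(
                region=r, observed=observed, local_density=density,
                expected=expected, fold=fold, p_raw=p_raw,
                p_bonferroni=p_bonf,
                significant=p_bonf < cfg.noncoding_alpha,
                n_flanking_used=n_flank,
            )
        )
    return out


def density_profile(genome: GenomeRecord, instances: list[MotifInstance],
                    anchor: int, cfg: PipelineConfig | None = None) -> DensityProfile:
    """Motif counts in sliding windows across a span centred on the anchor.

    Windows are anchored at the span start; at the default 500 bp window,
    50 bp step and 50 kb span an unclipped profile has 991 windows.
    Instances are counted by footprint overlap.
    """
    cfg = cfg or PipelineConfig()
    span_lo = max(0, anchor - cfg.span_bp // 2)
    span_hi = min(genome.length, anchor + cfg.span_bp - cfg.span_bp // 2)
    span = span_hi - span_lo
    n_windows = max(0, (span - cfg.window_bp) // cfg.step_bp + 1)
    window_starts = span_lo + cfg.step_bp * np.arange(n_windows, dtype=np.int64)
    starts = np.sort(np.array([i.start for i in instances], dtype=np.int64)) \
        if instances else np.empty(0, dtype=np.int64)
    ends = np.sort(np.array([i.end for i in instances], dtype=np.int64)) \
        if instances else np.empty(0, dtype=np.int64)
    counts = np.zeros(n_windows, dtype=np.int64)
    for j, w in enumerate(window_starts):
        lo = np.searchsorted(ends, w, side="right")
        hi = np.searchsorted(starts, w + cfg.window_bp, side="left")
        counts[j] = max(0, hi - lo)
    return DensityProfile(anchor, cfg.window_bp, cfg.step_bp, cfg.span_bp,
                          window_starts, counts)


def match_clusters_across_genomes(stats_a: list[NoncodingRegionStat],
                                  stats_b: list[NoncodingRegionStat],
                                  flanks_a: dict[str, tuple[Optional[str], Optional[str]]],
                                  flanks_b: dict[str, tuple[Optional[str], Optional[str]]],
                                  rbh: dict[str, str]) -> list[tuple[NoncodingRegionStat, NoncodingRegionStat]]:
    """Pair significant non-coding clusters across two genomes.

    ``flanks_*`` map region labels to (left gene, right gene); a pair is
    conserved when both flanking genes are reciprocal best hits, trying the
    strand-flipped order too.
    """
    sig_a = [s for s in stats_a if s.significant]
    sig_b = {s.region.label: s for s in stats_b if s.significant}
    out = []
    for sa in sig_a:
        fa = flanks_a.get(sa.region.label)
        if fa is None:
            continue
        la, ra = fa
        mapped = (rbh.get(la) if la else None, rbh.get(ra) if ra else None)
        for label_b, sb in sig_b.items():
            fb = flanks_b.get(label_b)
            if fb is None:
                continue
            if mapped == fb or mapped == (fb[1], fb[0]):
                if mapped != (None, None):
                    out.append((sa, sb))
                    break
    return out
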