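"""Gene regulatory regions and enrichment statistics for (un)methylated motifs.

A regulatory region spans 100 bp upstream to 50 bp downstream of a CDS start
(strand-aware, clipped at contig edges).  Three enrichment questions are
answered here:

* are motif instances, irrespective of state, enriched in regulatory regions
  relative to composition-matched random placements (1000 samplings)?
* are *unmethylated* instances enriched relative to methylated ones?
* do unmethylated instances overlap transcription-factor binding sites more
  often than methylated ones?

Folds compare observed to background fractions; significance comes from
Fisher's exact test (two-sided) on the corresponding 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact

from .calling import MethylationCall
from .io_formats import GeneAnnotation, GenomeRecord, PipelineConfig
from .motifs import MotifInstance


@dataclass(frozen=True)
class Region:
    contig_id: str
    start: int  # 0-based half-open
    end: int
    strand: str = "."
    linked_gene_id: Optional[str] = None
    label: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start


class RegionSet:
    """Strand-aware genomic intervals with overlap and membership queries."""

    def __init__(self, regions: Iterable[Region] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._regions: list[Region] = []
        for r in regions:
            self.add(r)

    def add(self, region: Region) -> None:
        if region.start >= region.end:
            raise ValueError(f"empty interval [{region.start}, {region.end})")
        self._regions.append(region)
        self._trees.setdefault(region.contig_id, IntervalTree()).addi(
            region.start, region.end, region
        )

    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self):
        return iter(self._regions)

    def overlaps(self, contig_id: str, start: int, end: int) -> bool:
        tree = self._trees.get(contig_id)
        return bool(tree.overlap(start, end)) if tree is not None else False

    def overlapping(self, contig_id: str, start: int, end: int) -> list[Region]:
        tree = self._trees.get(contig_id)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def contains_point(self, contig_id: str, pos: int) -> bool:
        return self.overlaps(contig_id, pos, pos + 1)

    def subset(self, predicate) -> "RegionSet":
        return RegionSet(r for r in self._regions if predicate(r))

    def total_length(self) -> int:
        return sum(r.length for r in self._regions)


@dataclass(frozen=True)
class EnrichmentResult:
    n_in: int
    n_total: int
    observed_fraction: float
    background_fraction: float
    fold: float  # NaN when the background fraction is zero
    p_value: float
    method: str  # 'resampling' or 'fisher'
    n_resamplings: int = 0
    seed: Optional[int] = None
    label: Optional[str] = None

    @property
    def fold_defined(self) -> bool:
        return np.isfinite(self.fold)


def define_regulatory_regions(genes: list[GeneAnnotation],
                              genomes: list[GenomeRecord],
                              cfg: PipelineConfig | None = None) -> RegionSet:
    """One interval per CDS around its start codon, clipped to contig bounds.

    Forward-strand CDS with 0-based start s: [s - upstream, s + downstream);
    reverse-strand CDS with 0-based exclusive end e: [e - downstream, e + upstream).
    """
    cfg = cfg or PipelineConfig()
    lengths = {g.contig_id: g.length for g in genomes}
    out = RegionSet()
    for gene in genes:
        if gene.feature_type != "CDS":
            continue
        limit = lengths.get(gene.contig_id)
        if limit is None:
            continue
        if gene.strand == "+":
            lo = gene.start0 - cfg.upstream_bp
            hi = gene.start0 + cfg.downstream_bp
        else:
            lo = gene.end0 - cfg.downstream_bp
            hi = gene.end0 + cfg.upstream_bp
        lo, hi = max(0, lo), min(limit, hi)
        if lo < hi:
            out.add(Region(gene.contig_id, lo, hi, gene.strand,
                           linked_gene_id=gene.gene_id,
                           label=gene.cog_letter))
    return out


# ---------------------------------------------------------------------------
# Composition-matched resampling


def _window_compositions(sequence: str, length: int) -> np.ndarray:
    """(n_windows, 5) base counts (A, C, G, T, N) per window of `length`."""
    codes = np.frombuffer(sequence.encode(), dtype="S1")
    onehot = np.zeros((len(sequence), 5), dtype=np.int32)
    for j, b in enumerate((b"A", b"C", b"G", b"T", b"N")):
        onehot[:, j] = codes == b
    cum = np.vstack([np.zeros((1, 5), dtype=np.int64), np.cumsum(onehot, axis=0)])
    return cum[length:] - cum[:-length]


def composition_key(seq: str) -> tuple[int, int, int, int]:
    return (seq.count("A"), seq.count("C"), seq.count("G"), seq.count("T"))


def sample_composition_matched_sites(genome: GenomeRecord,
                                     instance_sequences: list[str],
                                     n_sets: int = 1000,
                                     seed: int | None = None,
                                     rng: np.random.Generator | None = None):
    """Yield `n_sets` random position sets matching each instance's base content.

    Each yielded array holds one genome start position per real instance,
    drawn uniformly from the windows whose base multiset equals that
    instance's; windows containing N are never candidates.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lengths = {len(s) for s in instance_sequences}
    comp_by_len = {L: _window_compositions(genome.sequence, L) for L in lengths}
    candidates: dict[tuple, np.ndarray] = {}
    keys = []
    for s in instance_sequences:
        key = (len(s),) + composition_key(s)
        keys.append(key)
        if key not in candidates:
            comps = comp_by_len[len(s)]
            want = np.array(key[1:] + (0,), dtype=comps.dtype)  # no N allowed
            cand = np.nonzero((comps == want).all(axis=1))[0]
            if cand.size == 0:
                raise ValueError(
                    f"no genome window matches composition {key[1:]} at length {len(s)}"
                )
            candidates[key] = cand
    for _ in range(n_sets):
        yield np.array([candidates[k][rng.integers(candidates[k].size)] for k in keys],
                       dtype=np.int64)


def _start_overlap_mask(contig: str, genome_length: int, window: int,
                        regions: RegionSet) -> np.ndarray:
    """mask[s] is True iff a window of `window` bp starting at s overlaps a region."""
    mask = np.zeros(genome_length, dtype=bool)
    for r in regions:
        if r.contig_id != contig:
            continue
        lo = max(0, r.start - window + 1)
        hi = min(genome_length, r.end)
        mask[lo:hi] = True
    return mask


def fisher_from_counts(in_a: int, out_a: int, in_b: int, out_b: int) -> float:
    """Two-sided Fisher's exact p for a 2x2 (in/out x group) table."""
    return float(fisher_exact([[in_a, out_a], [in_b, out_b]],
                              alternative="two-sided")[1])


def motif_region_enrichment(instances: list[MotifInstance], regions: RegionSet,
                            genome: GenomeRecord,
                            cfg: PipelineConfig | None = None,
                            seed: int | None = None) -> EnrichmentResult:
    """Enrichment of all motif instances in regulatory regions.

    Background: mean in-region fraction over composition-matched random
    placements; Fisher control row pools every sampled placement.
    """
    cfg = cfg or PipelineConfig()
    if not instances:
        raise ValueError("no instances")
    contig = genome.contig_id
    n_total = len(instances)
    n_in = sum(regions.overlaps(contig, i.start, i.end) for i in instances)
    observed = n_in / n_total

    seqs = [genome.sequence[i.start: i.end] for i in instances]
    L = len(seqs[0])
    mask = _start_overlap_mask(contig, genome.length, L, regions)
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    fracs = []
    pooled_in = pooled_out = 0
    for starts in sample_composition_matched_sites(
            genome, seqs, n_sets=cfg.n_resamplings, rng=rng):
        hits = int(mask[starts].sum())
        fracs.append(hits / n_total)
        pooled_in += hits
        pooled_out += n_total - hits
    background = float(np.mean(fracs))
    fold = observed / background if background > 0 else float("nan")
    p = fisher_from_counts(n_in, n_total - n_in, pooled_in, pooled_out)
    return EnrichmentResult(n_in, n_total, observed, background, fold, p,
                            method="resampling",
                            n_resamplings=cfg.n_resamplings, seed=seed)


def unmethylated_region_enrichment(calls: list[MethylationCall],
                                   regions: RegionSet,
                                   label: str | None = None) -> EnrichmentResult:
    """Enrichment of unmethylated over methylated instances in regions."""
    unmeth = [c for c in calls if c.state == "unmethylated"]
    meth = [c for c in calls if c.state == "methylated"]
    if not meth:
        raise ValueError("no methylated calls to form the background")
    if not unmeth:
        raise ValueError("no unmethylated calls")

    def frac(group):
        n_in = sum(
            regions.overlaps(c.instance.contig_id, c.instance.start, c.instance.end)
            for c in group
        )
        return n_in, len(group)

    u_in, u_n = frac(unmeth)
    m_in, m_n = frac(meth)
    observed = u_in / u_n
    background = m_in / m_n
    fold = observed / background if background > 0 else float("nan")
    p = fisher_from_counts(u_in, u_n - u_in, m_in, m_n - m_in)
    return EnrichmentResult(u_in, u_n, observed, background, fold, p,
                            method="fisher", label=label)


def cog_category_enrichment(calls: list[MethylationCall], regions: RegionSet,
                            alpha: float = 0.01) -> pd.DataFrame:
    """Unmethylated-vs-methylated enrichment per COG functional category.

    Regions must carry the COG letter of their linked gene in ``label``.
    Letters whose region subset yields no testable table are skipped.
    """
    letters = sorted({r.label for r in regions if r.label})
    if not letters:
        raise ValueError("no COG letters on the region set")
    rows = []
    for letter in letters:
        sub = regions.subset(lambda r, L=letter: r.label == L)
        if len(sub) == 0:
            continue
        try:
            res = unmethylated_region_enrichment(calls, sub, label=letter)
        except ValueError:
            continue
        rows.append(
            {"cog_letter": letter, "n_in": res.n_in, "n_total": res.n_total,
             "observed_fraction": res.observed_fraction,
             "background_fraction": res.background_fraction,
             "fold": res.fold, "p_value": res.p_value,
             "significant": res.p_value < alpha and res.observed_fraction > res.background_fraction}
        )
    return pd.DataFrame(rows)


def tfbs_overlap_enrichment(calls: list[MethylationCall],
                            tfbs: RegionSet) -> EnrichmentResult:
    """Do unmethylated instances overlap TF binding sites more than methylated?"""
    if len(tfbs) == 0:
        raise ValueError("empty TFBS set")
    return unmethylated_region_enrichment(calls, tfbs, label="TFBS")
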