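"""Synthetic methylomes with known ground truth.

Every pipeline stage is testable without external data: this module builds a
random genome, a non-overlapping gene annotation, a motif instance set of a
requested size with a planted unmethylated subset (biased toward regulatory
regions, emulating orphan-MTase behaviour), optionally an extra motif cluster
in one intergenic region (the replication-origin signature), and a kinetic
track under an explicit noise model.

Kinetic model.  Coverage per position and strand is Poisson with the same
mean regardless of methylation state, so the coverage-parity diagnostic is a
real test rather than a tautology.  The per-position ipdR is lognormal with
median ``mu_meth`` at truth-methylated methylatable bases and median 1.0
everywhere else; because a position's ipdR is an average over its reads, the
lognormal scale shrinks with coverage as ``sigma / sqrt(coverage)``.
Modification-type presets set the methylated median to 4.0 (m6A), 3.0 (m4C)
and 1.5 (m5C), reflecting the platform's strong m6A/m4C and weak m5C kinetic
signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import (
    GeneAnnotation,
    GenomeRecord,
    KineticTrack,
    PipelineConfig,
    write_fasta,
    write_gff3,
    write_kinetics,
    write_motifs,
)
from .motifs import IUPAC, MotifInstance, MotifSpec, find_motif_instances
from .regulatory import define_regulatory_regions

MOD_TYPE_MU = {"m6A": 4.0, "m4C": 3.0, "m5C": 1.5}

COG_LETTERS = ("K", "T", "H", "E", "J")


@dataclass
class KineticModel:
    mu_meth: float = 4.0
    mu_unmeth: float = 1.0
    sigma: float = 0.25  # per-read lognormal scale
    coverage_mean: float = 60.0

    def __post_init__(self):
        if not self.mu_meth > self.mu_unmeth:
            raise ValueError("mu_meth must exceed mu_unmeth")

    @classmethod
    def for_mod_type(cls, mod_type: str, coverage_mean: float = 60.0) -> "KineticModel":
        return cls(mu_meth=MOD_TYPE_MU[mod_type], coverage_mean=coverage_mean)


@dataclass
class MethylomeScenario:
    """Full description of one synthetic methylome."""

    genome_length: int = 200_000
    gc_fraction: float = 0.5
    n_genes: int = 150
    motif: MotifSpec = field(
        default_factory=lambda: MotifSpec.palindromic("GATC", 1, "m6A"))
    n_instances: int = 500
    n_unmethylated: int = 20
    # fraction of unmethylated sites planted in regulatory regions;
    # None draws the unmethylated subset uniformly (null scenarios)
    f_regulatory: Optional[float] = 0.6
    kinetic_model: KineticModel = field(default_factory=KineticModel)
    ori_cluster_count: int = 0
    ori_cluster_span: int = 600
    cog_target_letter: Optional[str] = None
    seed: int = 0


@dataclass
class ScenarioBundle:
    scenario: MethylomeScenario
    genome: GenomeRecord
    genes: list[GeneAnnotation]
    instances: list[MotifInstance]
    truth: pd.DataFrame  # start, end, meth_pos_fwd, meth_pos_rev, state, in_regulatory
    track: KineticTrack
    ori_region: Optional[tuple[int, int]] = None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta([self.genome], out / "genome.fasta")
        write_gff3(self.genes, out / "annotation.gff3")
        write_kinetics(self.track, out / "kinetics.csv")
        write_motifs([self.scenario.motif], out / "motifs.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        sidecar = asdict(self.scenario)
        sidecar["motif"] = {"pattern": self.scenario.motif.pattern,
                            "meth_offset_fwd": self.scenario.motif.meth_offset_fwd,
                            "mod_type": self.scenario.motif.mod_type}
        sidecar["ori_region"] = list(self.ori_region) if self.ori_region else None
        with open(out / "scenario.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


def generate_genome(length: int, gc_fraction: float,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None,
                    contig_id: str = "synthetic_contig") -> GenomeRecord:
    """I.i.d. random genome at the stated GC content."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0 < gc_fraction < 1):
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    seq = "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))
    return GenomeRecord(contig_id, seq)


def generate_annotation(genome: GenomeRecord, n_genes: int,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None,
                        min_len: int = 300, max_len: int = 1500,
                        reserve_gap: int | None = None) -> list[GeneAnnotation]:
    """Non-overlapping CDS with alternating strands and intergenic gaps.

    COG letters cycle through {K, T, H, E, J}.  With ``reserve_gap`` set, one
    intergenic gap of at least that many bases is guaranteed (used to host a
    planted origin-like motif cluster).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    L = genome.length
    min_gap = 20
    lengths = rng.integers(min_len, max_len + 1, size=n_genes)
    # shrink genes uniformly if the draw cannot fit
    while lengths.sum() + (n_genes + 1) * min_gap + (reserve_gap or 0) > L:
        if lengths.max() <= min_len:
            raise ValueError("cannot pack requested genes into the genome")
        lengths = np.maximum(min_len, lengths - 50)
    # spread the slack over all n_genes+1 gaps so genes cover the whole genome
    slack = L - int(lengths.sum()) - (n_genes + 1) * min_gap - (reserve_gap or 0)
    extra = rng.multinomial(slack, np.full(n_genes + 1, 1 / (n_genes + 1)))
    gaps = min_gap + extra
    if reserve_gap:
        gaps[int(rng.integers(1, n_genes))] += reserve_gap
    genes: list[GeneAnnotation] = []
    pos = int(gaps[0])
    for i in range(n_genes):
        start0, end0 = pos, pos + int(lengths[i])
        genes.append(GeneAnnotation(
            contig_id=genome.contig_id, start=start0 + 1, end=end0,
            strand="+" if i % 2 == 0 else "-", feature_type="CDS",
            gene_id=f"gene{i:04d}", product=f"synthetic protein {i}",
            cog_letter=COG_LETTERS[i % len(COG_LETTERS)],
        ))
        pos = end0 + int(gaps[i + 1])
    assert pos <= L
    return genes


def _concrete_realization(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        sym if len(IUPAC[sym]) == 1 else IUPAC[sym][rng.integers(len(IUPAC[sym]))]
        for sym in pattern
    )


def _break_instance(seq: list[str], inst: MotifInstance, motif: MotifSpec,
                    keep: set[int], rng: np.random.Generator) -> None:
    """Mutate one footprint base so the instance no longer matches."""
    L = len(motif.pattern)
    for off in rng.permutation(L):
        pos = inst.start + int(off)
        if any(k <= pos < k + L for k in keep):
            continue
        sym = motif.pattern[off]
        allowed = set(IUPAC[sym])
        others = [b for b in "ACGT" if b not in allowed]
        if not others:
            # degenerate N position matches everything; try another offset
            continue
        seq[pos] = others[rng.integers(len(others))]
        return
    # fall back: mutate the methylatable base even inside an overlap
    pos = inst.start + motif.meth_offset_fwd
    sym = motif.pattern[motif.meth_offset_fwd]
    others = [b for b in "ACGT" if b not in set(IUPAC[sym])]
    if others:
        seq[pos] = others[rng.integers(len(others))]


def plant_methylome(genome: GenomeRecord, genes: list[GeneAnnotation],
                    motif: MotifSpec, scenario: MethylomeScenario,
                    rng: np.random.Generator | None = None,
                    cfg: PipelineConfig | None = None):
    """Adjust the genome to the requested instance count, choose the
    unmethylated subset, optionally plant an origin-like cluster.

    Returns (edited genome, instances, truth table, ori_region or None).
    The truth table records one row per instance with its state and whether
    it overlaps a regulatory region — before any kinetic noise exists.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    cfg = cfg or PipelineConfig()
    seq = list(genome.sequence)
    L = len(motif.pattern)
    target = scenario.n_instances
    ori_region = None
    ori_positions: list[int] = []

    if scenario.ori_cluster_count:
        gaps = _intergenic_gaps(genes, genome.length)
        wide = [g for g in gaps if g[1] - g[0] >= scenario.ori_cluster_span]
        if not wide:
            raise ValueError("no intergenic gap can host the origin cluster")
        # smallest adequate gap: keeps the hosting non-coding region compact
        lo, hi = min(wide, key=lambda g: g[1] - g[0])
        start = int(rng.integers(lo, hi - scenario.ori_cluster_span + 1))
        ori_region = (start, start + scenario.ori_cluster_span)
        spacing = scenario.ori_cluster_span // scenario.ori_cluster_count
        if spacing < L + 1:
            raise ValueError("origin cluster too dense for the motif length")
        for j in range(scenario.ori_cluster_count):
            pos = start + j * spacing
            word = _concrete_realization(motif.pattern, rng)
            seq[pos: pos + L] = list(word)
            ori_positions.append(pos)

    # converge on the exact instance count, protecting planted ori sites
    protected = set(ori_positions)
    for _ in range(60):
        current = GenomeRecord(genome.contig_id, "".join(seq))
        instances = find_motif_instances(current, motif)
        count = len(instances)
        want = target + len(ori_positions)
        if count == want:
            break
        if count < want:
            existing = {i.start for i in instances}
            need = want - count
            tries = 0
            while need > 0 and tries < 20 * (want - count + 1):
                tries += 1
                pos = int(rng.integers(0, genome.length - L))
                if any(abs(pos - e) < L for e in existing):
                    continue
                word = _concrete_realization(motif.pattern, rng)
                seq[pos: pos + L] = list(word)
                existing.add(pos)
                need -= 1
        else:
            removable = [i for i in instances if i.start not in protected]
            if not removable:
                raise ValueError("only protected instances left to remove")
            surplus = count - want
            for idx in rng.choice(len(removable), size=min(surplus, len(removable)),
                                  replace=False):
                _break_instance(seq, removable[int(idx)], motif,
                                protected, rng)
    else:
        raise ValueError("could not converge on the requested instance count")

    genome = GenomeRecord(genome.contig_id, "".join(seq))
    instances = find_motif_instances(genome, motif)
    if len(instances) != target + len(ori_positions):
        raise ValueError(
            f"instance count {len(instances)} != requested "
            f"{target + len(ori_positions)}")

    regions = define_regulatory_regions(genes, [genome], cfg)
    if scenario.cog_target_letter:
        regions = regions.subset(lambda r: r.label == scenario.cog_target_letter)
    in_reg = np.array([
        regions.overlaps(genome.contig_id, i.start, i.end) for i in instances
    ])
    n_unmeth = scenario.n_unmethylated
    states = np.array(["methylated"] * len(instances), dtype=object)
    if n_unmeth and scenario.f_regulatory is None:
        # no regulatory bias: uniform draw (null scenarios)
        states[rng.choice(len(instances), size=n_unmeth, replace=False)] = "unmethylated"
    elif n_unmeth:
        k_reg = int(round(scenario.f_regulatory * n_unmeth))
        reg_idx = np.nonzero(in_reg)[0]
        out_idx = np.nonzero(~in_reg)[0]
        if len(reg_idx) < k_reg or len(out_idx) < n_unmeth - k_reg:
            raise ValueError("not enough instances to honour the regulatory bias")
        chosen = np.concatenate([
            rng.choice(reg_idx, size=k_reg, replace=False),
            rng.choice(out_idx, size=n_unmeth - k_reg, replace=False),
        ])
        states[chosen] = "unmethylated"

    truth = pd.DataFrame({
        "start": [i.start for i in instances],
        "end": [i.end for i in instances],
        "meth_pos_fwd": [i.meth_pos_fwd for i in instances],
        "meth_pos_rev": [i.meth_pos_rev for i in instances],
        "state": states,
        "in_regulatory": in_reg,
    })
    return genome, instances, truth, ori_region


def _intergenic_gaps(genes: list[GeneAnnotation], length: int):
    spans = sorted((g.start0, g.end0) for g in genes)
    gaps = []
    prev = 0
    for lo, hi in spans:
        if lo > prev:
            gaps.append((prev, lo))
        prev = max(prev, hi)
    if prev < length:
        gaps.append((prev, length))
    return gaps


def simulate_kinetics(genome: GenomeRecord, truth: pd.DataFrame,
                      model: KineticModel,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None) -> KineticTrack:
    """Kinetic track under the lognormal/Poisson model described above."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    L = genome.length
    median_plus = np.full(L, model.mu_unmeth)
    median_minus = np.full(L, model.mu_unmeth)
    meth = truth[truth["state"] == "methylated"]
    median_plus[meth["meth_pos_fwd"].to_numpy(dtype=np.int64)] = model.mu_meth
    median_minus[meth["meth_pos_rev"].to_numpy(dtype=np.int64)] = model.mu_meth
    track = KineticTrack()
    for strand, median in (("+", median_plus), ("-", median_minus)):
        cov = rng.poisson(model.coverage_mean, size=L)
        scale = model.sigma / np.sqrt(np.maximum(cov, 1))
        ipdr = np.exp(np.log(median) + scale * rng.standard_normal(L))
        ipdr[cov == 0] = np.nan
        track.add_dense(genome.contig_id, strand, ipdr, cov)
    return track


PRESETS = ("orphan_regulatory", "rm_system", "ori_cluster", "m5c_low_signal")


def build_scenario(preset: str, seed: int = 0,
                   out_dir=None, **overrides) -> ScenarioBundle:
    """Generate a complete input bundle for a named scenario.

    orphan_regulatory
        500 GATC instances in a 200 kb genome, 20 unmethylated with 60% of
        them in regulatory regions — an orphan MTase leaving regulatory
        targets unprotected.
    rm_system
        Same geometry with zero unmethylated sites: restriction-system
        MTases methylate their genome completely.
    ori_cluster
        Background motif density of one per 500 bp plus 20 extra instances
        packed into one 600 bp intergenic region.
    m5c_low_signal
        The orphan scenario under the weak m5C kinetic preset (CCGG-like
        motif), so calling sensitivity degrades measurably.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    rng = np.random.default_rng(seed)
    base = dict(seed=seed)
    if preset == "orphan_regulatory":
        scen = MethylomeScenario(**{**base, **overrides})
    elif preset == "rm_system":
        scen = MethylomeScenario(**{**base, "n_unmethylated": 0, **overrides})
    elif preset == "ori_cluster":
        length = overrides.get("genome_length", 200_000)
        scen = MethylomeScenario(**{
            **base,
            "n_instances": length // 500,
            "n_unmethylated": 0,
            "ori_cluster_count": 20,
            "ori_cluster_span": 600,
            **overrides,
        })
    else:  # m5c_low_signal
        motif = MotifSpec.palindromic("CCGG", 0, "m5C")
        scen = MethylomeScenario(**{
            **base,
            "motif": motif,
            "kinetic_model": KineticModel.for_mod_type("m5C"),
            **overrides,
        })
    genome = generate_genome(scen.genome_length, scen.gc_fraction, rng=rng)
    genes = generate_annotation(
        genome, scen.n_genes, rng=rng,
        reserve_gap=scen.ori_cluster_span + 80 if scen.ori_cluster_count else None)
    genome, instances, truth, ori_region = plant_methylome(
        genome, genes, scen.motif, scen, rng=rng)
    track = simulate_kinetics(genome, truth, scen.kinetic_model, rng=rng)
    bundle = ScenarioBundle(scen, genome, genes, instances, truth, track,
                            ori_region=ori_region)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
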