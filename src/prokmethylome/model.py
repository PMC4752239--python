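"""The modelling surface: MethylomeModel (data in) and MethylomeResults.

``MethylomeModel`` bundles one contig's genome sequence, gene annotation,
kinetic track and one palindromic recognition motif.  ``fit()`` locates the
motif instances, estimates the ipdR thresholds from the data and classifies
every instance, returning a :class:`MethylomeResults` that carries the call
table, diagnostics and the downstream statistics (regulatory enrichment,
unmethylated-site clusters, the non-coding origin scan and density profiles).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .calling import (
    ThresholdSet,
    call_instances,
    call_summary,
    calls_to_frame,
    compute_thresholds,
)
from .clusters import ClusterResult, cluster_permutation_pvalue, find_unmethylated_clusters
from .io_formats import (
    GeneAnnotation,
    GenomeRecord,
    KineticTrack,
    PipelineConfig,
    read_fasta,
    read_gff3,
    read_kinetics,
    read_motifs,
    bed_score,
    write_bed,
)
from .motifs import MotifSpec, classify_motif, find_motif_instances, mean_intermotif_distance
from .noncoding import (
    density_profile,
    extract_noncoding_regions,
    noncoding_enrichment_scan,
)
from .regulatory import (
    RegionSet,
    cog_category_enrichment,
    define_regulatory_regions,
    motif_region_enrichment,
    tfbs_overlap_enrichment,
    unmethylated_region_enrichment,
)


class MethylomeModel:
    """One genome + kinetic track + palindromic motif, ready to fit."""

    def __init__(self, genome: GenomeRecord, genes: list[GeneAnnotation],
                 track: KineticTrack, motif: MotifSpec,
                 config: PipelineConfig | None = None) -> None:
        if not motif.is_double_strand:
            raise ValueError(
                "state calling requires a palindromic double-strand motif; "
                "asymmetric motifs can be scanned but not called"
            )
        self.genome = genome
        self.genes = [g for g in genes if g.contig_id == genome.contig_id]
        self.track = track
        self.motif = motif
        self.config = config or PipelineConfig()

    @classmethod
    def from_files(cls, fasta_path, gff3_path, kinetics_path, motif_path,
                   config: PipelineConfig | None = None,
                   motif_index: int = 0) -> "MethylomeModel":
        genomes = read_fasta(fasta_path)
        genes = read_gff3(gff3_path)
        track = read_kinetics(kinetics_path)
        motifs = read_motifs(motif_path)
        return cls(genomes[0], genes, track, motifs[motif_index], config)

    @classmethod
    def from_bundle(cls, bundle, config: PipelineConfig | None = None) -> "MethylomeModel":
        """Build directly from a :class:`~prokmethylome.simulate.ScenarioBundle`."""
        return cls(bundle.genome, bundle.genes, bundle.track,
                   bundle.scenario.motif, config)

    def fit(self) -> "MethylomeResults":
        instances = find_motif_instances(self.genome, self.motif)
        if not instances:
            raise ValueError("motif has no instances in this genome")
        thresholds = compute_thresholds(
            self.track, instances, self.motif, self.genome, self.config)
        calls = call_instances(self.track, instances, thresholds, self.config)
        return MethylomeResults(self, instances, thresholds, calls)


class MethylomeResults:
    """Fitted methylome: thresholds, per-instance calls and follow-up analyses."""

    def __init__(self, model: MethylomeModel, instances, thresholds: ThresholdSet,
                 calls) -> None:
        self.model = model
        self.instances = instances
        self.thresholds = thresholds
        self.calls = calls
        self._regions: Optional[RegionSet] = None

    # -- basic views --------------------------------------------------------

    @property
    def call_frame(self) -> pd.DataFrame:
        return calls_to_frame(self.calls)

    def state_counts(self) -> dict[str, int]:
        frame = self.call_frame
        return frame["state"].value_counts().to_dict()

    def summary(self) -> str:
        """Human-readable fit summary."""
        motif = self.model.motif
        type_call = classify_motif(motif)
        table = call_summary(self.calls)
        buf = io.StringIO()
        buf.write("Methylome fit\n")
        buf.write("=" * 60 + "\n")
        buf.write(f"contig             {self.model.genome.contig_id}"
                  f" ({self.model.genome.length:,} bp)\n")
        buf.write(f"motif              {motif.pattern} ({motif.mod_type}, "
                  f"{type_call.category})\n")
        buf.write(f"instances          {len(self.instances)}\n")
        buf.write(f"avg motif ipdR     {self.thresholds.avg_motif_ipdR:.3f}\n")
        buf.write(f"avg non-motif ipdR {self.thresholds.avg_nonmotif_ipdR:.3f}\n")
        buf.write(f"under-meth thr     {self.thresholds.under_thr:.3f}\n")
        buf.write(f"methylated thr     {self.thresholds.meth_thr:.3f}\n")
        if self.thresholds.degenerate:
            buf.write("WARNING: motif and background averages coincide\n")
        buf.write("-" * 60 + "\n")
        buf.write(table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
        buf.write("\n")
        return buf.getvalue()

    def diagnostics(self) -> pd.DataFrame:
        """Coverage-parity table (median coverage per call state)."""
        return call_summary(self.calls)

    # -- regions ------------------------------------------------------------

    @property
    def regulatory_regions(self) -> RegionSet:
        if self._regions is None:
            self._regions = define_regulatory_regions(
                self.model.genes, [self.model.genome], self.model.config)
        return self._regions

    # -- enrichment ---------------------------------------------------------

    def motif_enrichment(self, seed: int | None = None):
        """All-instance enrichment in regulatory regions vs composition-matched
        random placements."""
        return motif_region_enrichment(
            self.instances, self.regulatory_regions, self.model.genome,
            self.model.config, seed=seed)

    def unmethylated_enrichment(self):
        """Unmethylated-vs-methylated enrichment in regulatory regions."""
        return unmethylated_region_enrichment(self.calls, self.regulatory_regions)

    def cog_enrichment(self, alpha: float = 0.01) -> pd.DataFrame:
        return cog_category_enrichment(self.calls, self.regulatory_regions, alpha)

    def tfbs_enrichment(self, tfbs: RegionSet):
        return tfbs_overlap_enrichment(self.calls, tfbs)

    # -- clusters -----------------------------------------------------------

    def unmethylated_clusters(self, seed: int | None = None,
                              n_permutations: int | None = None) -> list[ClusterResult]:
        """Significant runs of adjacent unmethylated motifs with Monte-Carlo p."""
        mean_gap = mean_intermotif_distance(self.instances)
        found = find_unmethylated_clusters(self.calls, mean_gap, self.model.config)
        starts = [i.start for i in self.instances]
        for cluster in found:
            cluster_permutation_pvalue(
                cluster, starts, iters=n_permutations, seed=seed,
                mean_gap=mean_gap, cfg=self.model.config)
        return found

    # -- non-coding scan ----------------------------------------------------

    def noncoding_regions(self) -> RegionSet:
        return extract_noncoding_regions(self.model.genes, self.model.genome)

    def noncoding_scan(self):
        """Binomial scan for motif-enriched non-coding regions (origin signature)."""
        return noncoding_enrichment_scan(
            self.noncoding_regions(), self.instances, self.model.config)

    def density_profile(self, anchor: int):
        return density_profile(self.model.genome, self.instances, anchor,
                               self.model.config)

    # -- exports ------------------------------------------------------------

    def write_calls_tsv(self, path) -> None:
        self.call_frame.to_csv(path, sep="\t", index=False)

    def write_unmethylated_bed(self, path) -> None:
        rows = []
        for c in self.calls:
            if c.state != "unmethylated":
                continue
            inst = c.instance
            rows.append((inst.contig_id, inst.meth_pos_fwd, inst.meth_pos_fwd + 1,
                         f"unmeth_{inst.start}",
                         bed_score(min(c.ipdR_fwd, c.ipdR_rev)), "+"))
        write_bed(rows, path)

    def plot_strand_scatter(self, ax=None):
        """ipdR forward vs reverse strand, coloured by state (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.call_frame
        colors = {"methylated": "tab:red", "unmethylated": "tab:blue",
                  "ambiguous": "tab:gray", "low_coverage": "tab:olive"}
        for state, sub in frame.groupby("state"):
            ax.scatter(sub["ipdR_fwd"], sub["ipdR_rev"], s=8, alpha=0.6,
                       label=state, color=colors.get(state, "k"))
        for thr, style in ((self.thresholds.under_thr, ":"),
                           (self.thresholds.meth_thr, "--")):
            ax.axvline(thr, ls=style, c="k", lw=0.8)
            ax.axhline(thr, ls=style, c="k", lw=0.8)
        ax.set_xlabel("ipdR (forward strand)")
        ax.set_ylabel("ipdR (reverse strand)")
        ax.legend(frameon=False, fontsize=8)
        return ax
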