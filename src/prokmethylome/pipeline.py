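"""End-to-end orchestration: motifs -> calls -> enrichment -> clusters -> ori scan.

``run_all`` executes every stage for each palindromic motif in the input
bundle, persists the per-stage TSV reports and returns a machine-readable
summary.  Re-running with the same seed and config reproduces the outputs
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .calling import call_summary
from .io_formats import PipelineConfig, read_fasta, read_gff3, read_kinetics, read_motifs
from .model import MethylomeModel
from .motifs import classify_motif

log = logging.getLogger("prokmethylome")


@dataclass
class RunSummary:
    config: dict
    seed: int
    inputs: dict[str, str]  # path -> sha256
    per_motif: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(fasta_path, gff3_path, kinetics_path, motif_path,
            out_dir, config: PipelineConfig | None = None,
            seed: int = 0) -> RunSummary:
    """Run the full analysis for every double-strand motif in the motif list."""
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {str(p): _sha256(p) for p in
              (fasta_path, gff3_path, kinetics_path, motif_path)}
    summary = RunSummary(config=asdict(cfg), seed=seed, inputs=inputs)

    genomes = read_fasta(fasta_path)
    genes = read_gff3(gff3_path)
    track = read_kinetics(kinetics_path)
    motifs = read_motifs(motif_path)

    genome = genomes[0]
    for motif in motifs:
        tag = motif.pattern
        type_call = classify_motif(motif)
        entry: dict = {"motif": motif.pattern, "mod_type": motif.mod_type,
                       "category": type_call.category}
        if not motif.is_double_strand:
            log.info("motif %s is asymmetric; scanned but not called", tag)
            model = None
            entry["note"] = "asymmetric motif: instances reported, no state calls"
            from .motifs import find_motif_instances

            entry["n_instances"] = len(find_motif_instances(genome, motif))
            summary.per_motif.append(entry)
            continue
        try:
            model = MethylomeModel(genome, genes, track, motif, cfg)
            res = model.fit()
        except Exception as exc:  # stage failure: record, skip dependents
            log.error("fit failed for motif %s: %s", tag, exc)
            summary.failures.append({"motif": tag, "stage": "fit", "error": str(exc)})
            continue
        entry["n_instances"] = len(res.instances)
        entry["thresholds"] = {
            "avg_motif_ipdR": res.thresholds.avg_motif_ipdR,
            "avg_nonmotif_ipdR": res.thresholds.avg_nonmotif_ipdR,
            "under_thr": res.thresholds.under_thr,
            "meth_thr": res.thresholds.meth_thr,
        }
        entry["state_counts"] = res.state_counts()
        res.write_calls_tsv(out / f"calls_{tag}.tsv")
        res.write_unmethylated_bed(out / f"unmethylated_{tag}.bed")
        call_summary(res.calls).to_csv(out / f"summary_{tag}.tsv", sep="\t",
                                       index=False)

        n_unmeth = entry["state_counts"].get("unmethylated", 0)
        n_meth = entry["state_counts"].get("methylated", 0)
        if n_unmeth and n_meth:
            try:
                enr = res.unmethylated_enrichment()
                entry["unmethylated_enrichment"] = {
                    "n_in": enr.n_in, "n_total": enr.n_total,
                    "observed_fraction": enr.observed_fraction,
                    "background_fraction": enr.background_fraction,
                    "fold": enr.fold, "p_value": enr.p_value,
                }
                cog = res.cog_enrichment()
                cog.to_csv(out / f"cog_enrichment_{tag}.tsv", sep="\t", index=False)
            except ValueError as exc:
                summary.failures.append(
                    {"motif": tag, "stage": "enrichment", "error": str(exc)})
        clusters = res.unmethylated_clusters(seed=seed)
        entry["clusters"] = [
            {"start": c.start, "end": c.end, "k": c.k, "span": c.span,
             "p_value": c.p_value}
            for c in clusters
        ]
        pd.DataFrame(entry["clusters"]).to_csv(
            out / f"clusters_{tag}.tsv", sep="\t", index=False)
        scan = res.noncoding_scan()
        hits = [s for s in scan if s.significant]
        entry["noncoding_hits"] = [
            {"start": s.region.start, "end": s.region.end,
             "observed": s.observed, "expected": s.expected,
             "fold": s.fold, "p_bonferroni": s.p_bonferroni}
            for s in hits
        ]
        pd.DataFrame(
            [{"start": s.region.start, "end": s.region.end, "observed": s.observed,
              "local_density": s.local_density, "expected": s.expected,
              "fold": s.fold, "p_raw": s.p_raw, "p_bonferroni": s.p_bonferroni,
              "significant": s.significant} for s in scan]
        ).to_csv(out / f"noncoding_scan_{tag}.tsv", sep="\t", index=False)
        summary.per_motif.append(entry)

    summary.to_json(out / "run_summary.json")
    return summary
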