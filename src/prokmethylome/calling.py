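"""Per-motif ipdR thresholds and methylation-state calls.

For each palindromic double-strand motif, an under-methylated and a
methylated ipdR threshold are derived from two trimmed means: the average
ipdR over the motif's methylatable positions (both strands pooled) and the
average over all same-nucleotide positions outside any motif footprint.

    under_thr = 0.1 * avg_motif + 0.9 * avg_nonmotif
    meth_thr  = 0.5 * avg_motif + 0.5 * avg_nonmotif

i.e. the expected ipdR if 10% (respectively 50%) of molecules were
methylated.  Both trimmed means keep the central 60% of ranked values so
that genuinely unmethylated sites do not drag the motif average down.

An instance is *unmethylated* only when both strands have at least 20-fold
coverage and both ipdR values fall below the under-methylated threshold —
a deliberately stringent rule that yields high-confidence unmethylated
sites rather than borderline cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import GenomeRecord, KineticTrack, PipelineConfig
from .motifs import MotifInstance, MotifSpec, _COMPLEMENT

STATES = ("methylated", "unmethylated", "ambiguous", "low_coverage")


@dataclass(frozen=True)
class ThresholdSet:
    avg_motif_ipdR: float
    avg_nonmotif_ipdR: float
    under_thr: float
    meth_thr: float

    @property
    def degenerate(self) -> bool:
        """True when motif and background averages coincide (no signal)."""
        return not (self.avg_motif_ipdR > self.avg_nonmotif_ipdR)


@dataclass(frozen=True)
class MethylationCall:
    instance: MotifInstance
    state: str
    ipdR_fwd: float
    ipdR_rev: float
    cov_fwd: int
    cov_rev: int

    def __post_init__(self):
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")


def trimmed_central_mean(values, central_fraction: float) -> float:
    """Mean of the central fraction of ranked values.

    ``floor((1 - central_fraction)/2 * n)`` values are dropped from each end
    of the sorted list before averaging.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("trimmed_central_mean of empty list")
    if not (0 < central_fraction <= 1):
        raise ValueError("central_fraction must be in (0, 1]")
    k = math.floor((1 - central_fraction) / 2 * arr.size)
    trimmed = arr[k: arr.size - k] if k else arr
    return float(trimmed.mean())


def _instance_meth_values(track: KineticTrack, instances: list[MotifInstance]):
    """Per-instance (ipdR_fwd, ipdR_rev, cov_fwd, cov_rev) arrays."""
    contig = instances[0].contig_id
    fwd_pos = np.array([i.meth_pos_fwd for i in instances], dtype=np.int64)
    rev_pos = np.array([i.meth_pos_rev for i in instances], dtype=np.int64)
    return (
        track.ipdr_at(contig, "+", fwd_pos),
        track.ipdr_at(contig, "-", rev_pos),
        track.coverage_at(contig, "+", fwd_pos),
        track.coverage_at(contig, "-", rev_pos),
    )


def compute_thresholds(track: KineticTrack, instances: list[MotifInstance],
                       motif: MotifSpec, genome: GenomeRecord,
                       cfg: PipelineConfig | None = None) -> ThresholdSet:
    """Derive the under-methylated and methylated ipdR thresholds.

    The motif average pools ipdR at every methylatable motif position on both
    strands; the background average pools ipdR at every genome position whose
    base matches the methylated nucleotide and that lies outside all motif
    footprints (forward strand: positions carrying the base; reverse strand:
    positions carrying its complement).
    """
    cfg = cfg or PipelineConfig()
    if not instances:
        raise ValueError("no motif instances with kinetic data")
    if not motif.is_double_strand:
        raise ValueError("thresholds are defined for double-strand motifs")
    contig = genome.contig_id

    ipdr_f, ipdr_r, _, _ = _instance_meth_values(track, instances)
    motif_vals = np.concatenate([ipdr_f, ipdr_r])
    motif_vals = motif_vals[~np.isnan(motif_vals)]
    if motif_vals.size == 0:
        raise ValueError("no kinetic data at motif positions")

    seq = np.frombuffer(genome.sequence.encode(), dtype="S1")
    base = motif.methylated_base.encode()
    comp = _COMPLEMENT[motif.methylated_base].encode()
    in_footprint = np.zeros(genome.length, dtype=bool)
    for inst in instances:
        in_footprint[inst.start: inst.end] = True

    bg_vals = []
    for strand, want in (("+", base), ("-", comp)):
        mask = (seq == want) & ~in_footprint
        positions = np.nonzero(mask)[0]
        vals = track.ipdr_at(contig, strand, positions)
        bg_vals.append(vals[~np.isnan(vals)])
    bg = np.concatenate(bg_vals)
    if bg.size == 0:
        raise ValueError("no same-base non-motif positions with kinetic data")

    avg_motif = trimmed_central_mean(motif_vals, cfg.central_fraction)
    avg_nonmotif = trimmed_central_mean(bg, cfg.central_fraction)
    w_u, w_m = cfg.under_meth_weight, cfg.meth_weight
    return ThresholdSet(
        avg_motif_ipdR=avg_motif,
        avg_nonmotif_ipdR=avg_nonmotif,
        under_thr=w_u * avg_motif + (1 - w_u) * avg_nonmotif,
        meth_thr=w_m * avg_motif + (1 - w_m) * avg_nonmotif,
    )


def call_instances(track: KineticTrack, instances: list[MotifInstance],
                   thresholds: ThresholdSet,
                   cfg: PipelineConfig | None = None) -> list[MethylationCall]:
    """Classify every instance as methylated / unmethylated / ambiguous / low_coverage.

    Rules (both strands considered; positions absent from the track count as
    zero coverage):

    * low_coverage  — either strand below ``min_coverage`` reads;
    * unmethylated  — both ipdR strictly below the under-methylated threshold;
    * methylated    — both ipdR at or above the methylated threshold;
    * ambiguous     — everything else.
    """
    cfg = cfg or PipelineConfig()
    if not instances:
        return []
    if any(i.meth_pos_fwd is None or i.meth_pos_rev is None for i in instances):
        raise ValueError(
            "state calling requires palindromic double-strand instances; "
            "asymmetric motifs are reported, not statistically analysed"
        )
    ipdr_f, ipdr_r, cov_f, cov_r = _instance_meth_values(track, instances)
    calls = []
    for i, inst in enumerate(instances):
        cf, cr = int(cov_f[i]), int(cov_r[i])
        rf, rr = float(ipdr_f[i]), float(ipdr_r[i])
        if cf < cfg.min_coverage or cr < cfg.min_coverage:
            state = "low_coverage"
        elif rf < thresholds.under_thr and rr < thresholds.under_thr:
            state = "unmethylated"
        elif rf >= thresholds.meth_thr and rr >= thresholds.meth_thr:
            state = "methylated"
        else:
            state = "ambiguous"
        calls.append(MethylationCall(inst, state, rf, rr, cf, cr))
    return calls


def calls_to_frame(calls: list[MethylationCall]) -> pd.DataFrame:
    """Per-call table: coordinates, state and per-strand evidence."""
    return pd.DataFrame(
        {
            "contig": [c.instance.contig_id for c in calls],
            "start": [c.instance.start for c in calls],
            "end": [c.instance.end for c in calls],
            "meth_pos_fwd": [c.instance.meth_pos_fwd for c in calls],
            "meth_pos_rev": [c.instance.meth_pos_rev for c in calls],
            "state": [c.state for c in calls],
            "ipdR_fwd": [c.ipdR_fwd for c in calls],
            "ipdR_rev": [c.ipdR_rev for c in calls],
            "cov_fwd": [c.cov_fwd for c in calls],
            "cov_rev": [c.cov_rev for c in calls],
        }
    )


def call_summary(calls: list[MethylationCall]) -> pd.DataFrame:
    """Counts, fractions and median coverage per state.

    The median-coverage column is the coverage-parity diagnostic: genuinely
    unmethylated sites should show coverage equivalent to methylated ones,
    ruling out low-coverage artefacts.
    """
    if not calls:
        raise ValueError("no calls to summarise")
    df = calls_to_frame(calls)
    total = len(df)
    rows = []
    for state in STATES:
        sub = df[df["state"] == state]
        med_cov = float(np.median(np.concatenate([sub["cov_fwd"], sub["cov_rev"]]))) \
            if len(sub) else float("nan")
        rows.append(
            {"state": state, "count": len(sub),
             "fraction": len(sub) / total, "median_coverage": med_cov}
        )
    return pd.DataFrame(rows)
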