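"""Readers and writers for the external formats the pipeline touches.

Internal convention: all coordinates are 0-based half-open on the forward
strand.  External formats are converted at this boundary only — GFF3 stays
1-based inclusive in :class:`GeneAnnotation` (as on disk) and becomes 0-based
half-open when regions are built; the kinetics CSV is 1-based on disk and
0-based in :class:`KineticTrack`; BED is written 0-based half-open as the
format requires.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import yaml
from Bio import SeqIO

VALID_BASES = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomeRecord:
    """A contig: id plus an upper-case DNA sequence over {A,C,G,T,N}."""

    contig_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated feature, 1-based inclusive coordinates as in GFF3."""

    contig_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    feature_type: str  # 'CDS', 'RNA' or 'other'
    gene_id: str
    product: str = ""
    cog_letter: Optional[str] = None

    def __post_init__(self):
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    # 0-based half-open accessors used everywhere internally
    @property
    def start0(self) -> int:
        return self.start - 1

    @property
    def end0(self) -> int:
        return self.end


class KineticTrack:
    """Per-contig, per-strand ipdR and read-coverage arrays.

    Positions are 0-based internally.  Positions without data are absent
    (ipdR is NaN, coverage 0), never silently zero-filled ipdR.
    """

    def __init__(self) -> None:
        # (contig, strand) -> (ipdr float array, cov int array)
        self._data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    def add_dense(self, contig: str, strand: str, ipdr: np.ndarray, cov: np.ndarray) -> None:
        ipdr = np.asarray(ipdr, dtype=float)
        cov = np.asarray(cov, dtype=np.int64)
        if ipdr.shape != cov.shape:
            raise ValueError("ipdr and coverage arrays must have equal length")
        with np.errstate(invalid="ignore"):
            if np.any(ipdr[~np.isnan(ipdr)] <= 0):
                raise FormatError("ipdR must be > 0 where defined")
        ipdr = ipdr.copy()
        ipdr[cov == 0] = np.nan
        self._data[(contig, strand)] = (ipdr, cov)

    @property
    def keys(self):
        return list(self._data)

    def _arrays(self, contig: str, strand: str):
        return self._data.get((contig, strand))

    def ipdr_at(self, contig: str, strand: str, positions) -> np.ndarray:
        """ipdR at 0-based positions; NaN where absent."""
        positions = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        entry = self._arrays(contig, strand)
        out = np.full(positions.shape, np.nan)
        if entry is None:
            return out
        ipdr, _ = entry
        ok = (positions >= 0) & (positions < ipdr.size)
        out[ok] = ipdr[positions[ok]]
        return out

    def coverage_at(self, contig: str, strand: str, positions) -> np.ndarray:
        """Read coverage at 0-based positions; 0 where absent."""
        positions = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        entry = self._arrays(contig, strand)
        out = np.zeros(positions.shape, dtype=np.int64)
        if entry is None:
            return out
        _, cov = entry
        ok = (positions >= 0) & (positions < cov.size)
        out[ok] = cov[positions[ok]]
        return out

    def dense(self, contig: str, strand: str, length: int):
        """(ipdr, cov) arrays of exactly `length`, padded with absent values."""
        entry = self._arrays(contig, strand)
        ipdr = np.full(length, np.nan)
        cov = np.zeros(length, dtype=np.int64)
        if entry is not None:
            src_i, src_c = entry
            n = min(length, src_i.size)
            ipdr[:n] = src_i[:n]
            cov[:n] = src_c[:n]
        return ipdr, cov

    def iter_rows(self):
        """Yield (contig, position0, strand, ipdr, cov) for defined positions."""
        for (contig, strand), (ipdr, cov) in sorted(self._data.items()):
            defined = np.nonzero(cov > 0)[0]
            for pos in defined:
                yield contig, int(pos), strand, float(ipdr[pos]), int(cov[pos])

    def __eq__(self, other) -> bool:
        if not isinstance(other, KineticTrack):
            return NotImplemented
        return list(self.iter_rows()) == list(other.iter_rows())


@dataclass
class PipelineConfig:
    """All numeric constants of the analysis, with their published defaults.

    under_meth_weight / meth_weight
        Mixture weights defining the under-methylated and methylated ipdR
        thresholds: ``thr = w*avg_motif + (1-w)*avg_nonmotif``.
    central_fraction
        Fraction of ranked ipdR values kept for the trimmed mean (0.6 keeps
        the central 60%, shielding the average from unmethylated outliers).
    min_coverage
        Minimum per-strand read coverage (20) for a confident call.
    n_resamplings
        Composition-matched random samplings for background fractions (1000).
    n_permutations
        Monte-Carlo iterations for cluster significance (10000).
    cluster_min_size / cluster_alpha
        Minimum run length (3) and significance level (0.01) for clusters of
        adjacent unmethylated motifs.
    noncoding_alpha
        Bonferroni-corrected threshold (1e-5) for motif-enriched non-coding
        regions.
    flank_regions
        Non-coding regions pooled for the local motif density (100).
    window_bp / step_bp / span_bp
        Density-profile geometry: 500 bp windows, 50 bp step, 50 kb span.
    upstream_bp / downstream_bp
        Regulatory region: 100 bp upstream to 50 bp downstream of CDS start.
    similarity_threshold
        Bitscore-ratio score (>=35) declaring a potential ortholog.
    conservation_fraction
        Fraction of species (strictly >0.5) for a "conserved" MTase.
    family_identity_cutoff
        Minimum pairwise identity (0.35) within an orphan MTase family.
    """

    under_meth_weight: float = 0.1
    meth_weight: float = 0.5
    central_fraction: float = 0.6
    min_coverage: int = 20
    n_resamplings: int = 1000
    n_permutations: int = 10000
    cluster_min_size: int = 3
    cluster_alpha: float = 0.01
    noncoding_alpha: float = 1e-5
    flank_regions: int = 100
    window_bp: int = 500
    step_bp: int = 50
    span_bp: int = 50000
    upstream_bp: int = 100
    downstream_bp: int = 50
    similarity_threshold: float = 35.0
    conservation_fraction: float = 0.5
    family_identity_cutoff: float = 0.35
    rng_seed: int = 0
    # When True, the non-coding scan uses the literal strict tail P(X > obs)
    # instead of the default P(X >= obs).
    noncoding_strict_tail: bool = False

    def __post_init__(self):
        if not (0 < self.central_fraction <= 1):
            raise ValueError("central_fraction must be in (0, 1]")
        for w in (self.under_meth_weight, self.meth_weight):
            if not (0 <= w <= 1):
                raise ValueError("threshold weights must be in [0, 1]")
        for name in ("min_coverage", "n_resamplings", "n_permutations",
                     "cluster_min_size", "flank_regions", "window_bp",
                     "step_bp", "span_bp", "upstream_bp", "downstream_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[GenomeRecord]:
    """Read a FASTA file into GenomeRecords.

    Sequences are upper-cased; IUPAC ambiguity codes other than N are masked
    to N with a warning (they never match a motif symbol downstream).
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            warnings.warn(
                f"contig {rec.id}: masking non-ACGTN symbols {sorted(bad)} to N"
            )
            seq = "".join(c if c in VALID_BASES else "N" for c in seq)
        records.append(GenomeRecord(rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_RNA_TYPES = {"tRNA", "rRNA", "ncRNA", "tmRNA", "rRNA_gene", "miscRNA", "misc_RNA", "RNA"}


def _gff_attributes(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path) -> list[GeneAnnotation]:
    """Parse CDS and RNA features from a GFF3 file.

    Coordinates are kept 1-based inclusive as in the file.  CDS features
    without an ID or locus_tag get a synthesized identifier (with a warning).
    """
    genes: list[GeneAnnotation] = []
    n_anon = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype == "CDS":
                feature_type = "CDS"
            elif ftype in _RNA_TYPES or ftype.endswith("RNA"):
                feature_type = "RNA"
            else:
                continue
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise FormatError(f"{path}:{lineno}: start > end")
            attr = _gff_attributes(attrs)
            gene_id = attr.get("ID") or attr.get("locus_tag")
            if gene_id is None:
                n_anon += 1
                gene_id = f"{feature_type}_{contig}_{start_i}_{n_anon}"
                warnings.warn(f"{path}:{lineno}: feature without ID; using {gene_id}")
            genes.append(
                GeneAnnotation(
                    contig_id=contig,
                    start=start_i,
                    end=end_i,
                    strand=strand if strand in "+-" else "+",
                    feature_type=feature_type,
                    gene_id=gene_id,
                    product=attr.get("product", ""),
                    cog_letter=attr.get("cog") or None,
                )
            )
    return genes


def write_gff3(genes: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            ftype = "CDS" if g.feature_type == "CDS" else "tRNA"
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            if g.cog_letter:
                attrs += f";cog={g.cog_letter}"
            fh.write(
                f"{g.contig_id}\tprokmethylome\t{ftype}\t{g.start}\t{g.end}"
                f"\t.\t{g.strand}\t0\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Kinetics CSV

KINETICS_HEADER = ["contig", "position", "strand", "base", "ipdRatio", "coverage"]

_STRAND_CODES = {"+": "+", "-": "-", "0": "+", "1": "-"}


def read_kinetics(path) -> KineticTrack:
    """Read the per-base kinetics CSV (1-based positions) into a KineticTrack.

    Dialect: header ``contig,position,strand,base,ipdRatio,coverage``.
    Strand accepts +/- or the 0/1 codes of platform modifications.csv exports
    (0 maps to +, 1 to -).  Zero-coverage rows are dropped; duplicate
    (contig, position, strand) keys are an error.
    """
    per_key: dict[tuple[str, str], dict[int, tuple[float, int]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(KINETICS_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"kinetics CSV missing columns: {sorted(missing)}")
        for row in reader:
            strand = _STRAND_CODES.get(row["strand"].strip())
            if strand is None:
                raise FormatError(f"unknown strand code {row['strand']!r}")
            cov = int(row["coverage"])
            if cov == 0:
                continue
            ipdr = float(row["ipdRatio"])
            if ipdr <= 0:
                raise FormatError(f"ipdRatio must be > 0, got {ipdr}")
            pos0 = int(row["position"]) - 1
            key = (row["contig"], strand)
            bucket = per_key.setdefault(key, {})
            if pos0 in bucket:
                raise FormatError(
                    f"duplicate kinetics row for {row['contig']}:{row['position']}:{strand}"
                )
            bucket[pos0] = (ipdr, cov)
    track = KineticTrack()
    for (contig, strand), bucket in per_key.items():
        size = max(bucket) + 1
        ipdr = np.full(size, np.nan)
        cov = np.zeros(size, dtype=np.int64)
        for pos, (r, c) in bucket.items():
            ipdr[pos] = r
            cov[pos] = c
        track.add_dense(contig, strand, ipdr, cov)
    return track


def write_kinetics(track: KineticTrack, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(KINETICS_HEADER)
        for contig, pos0, strand, ipdr, cov in track.iter_rows():
            writer.writerow([contig, pos0 + 1, strand, "N", f"{ipdr:.6g}", cov])


# ---------------------------------------------------------------------------
# Motif TSV

def read_motifs(path):
    """Read the motif list TSV: pattern, meth_offset_fwd (1-based), mod_type.

    The complementary-strand offset is derived automatically for palindromes.
    """
    from .motifs import MotifSpec, is_palindrome  # local import to avoid cycle

    motifs = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pattern = row["pattern"].strip().upper()
            offset = int(row["meth_offset_fwd"]) - 1
            mod_type = row["mod_type"].strip()
            rev = len(pattern) - 1 - offset if is_palindrome(pattern) else None
            motifs.append(
                MotifSpec(pattern=pattern, meth_offset_fwd=offset,
                          mod_type=mod_type, meth_offset_rev=rev)
            )
    return motifs


def write_motifs(motifs, path) -> None:
    with open(path, "w") as fh:
        fh.write("pattern\tmeth_offset_fwd\tmod_type\n")
        for m in motifs:
            fh.write(f"{m.pattern}\t{m.meth_offset_fwd + 1}\t{m.mod_type}\n")


# ---------------------------------------------------------------------------
# BED

def write_bed(intervals, path) -> None:
    """Write 6-column BED: (contig, start0, end0, name, score, strand) tuples.

    Score may be '.', a number, or an ipdR (caller multiplies by 1000 and
    clamps to [0, 1000] for call exports via :func:`bed_score`).
    """
    with open(path, "w") as fh:
        for contig, start, end, name, score, strand in intervals:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path) -> list[tuple[str, int, int, str, str, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            contig, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "."
            score = f[4] if len(f) > 4 else "."
            strand = f[5] if len(f) > 5 else "."
            rows.append((contig, start, end, name, score, strand))
    return rows


def bed_score(ipdr: float) -> int:
    """BED score for an ipdR value: x1000, clamped to [0, 1000]."""
    return int(min(1000, max(0, round(ipdr * 1000))))
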