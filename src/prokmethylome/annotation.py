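"""Orphan-vs-RM classification of MTase genes and motif-to-gene matching.

An "orphan" methyltransferase is one encoded without a detectable cognate
restriction endonuclease in its genomic neighbourhood — the hallmark of the
gene-regulatory MTases (Dam, CcrM and relatives).  Because restriction genes
can be missed, the call is deliberately labelled *candidate* orphan.

A methylated motif is attributed to an MTase gene only when exactly one
compatible candidate exists; with several same-specificity candidates no
match is called.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional

from .io_formats import GeneAnnotation
from .motifs import MotifSpec, MotifTypeCall, reverse_complement

_RM_COMPAT = {
    "I": "TypeI_bipartite",
    "II": "TypeII_palindromic",
    "IIG": "TypeIIG_like",
    "III": "TypeIII_like",
}


@dataclass(frozen=True)
class MTaseGene:
    gene_id: str
    contig_id: str
    start: int  # 1-based inclusive, as annotations
    end: int
    strand: str
    rm_type: str = "unknown"  # I, II, IIG, III or unknown
    predicted_mod_type: str = "unknown"  # m6A, m4C, m5C or unknown
    predicted_specificity: Optional[str] = None

    def __post_init__(self):
        if self.rm_type not in ("I", "II", "IIG", "III", "unknown"):
            raise ValueError(f"unknown RM type {self.rm_type!r}")
        if self.predicted_mod_type not in ("m6A", "m4C", "m5C", "unknown"):
            raise ValueError(f"unknown mod type {self.predicted_mod_type!r}")


@dataclass(frozen=True)
class REaseGene:
    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    rm_type: str = "unknown"


@dataclass(frozen=True)
class MatchResult:
    motif: MotifSpec
    matched_gene: Optional[str]
    status: str  # matched, ambiguous, unmatched


def classify_orphan(mtase: MTaseGene, reases: list[REaseGene],
                    genes: list[GeneAnnotation],
                    window_genes: int = 5, window_bp: int = 10000) -> str:
    """'rm_associated' if a REase lies within the flanking window, else
    'orphan_candidate'.

    The flanking window is +/- ``window_genes`` genes (by position rank on the
    same contig) or +/- ``window_bp`` bases, whichever catches the REase.
    """
    same_contig = sorted(
        (g for g in genes if g.contig_id == mtase.contig_id),
        key=lambda g: g.start,
    )
    rank = {g.gene_id: i for i, g in enumerate(same_contig)}
    # the MTase's own rank: locate by overlapping coordinates if id not present
    my_rank = rank.get(mtase.gene_id)
    if my_rank is None:
        my_rank = sum(1 for g in same_contig if g.start < mtase.start)
    for re_gene in reases:
        if re_gene.contig_id != mtase.contig_id:
            continue
        bp_dist = max(0, max(mtase.start, re_gene.start) - min(mtase.end, re_gene.end))
        if bp_dist <= window_bp:
            return "rm_associated"
        re_rank = rank.get(re_gene.gene_id)
        if re_rank is None:
            re_rank = sum(1 for g in same_contig if g.start < re_gene.start)
        if abs(re_rank - my_rank) <= window_genes:
            return "rm_associated"
    return "orphan_candidate"


def _canonical(pattern: str) -> str:
    return min(pattern, reverse_complement(pattern))


def match_motifs_to_mtases(motifs: list[tuple[MotifSpec, MotifTypeCall]],
                           mtases: list[MTaseGene]) -> list[MatchResult]:
    """Attribute each motif to an MTase gene under the uniqueness rule.

    A gene is a candidate when its RM type is compatible with the motif's
    architecture (unknown types are compatible with everything) and its
    predicted specificity, when present, equals the motif pattern (palindromes
    canonicalised).  Exactly one candidate -> matched; several -> ambiguous;
    none -> unmatched.
    """
    results = []
    for motif, type_call in motifs:
        candidates = []
        for gene in mtases:
            if gene.rm_type != "unknown" and \
                    _RM_COMPAT.get(gene.rm_type) != type_call.category:
                continue
            if gene.predicted_mod_type not in ("unknown", motif.mod_type):
                continue
            if gene.predicted_specificity is not None and \
                    _canonical(gene.predicted_specificity.upper()) != _canonical(motif.pattern):
                continue
            candidates.append(gene)
        if len(candidates) == 1:
            results.append(MatchResult(motif, candidates[0].gene_id, "matched"))
        elif candidates:
            results.append(MatchResult(motif, None, "ambiguous"))
        else:
            results.append(MatchResult(motif, None, "unmatched"))
    return results


def read_gene_table(path) -> tuple[list[MTaseGene], list[REaseGene]]:
    """Read the RM-gene TSV: gene_id, contig, start, end, strand, role,
    rm_type, mod_type, specificity."""
    mtases, reases = [], []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            common = dict(
                gene_id=row["gene_id"], contig_id=row["contig"],
                start=int(row["start"]), end=int(row["end"]),
                strand=row["strand"],
                rm_type=row.get("rm_type") or "unknown",
            )
            if row["role"] == "MTase":
                spec = (row.get("specificity") or "").strip() or None
                mtases.append(MTaseGene(
                    predicted_mod_type=row.get("mod_type") or "unknown",
                    predicted_specificity=spec, **common))
            elif row["role"] == "REase":
                reases.append(REaseGene(**common))
            else:
                raise ValueError(f"unknown role {row['role']!r}")
    return mtases, reases
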