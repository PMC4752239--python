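"""Cross-genome conservation: ortholog scoring, reciprocal best hits,
conserved unmethylated sites, and orphan MTase families.

Homology is quantified by a self-normalised bitscore ratio
(100 * bitscore(hit) / bitscore(self)); scores of 35 or more flag potential
orthologs.  An MTase is "conserved" within a taxonomic group when strictly
more than half of the group's species carry an ortholog.  Orphan MTase
families are built by agglomerative clustering of pairwise protein identity
within each modification-type group (m6A versus m4C/m5C), requiring every
pair inside a family to share at least 35% identity, an identical canonical
motif and a common taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .motifs import reverse_complement


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    bitscore_hit: float
    bitscore_self: float

    @property
    def similarity_score(self) -> float:
        return similarity_score(self.bitscore_hit, self.bitscore_self)


@dataclass(frozen=True)
class ConservationCall:
    mtase_id: str
    taxon_level: str  # genus, family or class
    n_species_with_ortholog: int
    n_species_total: int
    conserved: bool

    @property
    def fraction(self) -> float:
        return self.n_species_with_ortholog / self.n_species_total


@dataclass
class FamilyCluster:
    member_mtase_ids: list[str]
    mod_type_group: str  # 'm6A' or 'm4C_m5C'
    shared_motif: str
    taxon_label: str

    @property
    def is_singleton(self) -> bool:
        return len(self.member_mtase_ids) == 1


def similarity_score(bitscore_hit: float, bitscore_self: float) -> float:
    """100 * bitscore(hit) / bitscore(self); >=35 marks a potential ortholog."""
    if bitscore_self <= 0:
        raise ValueError("self bitscore must be positive")
    return 100.0 * bitscore_hit / bitscore_self


def is_potential_ortholog(score: float, threshold: float = 35.0) -> bool:
    """Inclusive at the threshold ("35 or more")."""
    return score >= threshold


def conservation_fraction(hits: pd.DataFrame, taxonomy: dict[str, str],
                          mtase_id: str, taxon_level: str = "genus",
                          threshold: float = 35.0,
                          fraction_cutoff: float = 0.5) -> ConservationCall:
    """Fraction of taxon species carrying an ortholog; conserved iff strictly
    greater than the cutoff.

    ``hits`` columns: query (MTase id), species, bitscore_hit, bitscore_self.
    ``taxonomy`` maps species -> taxon label at the chosen level; it must
    cover every species in the table, and the species appearing there define
    the group's denominator.
    """
    species_in_taxon = {sp for sp in taxonomy}
    if not species_in_taxon:
        raise ValueError("empty taxonomy")
    sub = hits[hits["query"] == mtase_id]
    with_ortholog = set()
    for _, row in sub.iterrows():
        sp = row["species"]
        if sp not in taxonomy:
            raise ValueError(f"species {sp!r} missing from taxonomy")
        score = similarity_score(row["bitscore_hit"], row["bitscore_self"])
        if is_potential_ortholog(score, threshold):
            with_ortholog.add(sp)
    n_total = len(species_in_taxon)
    n_with = len(with_ortholog & species_in_taxon)
    return ConservationCall(
        mtase_id=mtase_id, taxon_level=taxon_level,
        n_species_with_ortholog=n_with, n_species_total=n_total,
        conserved=(n_with / n_total) > fraction_cutoff,
    )


def reciprocal_best_hits(scores_ab: pd.DataFrame,
                         scores_ba: pd.DataFrame) -> dict[str, str]:
    """Mutual unique best hits between two genomes.

    Tables carry columns query, subject, bitscore.  A pair (a, b) is kept iff
    b is a's unique best subject and a is b's unique best subject; ties for
    best disqualify the query deterministically.
    """

    def unique_best(table: pd.DataFrame) -> dict[str, str]:
        best: dict[str, str] = {}
        for query, group in table.groupby("query"):
            top = group["bitscore"].max()
            winners = group.loc[group["bitscore"] == top, "subject"].unique()
            if len(winners) == 1:
                best[query] = winners[0]
        return best

    ab = unique_best(scores_ab)
    ba = unique_best(scores_ba)
    return {a: b for a, b in ab.items() if ba.get(b) == a}


def flanking_genes(pos: int, genes, contig_id: str):
    """(left gene id, right gene id) nearest to a 0-based position.

    A site past the outermost gene has a single flank; the missing side is
    None.
    """
    same = sorted((g for g in genes if g.contig_id == contig_id),
                  key=lambda g: g.start)
    left = right = None
    for g in same:
        if g.end0 <= pos:
            left = g.gene_id
        elif g.start0 > pos and right is None:
            right = g.gene_id
            break
        elif g.start0 <= pos < g.end0:
            # site inside a gene: that gene flanks on both definitions;
            # treat it as the nearer side it began on
            left = g.gene_id
    return left, right


def conserved_unmethylated_sites(calls_a, calls_b, genes_a, genes_b,
                                 rbh: dict[str, str]) -> list[tuple]:
    """Pairs of unmethylated sites whose flanking genes are reciprocal best hits.

    Order-aware up to a strand flip: (leftA->leftB, rightA->rightB) or
    (leftA->rightB, rightA->leftB).  A site with a single flanking gene
    requires that gene alone to match (flagged by the None in the pair).
    """
    unmeth_a = [c for c in calls_a if c.state == "unmethylated"]
    unmeth_b = [c for c in calls_b if c.state == "unmethylated"]
    flanks_b = []
    for cb in unmeth_b:
        pos = cb.instance.meth_pos_fwd
        flanks_b.append((cb, flanking_genes(pos, genes_b, cb.instance.contig_id)))
    out = []
    for ca in unmeth_a:
        pos = ca.instance.meth_pos_fwd
        la, ra = flanking_genes(pos, genes_a, ca.instance.contig_id)
        ma = rbh.get(la) if la else None
        mb = rbh.get(ra) if ra else None
        if ma is None and mb is None:
            continue
        for cb, (lb, rb) in flanks_b:
            direct = (ma == lb or (la is None and lb is None)) and \
                     (mb == rb or (ra is None and rb is None))
            flipped = (ma == rb or (la is None and rb is None)) and \
                      (mb == lb or (ra is None and lb is None))
            if direct or flipped:
                out.append((ca, cb))
                break
    return out


def cluster_orphan_families(similarity: pd.DataFrame,
                            mod_types: dict[str, str],
                            motifs: dict[str, str],
                            taxa: dict[str, str],
                            identity_cutoff: float = 0.35,
                            linkage_method: str = "complete") -> list[FamilyCluster]:
    """Group orphan MTases into families by protein identity, motif and taxon.

    ``similarity`` is a square symmetric DataFrame of pairwise identities in
    [0, 1].  Within each modification-type group (m6A vs m4C/m5C pooled),
    agglomerative clustering on distance 1 - identity is cut so that every
    within-family pair has identity >= ``identity_cutoff`` (complete linkage;
    pass ``linkage_method='single'`` for chained families).  Clusters are then
    subdivided so all members share a canonical motif and taxon.
    """
    ids = list(similarity.index)
    if list(similarity.columns) != ids:
        raise ValueError("similarity matrix index/columns mismatch")
    mat = similarity.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("similarity matrix must be symmetric")

    def group_of(mid: str) -> str:
        return "m6A" if mod_types[mid] == "m6A" else "m4C_m5C"

    families: list[FamilyCluster] = []
    for group in ("m6A", "m4C_m5C"):
        members = [m for m in ids if group_of(m) == group]
        if not members:
            continue
        if len(members) == 1:
            labels = {members[0]: 0}
        else:
            idx = [ids.index(m) for m in members]
            sub = mat[np.ix_(idx, idx)]
            dist = 1.0 - sub
            np.fill_diagonal(dist, 0.0)
            condensed = squareform(dist, checks=False)
            Z = linkage(condensed, method=linkage_method)
            assignments = fcluster(Z, t=1.0 - identity_cutoff, criterion="distance")
            labels = dict(zip(members, assignments))
        buckets: dict[tuple, list[str]] = {}
        for m in sorted(members):
            canon = min(motifs[m], reverse_complement(motifs[m]))
            key = (labels[m], canon, taxa[m])
            buckets.setdefault(key, []).append(m)
        for (cluster_id, canon, taxon), mids in sorted(buckets.items()):
            families.append(FamilyCluster(
                member_mtase_ids=sorted(mids), mod_type_group=group,
                shared_motif=canon, taxon_label=taxon))
    return families
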