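import itertools

import numpy as np
import pandas as pd
import pytest

from prokmethylome import (
    cluster_orphan_families,
    conservation_fraction,
    conserved_unmethylated_sites,
    is_potential_ortholog,
    reciprocal_best_hits,
    similarity_score,
)
from prokmethylome.calling import MethylationCall
from prokmethylome.conservation import flanking_genes
from prokmethylome.io_formats import GeneAnnotation
from prokmethylome.motifs import MotifInstance


class TestSimilarityScore:
    def test_self_hit_scores_hundred(self):
        assert similarity_score(250.0, 250.0) == pytest.approx(100.0)

    def test_linear_in_hit_bitscore(self):
        assert similarity_score(70.0, 200.0) == pytest.approx(35.0)

    def test_threshold_inclusive_at_35(self):
        assert is_potential_ortholog(35.0)
        assert not is_potential_ortholog(34.999)

    def test_nonpositive_self_score_rejected(self):
        with pytest.raises(ValueError):
            similarity_score(50.0, 0.0)


def _hits(mtase, species_scores):
    rows = [{"query": mtase, "species": sp, "bitscore_hit": s,
             "bitscore_self": 100.0} for sp, s in species_scores.items()]
    return pd.DataFrame(rows)


class TestConservationFraction:
    def test_exactly_half_is_not_conserved(self):
        taxonomy = {f"sp{i}": "GenusX" for i in range(10)}
        hits = _hits("mt1", {f"sp{i}": 80.0 for i in range(5)})
        call = conservation_fraction(hits, taxonomy, "mt1")
        assert call.fraction == pytest.approx(0.5)
        assert not call.conserved

    def test_just_over_half_is_conserved(self):
        taxonomy = {f"sp{i}": "GenusX" for i in range(10)}
        hits = _hits("mt1", {f"sp{i}": 80.0 for i in range(6)})
        assert conservation_fraction(hits, taxonomy, "mt1").conserved

    def test_large_group_fraction(self):
        # 121 of 156 species with an ortholog -> conserved, fraction ~0.776
        taxonomy = {f"sp{i}": "Haloarchaea" for i in range(156)}
        hits = _hits("mt1", {f"sp{i}": 60.0 for i in range(121)})
        call = conservation_fraction(hits, taxonomy, "mt1",
                                     taxon_level="class")
        assert call.n_species_with_ortholog == 121
        assert call.fraction == pytest.approx(121 / 156)
        assert call.conserved

    def test_subthreshold_hits_do_not_count(self):
        taxonomy = {f"sp{i}": "GenusX" for i in range(4)}
        scores = {"sp0": 90.0, "sp1": 34.9, "sp2": 34.9, "sp3": 34.9}
        call = conservation_fraction(_hits("mt1", scores), taxonomy, "mt1")
        assert call.n_species_with_ortholog == 1
        assert not call.conserved

    def test_species_missing_from_taxonomy_rejected(self):
        taxonomy = {"sp0": "GenusX"}
        with pytest.raises(ValueError, match="taxonomy"):
            conservation_fraction(_hits("mt1", {"sp1": 90.0}), taxonomy, "mt1")


def _score_table(pairs):
    return pd.DataFrame(
        [{"query": q, "subject": s, "bitscore": b} for q, s, b in pairs])


def rbh_oracle(ab, ba):
    """Brute-force mutual-unique-best over explicit pair lists."""
    out = {}
    queries = {q for q, _, _ in ab}
    for a in queries:
        a_hits = [(s, b) for q, s, b in ab if q == a]
        top = max(b for _, b in a_hits)
        best = [s for s, b in a_hits if b == top]
        if len(set(best)) != 1:
            continue
        b_star = best[0]
        b_hits = [(s, b) for q, s, b in ba if q == b_star]
        if not b_hits:
            continue
        top2 = max(b for _, b in b_hits)
        back = [s for s, b in b_hits if b == top2]
        if len(set(back)) == 1 and back[0] == a:
            out[a] = b_star
    return out


class TestReciprocalBestHits:
    def test_simple_mutual_pair(self):
        ab = _score_table([("a1", "b1", 100), ("a1", "b2", 50)])
        ba = _score_table([("b1", "a1", 95), ("b1", "a2", 40)])
        assert reciprocal_best_hits(ab, ba) == {"a1": "b1"}

    def test_non_mutual_excluded(self):
        ab = _score_table([("a1", "b1", 100)])
        ba = _score_table([("b1", "a2", 95), ("b1", "a1", 90)])
        assert reciprocal_best_hits(ab, ba) == {}

    def test_tied_best_disqualifies(self):
        ab = _score_table([("a1", "b1", 100), ("a1", "b2", 100)])
        ba = _score_table([("b1", "a1", 95), ("b2", "a1", 80)])
        assert reciprocal_best_hits(ab, ba) == {}

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(7)
        for trial in range(40):
            n_a, n_b = rng.integers(2, 7, size=2)
            ab, ba = [], []
            for i, j in itertools.product(range(n_a), range(n_b)):
                if rng.random() < 0.7:
                    ab.append((f"a{i}", f"b{j}", int(rng.integers(10, 60))))
                if rng.random() < 0.7:
                    ba.append((f"b{j}", f"a{i}", int(rng.integers(10, 60))))
            if not ab or not ba:
                continue
            got = reciprocal_best_hits(_score_table(ab), _score_table(ba))
            assert got == rbh_oracle(ab, ba)


def _gene(gid, start1, end1, contig="c1"):
    return GeneAnnotation(contig, start1, end1, "+", "CDS", gid)


class TestFlankingGenes:
    GENES = [_gene("g0", 101, 200), _gene("g1", 301, 400), _gene("g2", 501, 600)]

    def test_between_genes(self):
        assert flanking_genes(250, self.GENES, "c1") == ("g0", "g1")

    def test_before_first_gene(self):
        assert flanking_genes(50, self.GENES, "c1") == (None, "g0")

    def test_after_last_gene(self):
        assert flanking_genes(700, self.GENES, "c1") == ("g2", None)

    def test_other_contig_has_no_flanks(self):
        assert flanking_genes(250, self.GENES, "c9") == (None, None)


def _call(start, state="unmethylated", contig="c1"):
    inst = MotifInstance(contig, start, start + 4, "+",
                         meth_pos_fwd=start + 1, meth_pos_rev=start + 2)
    ip = 1.0 if state == "unmethylated" else 4.0
    return MethylationCall(inst, state, ip, ip, 50, 50)


class TestConservedSites:
    GENES_A = [_gene("a0", 101, 200), _gene("a1", 301, 400),
               _gene("a2", 501, 600)]
    GENES_B = [_gene("b0", 101, 200), _gene("b1", 301, 400),
               _gene("b2", 501, 600)]
    RBH = {"a0": "b0", "a1": "b1", "a2": "b2"}

    def test_identical_toy_genomes_all_sites_pair(self):
        calls_a = [_call(250), _call(450)]
        calls_b = [_call(250), _call(450)]
        pairs = conserved_unmethylated_sites(calls_a, calls_b, self.GENES_A,
                                             self.GENES_B, self.RBH)
        assert len(pairs) == 2
        assert [(a.instance.start, b.instance.start) for a, b in pairs] == \
            [(250, 250), (450, 450)]

    def test_site_in_different_gene_context_not_paired(self):
        pairs = conserved_unmethylated_sites(
            [_call(250)], [_call(450)], self.GENES_A, self.GENES_B, self.RBH)
        assert pairs == []

    def test_strand_flipped_context_pairs(self):
        # genome B is inverted: the RBH maps a0->b1 and a1->b0, so A's
        # (a0, a1) context appears in B as (b0, b1) with flipped roles
        rbh = {"a0": "b1", "a1": "b0"}
        pairs = conserved_unmethylated_sites(
            [_call(250)], [_call(250)], self.GENES_A, self.GENES_B, rbh)
        assert len(pairs) == 1

    def test_methylated_sites_ignored(self):
        pairs = conserved_unmethylated_sites(
            [_call(250, state="methylated")], [_call(250)],
            self.GENES_A, self.GENES_B, self.RBH)
        assert pairs == []

    def test_rbh_missing_for_flanks_no_pair(self):
        pairs = conserved_unmethylated_sites(
            [_call(250)], [_call(250)], self.GENES_A, self.GENES_B, rbh={})
        assert pairs == []


def _sim(ids, fill=0.1):
    mat = pd.DataFrame(fill, index=ids, columns=ids, dtype=float)
    np.fill_diagonal(mat.values, 1.0)
    return mat


class TestOrphanFamilies:
    def test_two_member_family_at_high_identity(self):
        ids = ["m1", "m2"]
        sim = _sim(ids)
        sim.loc["m1", "m2"] = sim.loc["m2", "m1"] = 0.9
        fams = cluster_orphan_families(
            sim, {"m1": "m6A", "m2": "m6A"},
            {"m1": "GATC", "m2": "GATC"}, {"m1": "T", "m2": "T"})
        (fam,) = fams
        assert fam.member_mtase_ids == ["m1", "m2"]
        assert fam.mod_type_group == "m6A"

    def test_low_identity_gives_singletons(self):
        ids = ["m1", "m2"]
        sim = _sim(ids)
        sim.loc["m1", "m2"] = sim.loc["m2", "m1"] = 0.30  # below 0.35
        fams = cluster_orphan_families(
            sim, {"m1": "m6A", "m2": "m6A"},
            {"m1": "GATC", "m2": "GATC"}, {"m1": "T", "m2": "T"})
        assert all(f.is_singleton for f in fams) and len(fams) == 2

    def test_identity_exactly_at_cutoff_joins(self):
        ids = ["m1", "m2"]
        sim = _sim(ids)
        sim.loc["m1", "m2"] = sim.loc["m2", "m1"] = 0.35
        fams = cluster_orphan_families(
            sim, {"m1": "m6A", "m2": "m6A"},
            {"m1": "GATC", "m2": "GATC"}, {"m1": "T", "m2": "T"})
        assert len(fams) == 1

    def test_mod_type_groups_never_mix(self):
        ids = ["m1", "m2"]
        sim = _sim(ids)
        sim.loc["m1", "m2"] = sim.loc["m2", "m1"] = 0.95
        fams = cluster_orphan_families(
            sim, {"m1": "m6A", "m2": "m5C"},
            {"m1": "GATC", "m2": "GATC"}, {"m1": "T", "m2": "T"})
        assert len(fams) == 2
        assert {f.mod_type_group for f in fams} == {"m6A", "m4C_m5C"}

    def test_motif_and_taxon_subdivide_clusters(self):
        ids = ["m1", "m2", "m3"]
        sim = _sim(ids, fill=0.9)
        fams = cluster_orphan_families(
            sim, {m: "m6A" for m in ids},
            {"m1": "GATC", "m2": "GATC", "m3": "CCWGG"},
            {"m1": "T", "m2": "T", "m3": "T"})
        sizes = sorted(len(f.member_mtase_ids) for f in fams)
        assert sizes == [1, 2]

    def test_motif_compared_canonically(self):
        ids = ["m1", "m2"]
        sim = _sim(ids, fill=0.9)
        fams = cluster_orphan_families(
            sim, {m: "m6A" for m in ids},
            {"m1": "GGATC", "m2": "GATCC"},  # reverse complements
            {"m1": "T", "m2": "T"})
        assert len(fams) == 1

    def test_planted_blocks_recovered(self):
        # two 6-member blocks at identity 0.8 inside, 0.05 between
        ids = [f"m{i}" for i in range(12)]
        sim = _sim(ids, fill=0.05)
        for block in (ids[:6], ids[6:]):
            for a, b in itertools.combinations(block, 2):
                sim.loc[a, b] = sim.loc[b, a] = 0.8
        fams = cluster_orphan_families(
            sim, {m: "m6A" for m in ids},
            {m: "GATC" for m in ids}, {m: "T" for m in ids})
        members = sorted(tuple(f.member_mtase_ids) for f in fams)
        assert members == [tuple(sorted(ids[:6])), tuple(sorted(ids[6:]))]

    def test_complete_linkage_rejects_chained_family(self):
        # m1-m2 and m2-m3 similar but m1-m3 dissimilar: complete linkage
        # cannot hold all three in one family
        ids = ["m1", "m2", "m3"]
        sim = _sim(ids)
        for a, b in (("m1", "m2"), ("m2", "m3")):
            sim.loc[a, b] = sim.loc[b, a] = 0.5
        fams = cluster_orphan_families(
            sim, {m: "m6A" for m in ids},
            {m: "GATC" for m in ids}, {m: "T" for m in ids})
        assert max(len(f.member_mtase_ids) for f in fams) <= 2

    def test_asymmetric_matrix_rejected(self):
        ids = ["m1", "m2"]
        sim = _sim(ids)
        sim.loc["m1", "m2"] = 0.9  # not mirrored
        with pytest.raises(ValueError, match="symmetric"):
            cluster_orphan_families(
                sim, {m: "m6A" for m in ids},
                {m: "GATC" for m in ids}, {m: "T" for m in ids})
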