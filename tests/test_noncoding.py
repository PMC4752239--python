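import numpy as np
import pytest
from scipy.stats import binom

from prokmethylome import (
    GeneAnnotation,
    GenomeRecord,
    PipelineConfig,
    density_profile,
    extract_noncoding_regions,
    local_motif_density,
    match_clusters_across_genomes,
    noncoding_enrichment_scan,
)
from prokmethylome.motifs import MotifInstance
from prokmethylome.noncoding import NoncodingRegionStat
from prokmethylome.regulatory import Region, RegionSet


def _inst(start, L=4):
    return MotifInstance("c1", start, start + L, "+", meth_pos_fwd=start + 1,
                         meth_pos_rev=start + 2)


def _gene(start1, end1, ftype="CDS", gid="g"):
    return GeneAnnotation("c1", start1, end1, "+", ftype, gid)


class TestExtractNoncoding:
    GENOME = GenomeRecord("c1", "A" * 1000)

    def test_simple_complement(self):
        genes = [_gene(101, 300), _gene(501, 700)]
        regions = sorted(extract_noncoding_regions(genes, self.GENOME),
                         key=lambda r: r.start)
        assert [(r.start, r.end) for r in regions] == \
            [(0, 100), (300, 500), (700, 1000)]

    def test_overlapping_genes_merged(self):
        genes = [_gene(101, 400), _gene(301, 600)]
        regions = sorted(extract_noncoding_regions(genes, self.GENOME),
                         key=lambda r: r.start)
        assert [(r.start, r.end) for r in regions] == [(0, 100), (600, 1000)]

    def test_rna_features_count_as_coding(self):
        genes = [_gene(1, 500), _gene(601, 1000, ftype="RNA")]
        regions = sorted(extract_noncoding_regions(genes, self.GENOME),
                         key=lambda r: r.start)
        assert [(r.start, r.end) for r in regions] == [(500, 600)]

    def test_no_genes_whole_contig(self):
        (r,) = extract_noncoding_regions([], self.GENOME)
        assert (r.start, r.end) == (0, 1000)

    def test_per_base_oracle(self):
        rng = np.random.default_rng(0)
        genes = []
        for i in range(30):
            s = int(rng.integers(1, 950))
            genes.append(_gene(s, min(1000, s + int(rng.integers(5, 60)))))
        regions = extract_noncoding_regions(genes, self.GENOME)
        coding = np.zeros(1000, dtype=bool)
        for g in genes:
            coding[g.start0: g.end0] = True
        noncoding = np.zeros(1000, dtype=bool)
        for r in regions:
            assert not coding[r.start: r.end].any()
            noncoding[r.start: r.end] = True
        assert np.array_equal(noncoding, ~coding)


class TestLocalDensity:
    def _region_set(self, bounds):
        return RegionSet([Region("c1", lo, hi, label=f"nc{i}")
                          for i, (lo, hi) in enumerate(bounds)])

    def test_simple_flanking_density(self):
        # focal region 1; flanks 0 and 2 hold 50 motifs over 10,000 bp
        bounds = [(0, 5000), (6000, 6100), (7000, 12000)]
        rs = self._region_set(bounds)
        inst = [_inst(10 * i) for i in range(25)]            # region 0
        inst += [_inst(7000 + 10 * i) for i in range(25)]    # region 2
        density, n_used = local_motif_density(1, rs, inst)
        assert density == pytest.approx(50 / 10_000)
        assert n_used == 2

    def test_focal_region_excluded(self):
        bounds = [(0, 1000), (2000, 3000), (4000, 5000)]
        rs = self._region_set(bounds)
        inst = [_inst(2000 + 10 * i) for i in range(50)]  # all in the focal
        density, _ = local_motif_density(1, rs, inst)
        assert density == 0.0

    def test_window_limited_to_fifty_per_side(self):
        bounds = [(200 * i, 200 * i + 100) for i in range(200)]
        rs = self._region_set(bounds)
        _, n_used = local_motif_density(100, rs, [])
        assert n_used == 100  # 50 per side

    def test_edge_region_uses_available_side(self):
        bounds = [(0, 100), (200, 300), (400, 500)]
        rs = self._region_set(bounds)
        _, n_used = local_motif_density(0, rs, [])
        assert n_used == 2  # nothing to the left

    def test_single_region_rejected(self):
        rs = self._region_set([(0, 100)])
        with pytest.raises(ValueError):
            local_motif_density(0, rs, [])


class TestEnrichmentScan:
    def _scan_setup(self, focal_count):
        # 21 regions of 1000 bp; background 5 motifs each; focal (index 10)
        # gets focal_count
        bounds = [(2000 * i, 2000 * i + 1000) for i in range(21)]
        rs = RegionSet([Region("c1", lo, hi, label=f"nc{i}")
                        for i, (lo, hi) in enumerate(bounds)])
        inst = []
        for i, (lo, _) in enumerate(bounds):
            k = focal_count if i == 10 else 5
            inst += [_inst(lo + 20 * j) for j in range(k)]
        return rs, inst

    def test_binomial_tail_matches_pmf_summation(self):
        rs, inst = self._scan_setup(focal_count=30)
        stats = noncoding_enrichment_scan(rs, inst)
        focal = next(s for s in stats if s.region.label == "nc10")
        density = 5 / 1000  # 20 flanking regions, 5 each
        assert focal.local_density == pytest.approx(density)
        oracle = sum(binom.pmf(x, 1000, density) for x in range(30, 1001))
        assert focal.p_raw == pytest.approx(oracle, rel=1e-9)
        assert focal.p_bonferroni == pytest.approx(min(1.0, oracle * 21))

    def test_default_tail_includes_observed_count(self):
        # default p = P(X >= obs); strict variant p = P(X > obs)
        rs, inst = self._scan_setup(focal_count=30)
        default = noncoding_enrichment_scan(rs, inst)
        strict = noncoding_enrichment_scan(
            rs, inst, PipelineConfig(noncoding_strict_tail=True))
        f_def = next(s for s in default if s.region.label == "nc10")
        f_str = next(s for s in strict if s.region.label == "nc10")
        assert f_str.p_raw < f_def.p_raw
        assert f_def.p_raw - f_str.p_raw == pytest.approx(
            binom.pmf(30, 1000, 5 / 1000), rel=1e-9)

    def test_planted_dense_region_flagged_alone(self):
        rs, inst = self._scan_setup(focal_count=40)
        stats = noncoding_enrichment_scan(rs, inst)
        sig = [s for s in stats if s.significant]
        assert [s.region.label for s in sig] == ["nc10"]

    def test_uniform_density_not_significant(self):
        rs, inst = self._scan_setup(focal_count=5)
        stats = noncoding_enrichment_scan(rs, inst)
        assert not any(s.significant for s in stats)
        focal = next(s for s in stats if s.region.label == "nc10")
        assert focal.fold == pytest.approx(1.0)

    def test_observed_counts_match_recount_oracle(self):
        rng = np.random.default_rng(5)
        bounds = [(2000 * i, 2000 * i + int(rng.integers(200, 1500)))
                  for i in range(15)]
        rs = RegionSet([Region("c1", lo, hi, label=f"nc{i}")
                        for i, (lo, hi) in enumerate(bounds)])
        inst = [_inst(int(p)) for p in
                np.sort(rng.choice(30_000 - 4, size=400, replace=False))]
        stats = noncoding_enrichment_scan(rs, inst)
        for s in stats:
            expected = sum(1 for i in inst
                           if i.start < s.region.end and i.end > s.region.start)
            assert s.observed == expected

    def test_empty_region_set(self):
        assert noncoding_enrichment_scan(RegionSet(), [_inst(0)]) == []


class TestDensityProfile:
    def test_default_geometry_gives_991_windows(self):
        genome = GenomeRecord("c1", "A" * 200_000)
        prof = density_profile(genome, [], anchor=100_000)
        assert len(prof.window_starts) == 991
        assert prof.window_starts[0] == 100_000 - 25_000
        assert prof.window_starts[1] - prof.window_starts[0] == 50

    def test_span_clipped_at_contig_start(self):
        genome = GenomeRecord("c1", "A" * 60_000)
        prof = density_profile(genome, [], anchor=0)
        # span [0, 25000): (25000-500)//50 + 1 = 491 windows
        assert len(prof.window_starts) == 491

    def test_window_counts_match_recount(self):
        rng = np.random.default_rng(2)
        genome = GenomeRecord("c1", "A" * 100_000)
        inst = [_inst(int(p)) for p in
                np.sort(rng.choice(100_000 - 4, size=500, replace=False))]
        prof = density_profile(genome, inst, anchor=50_000)
        for w, c in zip(prof.window_starts[::100], prof.densities[::100]):
            expected = sum(1 for i in inst
                           if i.start < w + prof.window_bp and i.end > w)
            assert c == expected

    def test_planted_cluster_peaks_at_anchor(self):
        genome = GenomeRecord("c1", "A" * 100_000)
        inst = [_inst(50_000 + 8 * j) for j in range(30)]
        inst += [_inst(p) for p in range(0, 45_000, 3000)]
        prof = density_profile(genome, inst, anchor=50_100)
        peak = prof.window_starts[np.argmax(prof.densities)]
        assert abs(peak + prof.window_bp // 2 - 50_120) < 500


class TestMatchAcrossGenomes:
    def _stat(self, label, significant=True):
        return NoncodingRegionStat(
            region=Region("c", 0, 100, label=label), observed=10,
            local_density=0.001, expected=0.1, fold=100, p_raw=1e-9,
            p_bonferroni=1e-8, significant=significant)

    def test_direct_flank_match(self):
        a = [self._stat("ncA")]
        b = [self._stat("ncB")]
        pairs = match_clusters_across_genomes(
            a, b, {"ncA": ("g1", "g2")}, {"ncB": ("h1", "h2")},
            rbh={"g1": "h1", "g2": "h2"})
        assert len(pairs) == 1

    def test_strand_flipped_match(self):
        a = [self._stat("ncA")]
        b = [self._stat("ncB")]
        pairs = match_clusters_across_genomes(
            a, b, {"ncA": ("g1", "g2")}, {"ncB": ("h2", "h1")},
            rbh={"g1": "h1", "g2": "h2"})
        assert len(pairs) == 1

    def test_unrelated_flanks_do_not_match(self):
        a = [self._stat("ncA")]
        b = [self._stat("ncB")]
        pairs = match_clusters_across_genomes(
            a, b, {"ncA": ("g1", "g2")}, {"ncB": ("h3", "h4")},
            rbh={"g1": "h1", "g2": "h2"})
        assert pairs == []

    def test_insignificant_regions_ignored(self):
        a = [self._stat("ncA", significant=False)]
        b = [self._stat("ncB")]
        pairs = match_clusters_across_genomes(
            a, b, {"ncA": ("g1", "g2")}, {"ncB": ("h1", "h2")},
            rbh={"g1": "h1", "g2": "h2"})
        assert pairs == []


class TestEndToEndOriRecovery:
    def test_planted_origin_cluster_found(self):
        from prokmethylome.model import MethylomeModel
        from prokmethylome.simulate import build_scenario

        bundle = build_scenario("ori_cluster", seed=0)
        res = MethylomeModel.from_bundle(bundle).fit()
        stats = res.noncoding_scan()
        sig = [s for s in stats if s.significant]
        assert len(sig) == 1
        lo, hi = bundle.ori_region
        assert sig[0].region.start <= lo and sig[0].region.end >= hi
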