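# prokmethylome

Analysis of prokaryotic DNA methylomes from single-molecule sequencing
kinetics.

Single-molecule real-time (SMRT) sequencing reports, for every genomic
position and strand, an inter-pulse duration ratio (ipdR): the delay in base
incorporation relative to an unmodified control. Methylated bases (m6A, m4C
and — weakly — m5C) elevate the ipdR, so a genome's methylation landscape can
be read directly from its kinetics. In bacteria and archaea nearly every
occurrence of a methyltransferase (MTase) recognition motif is methylated; the
rare **unmethylated** motif instances are the interesting ones, because they
mark sites where a bound protein blocked the MTase — a signature of regulatory
activity concentrated in gene-regulatory regions and at replication origins.

`prokmethylome` implements that analysis end to end:

- **Motif scanning** — degenerate (IUPAC) recognition motifs located on both
  strands, overlap-aware, with palindrome detection and a motif-architecture
  classifier (Type I bipartite / Type II palindromic / Type III-like /
  Type IIG-like).
- **Methylation calling** — per-motif ipdR thresholds derived from trimmed
  central means of motif and non-motif positions; each instance is called
  `methylated`, `unmethylated`, `ambiguous` or `low_coverage` using evidence
  from **both strands** at ≥ 20-fold coverage.
- **Regulatory enrichment** — unmethylated sites tested against regulatory
  regions (100 bp upstream to 50 bp downstream of CDS starts) with Fisher's
  exact test, composition-matched resampling for motif placement, COG-category
  subsets and TFBS overlap.
- **Cluster statistics** — runs of ≥ 3 adjacent unmethylated motifs closer
  than the genome-wide mean inter-motif distance, with a 10,000-iteration
  permutation p-value (and an exact enumeration oracle for small inputs).
- **Non-coding scan** — binomial test of motif density per non-coding region
  against the locally estimated background (100 flanking regions), Bonferroni
  corrected; dense clusters in single intergenic regions are the classic
  replication-origin signature. Density profiles (500 bp windows, 50 bp step,
  50 kb span) visualise it.
- **Annotation matching & conservation** — motif-to-MTase attribution under a
  uniqueness rule, orphan-vs-RM classification, bitscore-ratio ortholog
  scoring, reciprocal best hits, conserved unmethylated sites and orphan-MTase
  family clustering.
- **Synthetic data** — a generator of complete input bundles (genome, GFF3
  annotation, kinetics, motif list, ground truth) under a lognormal/Poisson
  kinetic model, with presets for the main study conditions.

The package is organised around a statsmodels-style pair of objects:
`MethylomeModel` (data + configuration) and `MethylomeResults`
(estimates, diagnostics, `summary()`), with a `prokmethylome` CLI on top.

## Worked example

Simulate an orphan-MTase scenario (200 kb genome, 500 GATC instances, 20 of
them unmethylated with a regulatory bias), fit the model, and test the
regulatory enrichment:

```python
from prokmethylome.simulate import build_scenario
from prokmethylome.model import MethylomeModel

bundle = build_scenario("orphan_regulatory", seed=7, out_dir="demo")
results = MethylomeModel.from_bundle(bundle).fit()
print(results.summary())
```

```
Methylome fit
============================================================
contig             synthetic_contig (200,000 bp)
motif              GATC (m6A, TypeII_palindromic)
instances          500
avg motif ipdR     3.997
avg non-motif ipdR 1.000
under-meth thr     1.300
methylated thr     2.498
------------------------------------------------------------
       state  count  fraction  median_coverage
  methylated    480    0.9600          60.0000
unmethylated     20    0.0400          60.5000
   ambiguous      0    0.0000              NaN
low_coverage      0    0.0000              NaN
```

All 20 planted unmethylated sites are recovered with no false positives.
Are they where regulation happens?

```python
enr = results.unmethylated_enrichment()
print(f"{enr.n_in}/{enr.n_total} in regulatory regions "
      f"vs {100*enr.background_fraction:.1f}% of methylated sites; "
      f"fold = {enr.fold:.2f}, Fisher p = {enr.p_value:.2e}")
```

```
12/20 in regulatory regions vs 9.4% of methylated sites; fold = 6.40, Fisher p = 9.77e-08
```

The replication-origin signature works the same way — a planted cluster of 20
extra motifs in one 600 bp intergenic region is picked out of ~150 non-coding
regions:

```python
bundle = build_scenario("ori_cluster", seed=7)
results = MethylomeModel.from_bundle(bundle).fit()
for s in results.noncoding_scan():
    if s.significant:
        print(s.region.label, s.observed, f"{s.p_bonferroni:.2e}")
```

```
nc19 22 8.41e-13
```

(The planted cluster spans positions 26,546–27,146; region `nc19` covers
26,199–27,368.)

The same pipeline runs from files on disk:

```bash
prokmethylome simulate --preset orphan_regulatory --seed 7 --out-dir demo
prokmethylome all --fasta demo/genome.fasta --gff3 demo/annotation.gff3 \
    --kinetics demo/kinetics.csv --motifs demo/motifs.tsv --out-dir demo/run
```

which writes per-motif call tables, unmethylated-site BED files, enrichment
and cluster tables, the non-coding scan, and a `run_summary.json` with input
checksums and the fitted thresholds.

## Reproduction

- `pytest` runs the full suite, including an acceptance module covering the
  package's core guarantees (worked examples, oracle equivalence of
  every statistical primitive, parameter recovery, null calibration,
  origin-signature recovery, structural constants).
- `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  recomputes the headline quantities and writes them as JSON: the three
  worked-example values (99.9% methylated; 61% of unmethylated sites in
  regulatory regions, 4.67-fold; 20.83-fold upstream of transcriptional
  regulators), unmethylated-call sensitivity/precision and enrichment
  detection rate over 20 simulated genomes, null calibration rates, the
  origin-cluster recovery rate, and the 991-window density-profile constant.

All simulations are seeded and deterministic; `docs/methods.md` documents the
statistical model, the synthetic-data generator and its deliberate
simplifications.
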