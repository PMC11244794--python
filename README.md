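# coldspot-atlas

Crossover detection and recombination-coldspot cataloguing for
pooled-gamete linked-read sequencing of interspecific hybrids.

## The problem

Breeders introgress alleles from wild relatives into crops through
meiotic recombination. Genomic regions without crossovers (COs) —
*recombination coldspots* — trap whole groups of genes in fixed linkage
("linkage drag"), so a map of where each hybrid cross can and cannot
recombine is directly actionable: it tells a breeder which parental
combination can break an undesirable linkage. Pooled-pollen linked-read
sequencing makes such maps cheap: each long DNA molecule comes from one
gamete, and a single haplotype switch along a phased molecule localizes
one CO between two flanking SNP markers.

`coldspot-atlas` implements the full downstream analysis:

1. **CO calling** — phased molecules are segmented into haplotype
   blocks; a molecule with exactly two blocks yields one CO with
   *resolution* = 1/(distance between the bounding markers). Filters:
   markers/reads per block, molecule span (multiple molecules can share
   a droplet barcode), wildcard fraction, and a resolution cutoff
   (default: distance < 1 kb, i.e. resolution > 0.001 bp⁻¹).
2. **CO regions and coldspots** — CO counts in 10 kb sliding windows
   (5 kb step); windows with ≥ 1 CO merged within 1 kb form CO regions;
   CO-free complement gaps ≥ 1 Mb that still contain SNP markers are the
   hybrid's coldspots.
3. **Cross-hybrid clustering** — coldspots of all hybrids are grouped at
   ≥ 1 bp overlap, connected at ≥ 50% reciprocal overlap, and loosely
   spanning components (span ≥ 1.5× the smallest member) are refined by
   complete-linkage hierarchical clustering on
   d(i,j) = (f − 2·|i∩j|)/(f − |i∩j|) with f = |i|+|j| (equal to
   1 − Jaccard), cutting the dendrogram at 0.3. Clusters present in one
   hybrid are *unique*, in ≥ 2 *shared*; base pairs coldspot in every
   hybrid are *conserved* coldspots.
4. **SV filtering** — wild-parent SVs re-observed in the F1 pollen pool
   (same type, ≥ 50% reciprocal overlap) are *parental SVs*; DEL/INV
   calls not overlapping reference self-SV artifacts are retained, with
   size classes ≥ 50 bp, > 1 kb (analysis set) and INV > 30 kb.
5. **Association statistics** — length-preserving permutation tests
   (default 10,000 shuffles) of CO overlap with TEs, SVs, genes and
   accessible-chromatin regions (z-score sign = enrichment/suppression);
   Fisher's exact test of window co-occupancy between hybrids; Spearman
   correlation of CO counts in 500 kb/50 kb sliding windows; Gaussian
   kernel CO density (bandwidth 100 kb); Marey-map derivative (cM/Mb).
6. **Gene annotation** — single-label CO assignment over gene features
   (exon > UTR > intron > 1 kb flanks > intergenic), distance-to-gene
   bands, and coldspot gene groups (≥ 20 genes) with trait-gene
   enrichment.

A first-class synthetic-data module (`synthetic_data`) generates
complete corpora — genome with pericentromere (PER) / distal euchromatin
(DEU) compartments, markers, molecules with planted COs, TE/gene/ACR
tracks, and three SV call sets with exactly known filter outcome — so
every stage is testable with known ground truth.

## Worked example

```python
from coldspot_atlas import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(outdir="results", seed=1, n_perm=1000))
print(summary["clusters"])
print(summary["per_hybrid"][["hybrid", "n_cos", "co_region_fraction", "n_coldspots"]])
```

which prints (seed 1, default five-hybrid corpus):

```
{'unique': 54, 'shared': 23}
  hybrid  n_cos  co_region_fraction  n_coldspots
0     PM   1041            0.146500           22
1     NE    983            0.143000           21
2     CH    995            0.142222           25
3     HB    994            0.145333           20
4     PN   1006            0.145111           20
```

Each hybrid's ~1,000 COs (of 10,000 molecules at CO rate 0.1) condense
into CO regions covering ~14% of the 90 Mb synthetic genome; the CO-free
complement yields 20–25 coldspots ≥ 1 Mb per hybrid, which cluster into
54 unique and 23 shared cross-hybrid clusters. The run log (`results/run.log`)
reports per-stage counts, and `results/te_enrichment.tsv` the permutation
z-scores: strongly negative for the PER-biased retrotransposon tracks
(Gypsy, Copia) and SVs, positive for the DEU DNA-transposon track, genes
and ACRs — the planted structure.

The same stages are available from the shell:

```bash
coldspot-atlas simulate --seed 1 --outdir corpus/
coldspot-atlas call-co --molecules corpus/molecules_PM.tsv --hybrid PM --out PM
coldspot-atlas coldspots --events PM.tsv --genome corpus/genome.tsv \
    --per-bed corpus/per.bed --markers corpus/markers_PM.tsv --out PM
coldspot-atlas run --seed 1 --outdir results/
```

## Layout

```
src/coldspot_atlas/
  genome_model.py        # intervals, genome layout, merge/intersect/shuffle/...
  synthetic_data.py      # corpus generator with planted truth
  crossover_detection.py # molecule phasing blocks -> CO events + filters
  coldspot_catalog.py    # CO regions, coldspots, clustering, Marey rate
  sv_filtering.py        # parental-SV derivation and size classes
  enrichment_stats.py    # permutation/Fisher/Spearman/KDE statistics
  feature_annotation.py  # gene features, coldspot gene groups
  pipeline.py, cli.py    # orchestration, manifest, command line
docs/methods.md          # model, parameters, design choices, limitations
scripts/acceptance.py    # recompute headline quantities as JSON
```
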