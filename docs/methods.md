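# Methods

This note documents the models and procedures implemented in
`coldspot-atlas`, the parameters that matter, what the synthetic corpus
does and does not emulate, and the design choices made where the
procedure left room for interpretation.

## Coordinates and the interval engine

All coordinates are 0-based, half-open (BED convention) internally;
GFF3 and VCF are converted on read/write. The interval engine
(`genome_model`) provides merge (with a gap tolerance), intersection,
subtraction, coverage, sliding windows, reciprocal overlap,
length-preserving random placement, and signed nearest-feature
distances. Its semantics follow the corresponding bedtools subcommands:
`makewindows` emits a window for every start below the chromosome
length and clips the last windows; `shuffle` places each interval
uniformly over all genome-wide start positions that fit it (chromosome
drawn with probability proportional to its number of fitting starts),
with a same-chromosome mode and an allowed-regions restriction as
options. "No neighbor" is reported as NaN, never as a sentinel
magnitude. The whole engine is property-tested against a per-base
boolean-array oracle on thousands of random toy genomes.

## Crossover calling

A phased molecule is an ordered run of per-marker haplotype calls
(A, B, or `?` for ambiguous). Calls are segmented into maximal
same-haplotype blocks; wildcards belong to no block. A crossover is
reported iff the molecule has exactly two blocks. Molecules with three
or more blocks are discarded whole: at this resolution a double switch
is indistinguishable from a gene-conversion tract or phasing noise, and
the single-CO molecule model is what the pooled-gamete design supports.
The CO interval is `[last marker of block 1, first marker of block 2)`;
its **resolution** is 1/distance between those markers.

Filter parameters (`CoFilterParams`):

| parameter | default | unit | role |
|---|---|---|---|
| `min_resolution` | 0.001 | bp⁻¹ | keep COs localized to < 1 kb; a 0.002 grade exists for motif-level work |
| `max_molecule_span` | 200,000 | bp | reject barcode chimeras (two molecules in one droplet) |
| `min_markers_per_block` | 3 | markers | both flanking blocks must be multiply supported |
| `min_reads_per_block` | 2 | reads | read support per flanking block |
| `max_wildcard_fraction` | 0.1 | — | reject poorly phased molecules |

Boundary semantics are strict: "distance below 1 kb" means < 1000 bp,
equivalently resolution > 0.001; the two phrasings agree only under
strict inequality, which is why strictness was chosen. The block-level
defaults (3 markers, 2 reads, 10% wildcards) are this package's own
operating points, config-exposed and logged with every run. Events from
distinct molecules at the same interval are kept separate — a pollen
pool samples independent meioses.

## CO regions and coldspots

CO counts are taken in 10 kb sliding windows with 5 kb step; windows
with ≥ 1 overlapping CO are merged when separated by ≤ 1 kb, giving the
CO regions. Per chromosome, the complement of the CO regions, clipped
to `[0, L)`, is scanned for gaps ≥ 1 Mb. Terminal gaps count: large
pericentromere-spanning coldspots require it. A gap containing zero
segregating markers is *not* catalogued (absence of COs cannot be
distinguished from absence of markers there) but is written to a side
table. Every catalogued coldspot records its marker count and its
DEU/PER base-pair split.

## Cross-hybrid clustering

Coldspots from all hybrids are clustered in three stages:

1. transitive grouping at ≥ 1 bp overlap (a sweep per chromosome);
2. within each group, a graph with edges at reciprocal overlap ≥ 0.5
   (reciprocal overlap = min of the two mutual overlap fractions);
   connected components are taken;
3. for each component, the span `p = max(end) − min(start)` is compared
   with 1.5× the smallest member's length. Wide components are
   re-clustered by complete-linkage hierarchical clustering on
   `d(i,j) = (f − 2I)/(f − I)` (f = |i|+|j|, I = |i∩j|; algebraically
   1 − Jaccard), cutting the dendrogram so that merges with linkage
   distance < 0.3 survive; narrow components stay single clusters.

Design choices: the component "distance between the leftmost and
rightmost coldspot" is read as the span `max(end) − min(start)` — the
only monotone, membership-stable reading; the cut "at height 0.3" keeps
merges strictly below 0.3 (implemented via the largest float below 0.3
as the `fcluster` threshold); members are canonically sorted before
linkage, so clustering is deterministic and invariant to input order
(property-tested). A cluster whose members come from one hybrid is
*unique*, otherwise *shared*.

**Conserved coldspots** are computed independently of clustering as the
direct base-pair intersection of the per-hybrid coldspot sets, with all
intersection fragments retained (including sub-Mb ones), and reported
with a DEU/PER split.

## SV filtering

Three call sets against the same reference enter: wild-inbred SVs, F1
pollen SVs, and reference self-SVs (assembly artifacts). An inbred SV
is *parental* iff a pollen SV of the same type reaches 50% reciprocal
overlap — the matching rule is not dictated by the calling protocol, so
the community-standard SV concordance criterion (same type, RO ≥ 0.5)
was adopted; breakpoint-tolerance matching is available as an
alternative. Parental DEL/INV calls with zero-bp overlap against any
self SV are retained ("do not overlap" read strictly). Size classes:
detection ≥ 50 bp; analysis > 1 kb (strict, literal reading of "larger
than 1 kb"); INV report > 30 kb. Other SV types pass through readers as
`type="other"` for reporting but never into the retained set.

## Association statistics

* **Permutation enrichment**: observed = number of CO intervals with
  ≥ 1 bp feature overlap (the counting unit is the event, not
  overlapped bp); null = the same count over n length-preserving
  shuffles (default n = 10,000). Reported: z = (obs − mean)/sd, a
  two-sided empirical p with pseudo-count (r+1)/(n+1) (never zero), and
  a normal-tail p for tail magnitudes beyond empirical reach.
  A feature set covering the whole genome makes the null degenerate
  (sd = 0); this is flagged, not silently divided.
* **Compartment-restricted gene enrichment**: COs overlapping the
  compartment are tested against gene spans ± 1 kb with shuffles placed
  inside the compartment only; COs wider than every allowed slot are
  clipped to their compartment overlap before shuffling.
* **Cross-hybrid overlap**: the genome is tiled into 10 kb windows
  (matching the CO-region window scale; configurable), each window
  scored for CO presence per hybrid, and the 2×2 window table tested
  two-sided with Fisher's exact test; `shared_fraction` = windows with
  both / windows with either.
* **Landscape**: CO counts in 500 kb windows, 50 kb step, concatenated
  genome-wide, compared across hybrids by Spearman rank correlation.
  The CO density track is a Gaussian kernel sum with bandwidth 100 kb
  evaluated on a 10 kb grid, scaled so the per-chromosome integral
  equals the CO count ("binwidth" of an R `density()` call is read as
  the kernel bandwidth — the only parameter the phrase can denote).
* **Distances**: signed CO-to-nearest-SV distances (positive =
  downstream), histogrammed against a shuffled null band.
* Multiple testing across TE superfamilies uses Benjamini–Hochberg on
  the empirical p-values; raw and adjusted values are both reported.

## Gene-feature annotation

Gene models carry strand-aware 1 kb flanks from TSS/TTS. The exon track
excludes UTR bases so the single-label priority
exon > UTR > intron > upstream > downstream > intergenic is attainable
for every class. COs spanning several genes keep the highest-priority
label and a multi-gene flag. Distance bands partition COs into
within ±1 kb of a gene, 1–3 kb, and beyond (any-bp overlap; a midpoint
mode exists). Genes overlapping a coldspot by ≥ 1 bp form its gene set;
sets of ≥ 20 genes are coldspot gene groups; trait annotations come
from an external two-column table and are tested for enrichment among
coldspot genes with Fisher's exact test.

## The synthetic corpus

The generator (`synthetic_data`) emulates the statistical structure of
the real experiment at test scale; defaults (the study conditions):

* genome: 3 chromosomes × 30 Mb; centered PER block covering 60% of
  each chromosome (pericentromeric heterochromatin dominates these
  genomes);
* markers: Poisson-placed at 1.0/kb (DEU) and 0.5/kb (PER) per hybrid;
* molecules: 10,000 per hybrid; log-normal lengths (mean 50 kb,
  sd 40 kb, truncated at 200 kb — long-tailed linked-read molecule
  sizes); reads per marker 1 + Poisson(1);
* COs: 10% of molecules carry exactly one CO. The CO position is drawn
  over inter-marker gaps with weight = compartment rate × multipliers ×
  gap length, where the DEU:PER weight share is 0.9:0.1 (≈ the ~90/10
  distal/pericentromeric CO split of such maps), genes multiply the
  rate by 3 (genic CO preference), TE tracks by their own factor
  (Gypsy 0.2 and Copia 0.3, PER-biased; Stowaway 2.0, DEU-biased), SVs
  > 1 kb by 0.05 (strong heterozygous-SV suppression), and planted
  coldspot blocks by 0. Multipliers apply to any gap overlapping the
  feature, so planted COs never straddle a suppressed or blocked edge.
  Each recombinant molecule is built around its CO with ≥ 3 markers on
  both sides, so the planted event is recoverable exactly;
* coldspot structure: 2 shared + 1 hybrid-unique CO-free 2 Mb blocks
  planted in DEU per hybrid (PER coldspots arise naturally from the low
  PER rate), placed uniformly over the remaining free DEU space;
* SVs: 250 per hybrid, 61% in DEU (the ~1.55:1 DEU:PER count contrast),
  log-normal lengths with median 4 kb (DEU) / 10 kb (PER) — PER SVs are
  planted longer; 75% DEL, 5% non-DEL/INV "other"; 80% re-observed in
  the pollen set with breakpoint jitter < 20% of length (keeping
  reciprocal overlap ≥ 0.5 by construction); 10% of parental SVs get an
  overlapping self SV. The expected output of the full SV filter is
  therefore known exactly and asserted as set algebra;
* features: 3,000 genes (85% DEU) with exon/UTR structure; 2,000 ACRs
  of mean length 733 bp, 70% placed at gene TSSs; TE tracks with hard
  compartment bias;
* noise: per-marker wildcard and flip rates and a double-switch
  contaminant rate exist but default to 0 — noise-free defaults keep
  planted-truth recovery exact, and the noise paths are exercised
  explicitly in tests.

All randomness derives from one seed through named `SeedSequence`
sub-streams, so a corpus is bit-reproducible.

What the corpus does **not** emulate: read-level data (no FASTQ,
barcodes, or alignment), sequence content, empirical molecule-length
and phasing-noise distributions (order-of-magnitude stand-ins only),
chromosome-size variation, marker ascertainment structure, and complex
SVs (translocations/duplications appear only as `other`-typed
pass-throughs). Passing tests therefore demonstrate the correctness of
the pipeline's logic and calibration of its statistics under the
planted model, not end-to-end performance on real libraries.

## Numerical and degenerate-input choices

* All tie-breaks deterministic: canonical sorting before clustering;
  stable window enumeration; seeds recorded in the run manifest.
* `fcluster` threshold `nextafter(0.3, 0)` implements the strict cut.
* Degenerate statistics (empty CO sets, whole-genome features, constant
  window vectors) are flagged (`degenerate`, NaN) rather than raised,
  except where the input is unusable (empty feature set).
* Molecules with < 2 informative markers are kept but unusable, counted
  under their own rejection reason.
* The pipeline's end-to-end determinism (byte-identical catalogues for
  identical config + seed) is asserted in the test suite.

## Problem sizes used by the test suite

The standard test corpus is 5 hybrids × 3 chromosomes × 12 Mb with
3,000 molecules each; directional-recovery checks run one hybrid at the
full default scale (3 × 30 Mb, 10,000 molecules) with 1,000
permutations; calibration checks use 1,000 seeded trials of 200-interval
CO sets with 1,000 permutations each. `scripts/acceptance.py` runs the
full default five-hybrid corpus with 10,000 permutations.

## Known limitations

* CO calling assumes one CO per molecule; closely spaced double COs on
  one molecule are discarded as multi-switch, which slightly biases
  against CO clusters at molecule scale.
* The inbred↔pollen SV matching rule is a stand-in for an unspecified
  upstream convention; concordance-sensitive results should be checked
  against the breakpoint-tolerance mode.
* Historical-recombination estimation, motif discovery, GO enrichment
  and assembly-based SV validation are out of scope; their outputs can
  be consumed as plain feature tracks.
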