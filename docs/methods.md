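# Methods

## Problem

Gene duplication can preserve a protein while its regulation diverges. For a
duplicated gene pair this package asks two complementary questions:

1. **Chromatin**: do the two copies carry similar nucleosome occupancy
   profiles over their regulatory (promoter) and transcribed (coding)
   regions? In budding yeast the homocitrate synthase paralogs LYS20/LYS21
   are the motivating case: near-identical enzymes whose promoter chromatin
   differs, suggesting distinct regulatory systems.
2. **Phylogeny**: on a gene tree whose tips are labeled with species, how
   many copies does each species hold, and which internal nodes correspond
   to duplication events?

## Region definitions and coordinates

The *promoter* is operationally the `upstream_len` bases (default 1000)
immediately 5′ of the **translational start site**, and the *coding region*
is the full genomic span between translational start and end. No
transcription start sites, UTRs or splice structure are modeled; introns, if
present, are included in the coding window (yeast homocitrate synthase genes
are intronless, and a warning is emitted when a GFF3 gene shows multiple CDS
segments). Internally all coordinates are 0-based half-open, matching the
BED fragments; GFF3/TSV annotation (1-based inclusive) is converted on read.
A promoter running past the sequence origin (or a supplied chromosome
length) is kept as a partial window with a `truncated` flag rather than an
error, so toy contigs degrade gracefully; a promoter that vanishes entirely
raises. No masking is applied when a promoter window overlaps a neighboring
gene — with 1 kb windows in a compact genome this can happen, and callers
who care should filter gene pairs beforehand.

## Occupancy profiles

For a window the profile is the per-nucleotide count of nucleosomal DNA
fragments, oriented so index 0 is the gene's 5′-most position (the genomic
vector is reversed for − strand genes). Two conventions are exposed:

- **coverage** (default): a fragment counts at every position it overlaps.
  Overlap is half-open; a fragment ending exactly at a position does not
  cover it.
- **dyad**: a fragment counts only at its midpoint (even lengths tie-break
  to the lower central position), a point representation of the nucleosome.

Which convention the original occupancy maps used is not recoverable from
the motivating analysis, so the choice is configurable, recorded in output
metadata, and defaults to coverage. Counts stay raw integers — the
downstream statistic is rank-based, so positive rescaling (sequencing
depth) cannot change it. An optional 120–180 bp fragment-length filter is
available for MNase-style data but is off by default.

## Profile similarity

Similarity between two oriented profiles is **Spearman's rank correlation**
computed as the Pearson product-moment correlation of fractional (average)
ranks. The `6Σd²` shortcut is deliberately not used as the implementation:
per-base count data is heavily tied and the shortcut is biased under ties
(it remains a test oracle for tie-free inputs). A correlation against a
constant profile (e.g. a locus with no fragments) is reported as an explicit
undefined value with a reason, never coerced to 0 — zero would fabricate a
similarity statement.

`compare_paralog_pair` builds promoter and coding profiles for both genes
and reports promoter-ρ and coding-ρ side by side. Promoter windows are
equal-length by construction; coding windows usually are not, and the
reconciliation is a recorded policy:

- `resample_min` (default): linearly interpolate the longer profile onto
  the shorter one's point count, spanning the full index range;
- `truncate_min`: keep the 5′-most common-length prefix.

Truncated promoter windows (contig edge) fall back to the same policy, with
the `resampled` flag set. No p-values are attached to ρ. The statistic is
invariant under mirroring the whole genome (flip strands, reflect
coordinates), which the test suite asserts exactly.

## Gene-tree copy number and duplications

`copy_number_table` counts tips per species, optionally within a clade
filter. `label_duplications` applies the **species-overlap criterion**: an
internal node is a duplication iff the species sets of at least two of its
child subtrees intersect (tested pairwise, so multifurcations are handled).
With no gene losses this criterion is exact; with losses it can under- or
mis-count, and no reconciliation against a species tree is attempted —
that, like tree inference itself, is out of scope. `sister_paralog_pairs`
lists within-species cherries, the topological pattern of a paralog pair
whose closest relative is the other copy. Trees must be rooted; a basal
multifurcation is rejected with a pointer to root the tree first. Tip labels
are `Species|gene` by default (delimiter and field index configurable), or a
tip→species map can be supplied.

## Synthetic data: what it emulates, and what it does not

The generators stand in for two external resources: a genome-wide
nucleosome fragment map and a curated gene-tree of a fungal enzyme family.

**Fragments.** A region's chromatin is a `NucArchitecture`: dyad offsets
(relative to the translational start, gene-oriented), per-dyad occupancy
weights in (0, 1], and positional jitter. Each dyad receives
Poisson(depth × weight) fragments; centers are normally jittered; lengths
are Normal(147, 10) clamped at ≥ 50 bp — the canonical mononucleosome
footprint, since no fragment statistics were available to copy. A uniform
background (default 0.02 fragments/bp in random architectures) models
unpositioned signal. `random_architecture` draws one nucleosome repeat
length per region from 150–185 bp with a uniform phase — typical yeast
spacing — and per-dyad weights from 0.3–1.0.

**Paralog pairs.** `make_paralog_pair` places two genes (default coding
length 1287 bp, a typical intronless homocitrate synthase ORF) on disjoint
loci. Per region (promoter / coding, toggled independently) the two loci
either share one architecture — so their profiles differ only by sampling
noise and should correlate strongly — or receive independent draws, whose
profiles should not correlate. A `promoter_occupancy_boost` ≥ 1 (default
1.5) scales promoter depth, reproducing the qualitative observation that
promoters carry more mapped nucleosomes than coding regions. Defaults:
depth 100 expected fragments per full-weight dyad, 10 bp jitter.

**Gene trees.** `simulate_gene_tree` builds a random rooted binary species
topology and plants each requested duplication by splitting a random
existing tip of the named species into a within-species cherry. No losses
are simulated — by design, so the species-overlap criterion provably
recovers exactly the planted events, giving the detector a ground truth.
(The simulation API takes the species per event; a clade selector would be
redundant since events are planted at tips.)

**What a green test does not establish.** The simulators contain no
sequence-dependent nucleosome affinity, no MNase digestion bias, no
read-level errors, no duplicate reads, and no gene loss. Recovery of the
planted promoter/coding contrast shows the pipeline measures what it claims
on data matching its assumptions; it does not validate the upstream mapping
pipeline of a real experiment, and the two published correlation values for
LYS20/LYS21 (0.833 coding, 0.396 promoter) depend on an external dataset
and are not reproduced here.

## Numerical and design notes

- All randomness flows from a single integer seed through one
  `numpy.random.Generator`; outputs are byte-identical across reruns.
- Correlations are serialized with 6 decimal places; undefined ones as the
  literal `NA` plus a reason field.
- Fragments whose jittered start would be negative are dropped (they cannot
  be represented in BED); loci are placed away from the origin so this is
  vanishingly rare at defaults.
- Coverage counting uses a difference-array accumulation (O(fragments +
  window)); the tests check it position-by-position against a quadratic
  brute-force loop.
- Run manifests record command, parameters, input SHA-256 checksums, seed
  and package version; the manifest's timestamp is the only
  non-reproducible output field.
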