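# Methods

## In silico digestion

An enzyme is a named IUPAC recognition motif with a `cut_offset`, the
top-strand cut position relative to the motif start (REBASE convention:
ApeKI `G^CWGC` is offset 1, NlaIII `CATG^` is offset 4). Coordinates are
0-based half-open throughout; VCF positions are converted at the boundary.

Cut-site scanning uses a lookahead regex compiled from the motif's IUPAC
character classes, so overlapping occurrences (e.g. `TTAATTAA` for MseI) all
cut. `N` in a genome matches no motif position — assembly gaps never create
sites, though fragments may span them (an optional filter drops fragments
above a chosen N fraction; it is off by default). For a non-palindromic
motif the bottom strand is scanned as the motif's reverse complement on the
top strand, cutting at `start + (len(motif) − cut_offset)`; for palindromic
motifs (all five built-ins) the second scan is skipped, and a property test
confirms it would change nothing. Scanner output is checked against a naive
position-by-position matcher in the test suite.

Consecutive cut coordinates define internal fragments labelled by the enzyme
creating each end. Chromosome-end pieces are excluded by default because GBS
ligation needs a cut end on both sides; with `keep_terminal` the fragments
tile each chromosome exactly (a tested invariant). In a double digest the
two cut sets are pooled; a coordinate cut by both enzymes is labelled
`both` and satisfies either end requirement — a conservative superset. The
default selection `AB_only` keeps fragments whose ends can be assigned to
two different enzymes, mirroring two-enzyme GBS adapter chemistry; `all`
keeps every internal fragment. Which convention existing digestion
calculators use for two-enzyme counts is not standardised, so both are
exposed. Methylation sensitivity, star activity and partial digestion are
out of scope.

## Design math

The size window is inclusive on both ends (100–800 bp by default).
Histogram bins are `[lo, lo+bin)` except the last, closed at `max_len`, so
the window bounds are honoured exactly; when the bin size does not divide
the span the last bin is truncated. `adapter_length` shifts the selection
window from insert length to library-molecule length, letting an instrument
trace window (e.g. 200–600 bp including adapters) be applied to insert
fragments; the in silico default is 0.

Uniformity of a size distribution is summarised as `min(bin)/max(bin)`: 1
for a perfectly flat histogram, 0 when any bin is empty. It is a crude but
monotone, bounded score; any alternative can be computed from the histogram
the screen table carries.

Depth and cost models are deliberately elementary:
`reads_per_sample = lane_pairs × on_target_fraction / multiplex`,
`pairs_per_fragment = reads_per_sample / n_selected_fragments` (uniform
coverage assumed — no PCR duplication, GC bias or per-fragment efficiency),
`cost_per_sample = library_cost + lane_cost / multiplex` (currency is an
opaque unit), and barcode capacity is the product of well and plate barcode
counts. `on_target_fraction` defaults to 1 and is the single lever for
adapter-dimer/off-target loss.

## Library simulation and demultiplexing

Reads carry the sample's inline well barcode at the start of read 1, the
standard GBS layout; the plate barcode is modelled as file/lane metadata
rather than an in-read sequence, which captures the capacity arithmetic of
plate barcoding without committing to a specific in-read architecture.
For each sample, fragments are drawn uniformly with replacement; read 2 is
the reverse complement of the fragment's 3′ end; short fragments truncate
reads rather than padding them; qualities are constant `I` and the only
error model is an optional uniform substitution rate (default 0) — depth
and demultiplexing logic, not base accuracy, is what downstream analyses
consume. Barcode sets must be prefix-free within a plate, which makes exact
matching unambiguous; at one allowed mismatch, a read matching two barcodes
equally well is routed to the undetermined bin. Subsampling keeps each read
pair independently with the given probability, mates together — the
construction used to emulate skim sequencing from deeper data. Every
stochastic operation takes an explicit seed and is bit-reproducible.

## Synthetic data

`random_genome` draws i.i.d. bases at a chosen GC content. Test and
acceptance genomes use GC 0.35, a typical plant-genome composition; note an
i.i.d. genome reproduces motif-density *ordering* across enzymes but not the
dinucleotide biases (notably CG depletion) of real genomes, so per-Mb
fragment counts from it are indicative, not predictive, of any particular
assembly.

`genome_with_sites` plants concrete motif instances at approximately
exponential spacings (minimum gap one motif length, so instances cannot
interact) on a background scrubbed of accidental matches: any unwanted
occurrence is rewritten by advancing one non-planted base through the
lexicographic base order until the window no longer matches. The planted cut
set is returned, giving digestion an exact construction oracle.

The haplotype panel simulator is a founder mosaic, not a coalescent:
founder haplotypes are drawn per-variant from an allele-frequency
distribution (default uniform on [0.01, 0.5]); each descendant haplotype
copies founder segments separated by a Poisson number of breakpoints at
uniform variant positions; per-allele flip noise models genotyping error;
consecutive haplotype pairs form diploid samples. Fewer breakpoints mean
longer shared segments — longer-range linkage disequilibrium — which is the
single knob the imputation analyses need, and the zero-recombination,
zero-error limit makes recovery tests exact. The model has no demographic
realism, no indels, no structural variation; passing tests demonstrate the
harness's internal consistency and qualitative behaviour, not accuracy
levels attainable on any real germplasm.

## Imputation evaluation

Masking emulates a lower-density platform by setting all genotypes at
non-kept variants to missing; the kept set is drawn uniformly with a seed
(or supplied explicitly), and one seed-controlled mask per density keeps
platform contrasts free of masking noise.

The built-in imputer is windowed nearest-haplotype copying. For each variant
with missing calls, the `flank` (default 10) nearest typed variants per side
form a window; missing observations inside the window simply drop out of the
mismatch counts. Per sample, haplotype 1 minimises mismatches against the
observed dosages (hom-ref conflicts with allele 1, hom-alt with allele 0,
het with neither); haplotype 2 is chosen greedily against the residual,
where het sites demand the complementary allele. Ties break to the lowest
panel index, making the imputer fully deterministic. Imputed dosage is the
sum of the two copied alleles. Variants with no typed variant in reach fall
back to the panel major allele and are logged. This is intentionally far
simpler than HMM-based production imputers; the metrics accept externally
imputed VCFs so those can be evaluated through the same harness.

Accuracy is the squared Pearson correlation between imputed and true
dosages over masked entries, binned by allele frequency **computed on the
reference panel** — panel AF is defined even for fully masked variants,
whereas study-sample AF is not. Bins are width 0.1, half-open with the last
bin closed. By default R² pools entries across variants within a bin (one
curve per platform); a `per_variant` mode averages per-variant correlations
instead, and its overall score is the mean over all masked variants, which
makes it invariant to swapping allele labels at any single variant. The
pooled score is invariant under a global label swap but not under
single-variant swaps — a property of pooled correlation, not a bug — which
is why both modes exist. Bins (or variants) with zero dosage variance on
either side are flagged undefined, excluded from the overall score, and
counted in the log.

## Problem sizes and numerical conventions

Test and acceptance runs use desk-scale inputs chosen to keep every oracle
exact or tightly bounded: 10–300 kb genomes for scanner/partition checks
(the scanner is linear-time, so scale adds nothing beyond runtime), a 1 Mb
genome for the screen, 96 samples × 500–1000 pairs for the library round
trip, and panels of 80–140 haplotypes × 300–400 variants with 5–10 seeds
for the imputation sweeps. Stochastic assertions use 3σ bounds under the
exact binomial/Poisson distribution of the statistic. All CLI randomness
derives from one root seed expanded per stage by stable SHA-256 labels, so
a single integer reproduces a whole experiment; seeded outputs are
byte-identical across reruns (`--no-timestamp` removes the one
non-deterministic header field).

## Known limitations

* Fragment counts from i.i.d. genomes ignore genome-specific motif
  clustering; real-assembly screens should use the real FASTA.
* The depth model assumes uniform fragment coverage; real GBS libraries
  show size- and GC-dependent amplification bias.
* The demultiplexer is exact/Hamming-1 only; indel barcode errors are not
  recovered.
* The imputer's greedy diploid phasing can be suboptimal at dense
  heterozygosity; it is an evaluation baseline, not a production tool.
* Multi-allelic and indel VCF records are skipped, never split.
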