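# Methods

This note records the models and procedures behind each pipeline stage, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic study does and does not demonstrate.

## Circular genomes and canonical coordinates

Chloroplast genomes are circular molecules; all internal coordinates are
0-based half-open, with modular arithmetic on the circle, and 1-based
coordinates appear only in emitted VCF/GFF3. FASTA input is assumed
circular unless flagged otherwise; GenBank topology is honoured. `U` is
mapped to `T` and sequences are uppercased on input; the alphabet is
restricted to `ACGTN`, and windows containing `N` are excluded from primer
and anchor searches to avoid spurious exact matches.

Cross-genome coordinates are made comparable by canonical rotation: the
genome is rotated so position 0 is the first LSC base and segments read
LSC–IRb–SSC–IRa (IRb is defined as the IR copy adjacent to the right end
of the LSC). Both strands satisfy that layout, so the strand is fixed by
taking the lexicographically smaller of the two candidate linearizations —
an arbitrary but deterministic rule that makes canonicalization idempotent
and invariant to reverse-complementing the input. Features that wrap the
origin after rotation are stored as two sub-intervals.

## Quadripartite structure detection

The inverted repeat is found as the maximal-length pair of disjoint exact
reverse-complement repeats of at least `min_ir_len` (default 1000) bp.
Matches between the doubled sequence and its reverse complement are seeded
with 24-mers stepped so that any repeat of the minimum length necessarily
contains a seed, then extended maximally; circularity is respected by the
doubling. The shorter gap between the chosen pair is the SSC, the longer
the LSC. Ties between equally long repeat pairs go to the pair minimizing
the SSC, then to the lowest start coordinate, so detection is
deterministic. An optional mismatch-tolerant mode is deliberately absent:
exact repeats are the default and the tested configuration because the two
IR copies of a chloroplast genome are expected to be identical; genomes
whose IRs have diverged would need re-detection at a lower `min_ir_len`
and inspection.

GC content is reported as a percentage rounded half-up to two decimals,
matching the precision conventions of genome reports.

Junction reports list, for each of the four LSC/IR/SSC boundaries, the
features spanning it (with the fragment length on each side, which sum to
the feature length) and the nearest flanking features.

## Pairwise alignment and variant calling

Two genomes of the same genus differ by well under 0.1%, so a full-genome
dynamic program is wasteful. The aligner chains k-mers (default k = 21)
that occur exactly once in both genomes, takes the longest increasing
subsequence in query order, and aligns only the windows between anchors
with an affine-gap Gotoh algorithm under a fixed scoring: match +1,
mismatch −2, gap open −4, gap extend −1 (a gap of length L costs 4 + L).
Windows larger than `max_window` (default 20 000 bp) raise an error rather
than silently consuming memory; inputs shorter than ~200 bp skip anchoring
and go straight to the full DP. The result is a true global alignment
whose ops tile both genomes exactly (validated on construction). Anchored
and full-DP alignments are verified equivalent (same optimal score, same
variant event set) in the test suite.

Variant calling walks the alignment columns: consecutive gap columns of
one type form one InDel event; runs of two or more adjacent mismatches
form an MNP by default (a flag decomposes MNPs to SNPs, and counts are
reported under both conventions, because SNP tallies in the literature are
convention-sensitive). An insertion and a deletion separated by fewer than
three matched bases are kept as separate events, never merged into a
complex event — the simplest deterministic rule; it affects counts, so it
is stated here. InDels are left-normalized in the VCF sense: shifted to
the lowest reference position that preserves the haplotype, and reported
with the anchor base. The signed InDel lengths therefore always sum to the
genome length difference, which is the bookkeeping invariant the test
suite and acceptance script enforce. Context is assigned from the
annotation: genic (overlapping a gene/tRNA/rRNA feature, named) or
intergenic (labelled with the flanking gene pair, e.g. `rpoC2-rps2`).

## Tandem-repeat copy-number markers

A diagnostic InDel is most robust when it is a copy-number change of a
short tandem repeat: the size difference is then quantized in unit
lengths. For each InDel the detector tries every unit length dividing the
event length, smallest first and up to `max_unit` = 100: the unit must be
primitive (not itself a repetition), the event an exact integer number of
copies, and at least one further exact copy must flank the event in the
reference — otherwise the InDel is not a tandem phenomenon and `None` is
returned. Copy numbers are counted as maximal exact tandem runs around the
locus in each genome; exact counting is the default and the tested mode.
The detector is validated against an exhaustive unit/phase enumeration on
fuzzed events.

Marker candidates are InDels strictly longer than `min_len` = 20 bp
(a 20-bp event is excluded; the cutoff is configurable), intergenic by
default, ordered longest first and named `cp_01`, `cp_02`, …

Primer design searches 200-bp flanks on each side of the tandem run
(excluding the run itself) for primers of 18–25 nt, GC 40–60%, melting
temperature 55–62 °C, a single exact binding site in both genomes, and a
product of at most 400 bp, scoring pairs by Tm balance and closeness of
the product to 250 bp. Tm uses nearest-neighbor thermodynamics
(Biopython's SantaLucia parameters) at 50 mM monovalent salt and 0.5 µM
primer; published Tm values computed under unknown conditions are treated
as informative, never as targets. Published primer pairs can be injected
verbatim, bypassing design — the normal route when reproducing an
established marker system. Expected per-cytotype product sizes are always
filled by in-silico PCR, never asserted.

## In-silico PCR and cytotype classification

PCR is simulated by locating the forward primer and the reverse complement
of the reverse primer on the template (both orientations searched), with
at most `max_mismatch` mismatches (default 0) and the three 3'-terminal
bases always exact — a model of primer-extension chemistry that is inert
at the default but matters in mismatch-tolerant scans. Product length is
outer edge to outer edge, inclusive of both primer footprints, which is
what makes capillary sizing comparable; footprints may not overlap.
Products spanning the circular origin are found by scanning the doubled
sequence. All products up to `max_product` = 2000 bp are reported, sorted
by length.

A sample is called S (or N) only if every amplifying marker matches that
cytotype's expected size within the tolerance (default ±2 bp, mimicking
capillary sizing error); mixed signals, multiple products matching
different expectations, or products matching nothing give `ambiguous`; no
product from any marker gives `no_amplification`. Markers that simply fail
to amplify are excluded from the consensus rather than voting. Cohorts can
be genotyped with one marker or several; summaries tally S/N/other per
cultivar with a grand total row.

## Distances, neighbor joining, bootstrap

Multiple alignment uses the star method: every genome is pairwise-aligned
to one designated reference and the alignments are merged on reference
coordinates, padding insertions to the per-position maximum. This is exact
enough here because all pairwise identities exceed 99.9%; it is *not* a
general-purpose MSA and would misplace overlapping insertions in divergent
data — a documented limitation.

Two distance models are provided. The p-distance is the proportion of
differing sites among pairwise-compared sites (gap and N columns excluded
per pair; complete deletion is available via a flag). The TN93 distance
uses the Tamura–Nei formula with base frequencies pooled over all rows of
the alignment and transition/transversion rate ratios (k1 purine, k2
pyrimidine) estimated once from substitution counts pooled over all pairs
— a composite estimation in the spirit of pooling schemes used by standard
phylogenetics software, chosen because per-pair rate estimates are
meaningless at the divergences involved (often zero or one substitution).
At p < 1e-4 the two models agree within 1e-6, which the suite asserts.
Distances are kept at full precision internally and rounded only for
reporting (4–5 decimals).

Neighbor joining is the Saitou–Nei algorithm with the standard Q
criterion; ties are broken toward the smallest index pair in the current
ordering, making the tree deterministic. Negative branch lengths are kept
by default (required for exact recovery of additive matrices, which the
suite verifies against randomly generated trees and against scikit-bio's
implementation); an optional clamp moves the deficit to the sibling
branch for presentation. Bootstrap resamples alignment columns with
replacement — replicate r uses seed + r — recomputes the distance matrix
with pairwise deletion inside the replicate, and reports the percentage of
replicates containing each original bipartition. Supports are keyed by
taxon names, not input order, so they are invariant to input permutation.
An all-zero distance matrix is flagged degenerate and reported with full
support by convention.

## The synthetic study

The generator builds, from a single seed via named substreams (backbone,
genes, markers, snps, cohort, species), a quadripartite genome of LSC
8 000 + IR 2 500 + SSC 1 200 bp (~14 kb, small enough that the whole suite
runs in seconds while every algorithmic regime — circularity, repeats,
junction-spanning genes — is exercised), at a target GC of 38.5%, with
named gene features including one spanning the IRb–SSC junction. Each
tandem-repeat CNV locus sits in its named intergenic spacer as
(forward-primer site, pad, unit copies, pad, reverse-primer site); the
default study plants the two field-validated marker loci — a 28-bp unit in
*rpoC2–rps2* and a 22-bp unit in *cemA–petA*, two copies in S versus one
in N, flanked by the published primer sequences and padded so the S-type
products are 270 and 265 bp (N: 242 and 243 bp). Between-cytotype SNPs are
drawn at 1.35e-4 per site, the genome-wide SNP density observed between
sterile and fertile *Sorghum* chloroplasts, outside the marker spacers;
SNPs landing in the IR are mirrored into the second copy so the repeat
stays exact. IR junction bases are pinned so the planted repeat is also
the maximal one, and the first/last LSC bases are pinned so the assembled
strand is the canonical one — emitted coordinates therefore equal
canonical coordinates exactly, and the truth record is byte-consistent
with the emitted FASTA/GFF3.

The default cohort is six cultivars of 195/170/236/313/95/95 plants, three
fixed for each cytotype (501 S and 603 N of 1,104) — the shape of a
released-cultivar survey where each pure line carries a single maternally
inherited cytoplasm. The species set derives eight taxa from the pair on a
known tree (two identical sterile-side taxa; two fertile-side taxa one
substitution apart; two further relatives; two long-branch outgroups), so
sister relationships and near-zero distances have a planted ground truth.

What passing on synthetic data does *not* show: robustness to sequencing
or assembly error, to IR copies that differ by real mutations, to
heteroplasmy, or to PCR artefacts (dimers, secondary structure, competing
amplicons); primer thermodynamics are modelled, not measured. Real-data
runs should treat `ambiguous` calls and multi-product amplifications as a
signal to inspect, not noise.

## Numerical and degenerate-input choices

- Alignment DP memory is capped (~3e7 cells); larger windows raise an
  error suggesting parameter changes instead of thrashing.
- Variants at position 0 of the linearization anchor on the following base
  (the VCF edge convention); a variant spanning the origin cannot arise
  because alignment happens on canonical linearizations.
- Zero compared sites between two rows (all-gap overlap) is an error, not
  a zero.
- Empty cohorts summarize to an all-zero table; unmapped samples are
  errors naming the sample.
- All CLI randomness flows from `--seed`; re-running a subcommand with the
  same inputs and config is byte-identical (timestamps appear only in
  logs).
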