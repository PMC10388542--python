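# chlorotype

Chloroplast-genome InDel markers for cytoplasmic male sterility (CMS)
typing, as a reusable, tested pipeline.

## The problem

F1 hybrid breeding in crops such as *Sorghum* depends on cytoplasmic male
sterility: a maternally inherited, organelle-encoded failure to make
functional pollen. Breeders must know whether a line carries the sterile
(CMS-S) or the normal fertile (CMS-N) cytoplasm before crossing, and the
classical test cross takes a full season. Because the chloroplast genome is
maternally inherited and nearly invariant within a species, a short InDel
that differs between the S and N chloroplast is a fast, cheap diagnostic:
amplify it by PCR and read the product size.

`chlorotype` implements the comparative-genomics pipeline that discovers
such markers and applies them:

1. **Quadripartite structure** — find the inverted-repeat pair (IRa/IRb) of
   a circular chloroplast genome as the maximal disjoint exact
   reverse-complement repeats; partition into LSC / IRb / SSC / IRa; report
   junction gene context; canonicalize rotation and strand so coordinates
   are comparable across genomes.
2. **Variant calling** — align two near-identical genomes (unique shared
   k-mers chain collinearly; affine-gap Gotoh alignment between anchors:
   match +1, mismatch −2, gap open −4, extend −1) and call SNPs, MNPs and
   left-normalized VCF-style InDels with genic/intergenic context.
3. **Tandem-repeat markers** — explain each large InDel as a copy-number
   change of a primitive tandem unit (e.g. 28-bp and 22-bp units in the
   *rpoC2–rps2* and *cemA–petA* spacers), keep intergenic InDels longer
   than 20 bp, and design or accept diagnostic primer pairs.
4. **In-silico PCR genotyping** — locate primer sites on both strands of
   the circular template (3'-terminal 3 bases always exact), measure
   primer-inclusive product sizes, call each sample S / N / ambiguous /
   no-amplification within a sizing tolerance (default ±2 bp), and tally
   cohorts per cultivar.
5. **Phylogenetics** — star multiple alignment against a reference,
   p-distance or Tamura–Nei (TN93) distances with composite (pooled)
   frequency and rate estimates, Saitou–Nei neighbor joining, and
   column-resampling bootstrap.
6. **Synthetic data** — a deterministic generator that builds desk-scale
   quadripartite genomes (~14 kb) with planted tandem-repeat CNV loci,
   primer-compatible flanks, between-cytotype SNPs, cultivar cohorts and a
   truth record, so the whole pipeline is testable offline in seconds.

## Worked example

Generate the default synthetic study and run the discovery chain:

```sh
chlorotype simulate --seed 42 --out fixtures
chlorotype structure fixtures/synthetic_S.fasta fixtures/synthetic_N.fasta --out st
cat st/structure.tsv
```

```text
genome       total_bp  lsc_bp  ssc_bp  ira_bp  irb_bp  gc_percent  delta_total_bp  delta_lsc_bp ...
synthetic_S  14250     8050    1200    2500    2500    38.22       0               0
synthetic_N  14200     8000    1200    2500    2500    38.23       -50             -50
```

Both genomes partition exactly (LSC + SSC + 2·IR = total); the 50-bp
difference sits entirely in the LSC, where the two marker loci live.

```sh
chlorotype compare fixtures/synthetic_S.fasta fixtures/synthetic_N.fasta --out cmp
# stderr: variants: {'snp_events': 1, 'snp_sites': 1, 'indels': 2, 'signed_indel_sum': -50}
chlorotype markers fixtures/synthetic_S.fasta fixtures/synthetic_N.fasta --out mk
cat mk/candidates.tsv
```

```text
name   type      length  context     unit_len  copies_ref  copies_qry
cp_01  deletion  28      rpoC2-rps2  28        2           1
cp_02  deletion  22      cemA-petA   22        2           1
```

The two InDels longer than 20 bp are both tandem-repeat copy-number
variants: the S cytotype carries two copies of a 28-bp unit (respectively a
22-bp unit) where the N cytotype carries one, so any primer pair spanning a
locus yields products differing by exactly 28 (or 22) bp between cytotypes.
With the published diagnostic primers the products are 270/242 bp (cp_01)
and 265/243 bp (cp_02) for S/N. Genotyping a cohort:

```sh
chlorotype genotype cohort/manifest.tsv --markers mk/markers.yaml --out gt
```

```text
          n_total  n_S  n_N  n_other
cultivar
DemoA           6    6    0        0
DemoB           4    0    4        0
Total          10    6    4        0
```

Every plant is called from its amplicon sizes alone and the per-cultivar
tallies match the planted cytotypes. `chlorotype phylo` adds distances, a
neighbor-joining tree in Newick and bootstrap supports for any genome set.

The same operations are available as a library (`import chlorotype`); the
CLI is a thin wrapper.

## Layout

```
src/chlorotype/
  genome_io.py     FASTA/GenBank/GFF3 I/O, canonical rotation
  quadripartite.py IR detection, junctions, structure tables
  variants.py      anchored alignment, variant calling, VCF
  markers.py       tandem units, marker selection, primer design
  genotyping.py    in-silico PCR, cytotype calls, cohort summaries
  phylo.py         distances, neighbor joining, bootstrap
  synth.py         synthetic genomes, cohorts, species sets
  cli.py           subcommands: simulate/structure/compare/markers/genotype/phylo
tests/             pytest suite with independent brute-force oracles
docs/methods.md    models, parameters, design choices, limitations
```
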