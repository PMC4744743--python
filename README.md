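# autozygmap

Autozygosity mapping and disease-candidate screening from per-sample exome
VCFs, with optional high-density SNP-microarray genotypes.

## Who this is for

Groups mapping rare autosomal-recessive disease genes in consanguineous
families, or screening nuclear families for de novo mutations, using exome
variant data — optionally alongside SNP-array genotypes — without a joint
variant-calling pipeline. The package is a library plus a command-line tool;
a built-in pedigree simulator with exactly known truth stands in for patient
data in all tests.

## The method

**Unified dataset.** Single-sample exome VCFs list only non-reference
genotypes, so a site absent from one sibling's VCF is ambiguous (homozygous
reference, or just uncovered?). All samples' variants are merged into one
site-by-sample matrix; per-sample read-depth tables fill in
homozygous-reference (AA) genotypes wherever total depth ≥ a user-chosen
retention threshold, and everything else is an explicit no-call.

**Genotype re-calling.** Caller conventions differ, so every genotype is
re-determined from its reference/alternate allele depths (fraction
f = alt/(ref+alt)):

- 1−f > 0.8 → AA; f > 0.8 → BB; 0.4 ≤ f ≤ 0.6 → AB; otherwise no call.

**Autozygous regions.** Autozygosity — homozygosity by descent through a
consanguineous loop — shows up as runs of homozygous markers. Per sample and
chromosome, calls passing an rs-dependent depth floor (15/30 reads for
rs-annotated homozygous/heterozygous genotypes, 75/150 for novel ones) form
a marker sequence; maximal homozygous runs are built (no-calls are
transparent); a single heterozygote interrupting two runs of >25 homozygous
variants each is reassigned to no-call and the runs recomputed, iterated
four times; runs spanning >500 kb are reported. Microarray genotypes go
through the same run logic without re-calling, with the per-flank
requirement scaled to the array design as round(n_SNPs × 7×10⁻⁴)
(>10,000-genotype designs only).

**Screens.** Candidate filters, chainable with per-stage counts: homozygous
variant in all affecteds and in no other called sample; no rs identifier;
inside the shared autozygous interval; de novo heterozygous (affected AB,
parents and unaffected sibs confirmed AA); Mendelian-impossible homozygotes
(deletion footprints).

**Annotation.** Surviving sites are placed in gene context from
refFlat/genePred models plus a genome FASTA: spliced strand-aware CDS
translation (synonymous/missense/nonsense/stop-loss, p.-style change with +1
at the initiating Met), frameshift vs in-frame for indels, splice-region
proximity, and per-sample genotypes and depths.

## Worked example

Simulate a first-cousin pedigree (two affected children, both parents; a
recessive missense variant planted in a shared autozygous segment), build
the dataset, map regions, and screen:

```sh
autozygmap simulate --seed 7 --pedigree first-cousin --out sim --write-reference
autozygmap build   --in sim --pedigree sim/pedigree.tsv --out dataset
autozygmap regions --in sim --pedigree sim/pedigree.tsv --out regions
autozygmap screen  --dataset dataset/unified_dataset.tsv --pedigree sim/pedigree.tsv \
    --filter affected-hom --filter no-rs --filter in-regions \
    --regions regions/shared_regions.bed \
    --genes sim/genes.refFlat --fasta sim/reference.fa \
    --protein-affecting --out screen
```

which prints:

```
simulated 4 exome samples (1 planted variants) -> sim
unified dataset: 3314 sites x 4 samples -> dataset/unified_dataset.tsv
4 autozygous regions -> regions/regions.tsv
affected_homozygous: 3314 -> 516 variants retained
no_rs: 516 -> 33 variants retained
in_regions: 33 -> 33 variants retained
1 candidate rows -> screen/candidates.tsv
```

Reading the numbers: of 3314 merged sites, 516 are homozygous-variant in
both affected sibs and in neither parent; 33 of those carry no rs
identifier; all 33 fall inside the shared autozygous intervals (in this
seed the sibs share most of chromosome 2); and exactly one affects a
protein. The final candidate row is

```
chrom pos      rsid ref alt gene     transcript region consequence protein_change
2     29167003 .    A   C   GENE0438 TX0438     coding missense    p.(Leu770Phe)
```

— which matches the simulator's truth file (`sim/truth_variants.tsv`):
the planted causal variant, BB in both affecteds and AB in both carrier
parents.

For a trio, `autozygmap denovo --dataset ... --pedigree ... --out ...`
reports sites heterozygous in the affected child with both parents confirmed
homozygous reference.

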