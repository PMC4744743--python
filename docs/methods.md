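# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Genotype re-calling and depth qualification

Every variant genotype is re-derived from its per-genotype allele depths
(`AD`-style field; a reference/alternate observation-count pair can be
configured as a fallback). With f = alt/(ref+alt), the rules are applied in
order: no reads → no call; 1−f > 0.8 → AA; f > 0.8 → BB; 0.4 ≤ f ≤ 0.6 → AB;
otherwise no call. Comparisons are strict for the 80% rules and inclusive
for the 40–60% band; an alternate fraction of exactly 0.8 is therefore a
no-call, which the tests pin. At a split multi-allelic record only that
allele's depths enter the fraction (a per-record biallelic model). An alt
fraction between 0.6 and 0.8 at any depth is reported as a no-call; no
mosaicism flag is attempted.

Two independent depth thresholds exist by design. The *retention* depth
(`display_min_depth`, default 10) controls only homozygous-reference fill-in
when building the dataset. The *autozygosity* floors gate which calls enter
run detection: 15 reads (homozygous) / 30 (heterozygous) for variants whose
VCF ID matches `rs\d+`, 75/150 for variants without one — novel variants
need far more evidence because a spurious novel heterozygote is the failure
mode that fragments true runs. Floors are inclusive ("set to 15 reads" ⇒
depth ≥ 15 passes).

## Unified dataset

Sites are keyed by (chromosome, position, ref, alt), so two alternate
alleles at one position are distinct sites; chromosome names are normalised
by stripping a `chr` prefix; sample columns are ordered alphabetically. For
a sample whose VCF lacks a site, the cell becomes AA (with the table's total
depth as the reference depth) iff the sample's depth table covers the
position at ≥ `display_min_depth`; otherwise a no-call. Fill-in can never
create AB or BB. Indels are admitted as sites with the same depth semantics
as SNVs.

The exported TSV (`#chrom pos rsid ref alt <samples…>`, tokens AA/AB/BB/NC)
carries genotypes only; reading it back restores sites, sample order and
genotypes exactly (re-export is byte-identical) but not read depths. For
this reason region detection from a re-read TSV admits every called genotype
(the floors cannot be evaluated without depths, and the CLI says so);
the canonical workflow runs region detection from the VCF/depth folder.

## Autozygous-region detection

Marker sequences per sample and chromosome hold HOM (AA or BB), HET, or
NOCALL states. No-calls are transparent: they neither support, extend, nor
break runs, and do not count toward flank requirements — the same treatment
a reassigned heterozygote receives. Maximal HOM runs are delimited by HETs.
In each of four iterations, every HET whose flanking runs (no other HET
between) both hold strictly more than 25 HOM markers is identified against
the current structure; all are reassigned to NOCALL simultaneously; runs are
recomputed once. Simultaneous reassignment is deterministic and
order-independent; the iteration stops early at a fixed point (which changes
nothing). The same >25 flank rule is reused unchanged in every iteration. A
run is reported as a region iff the span from its first to last supporting
HOM marker strictly exceeds 500 kb; the region is that span (no extension
toward flanking heterozygotes — conservative and reproducible). Both
homozygous states count as HOM: autozygosity is the absence of
heterozygosity, and with reference fill-in most supporting markers are AA
(a VCF-only dataset degenerates to BB/HET markers, which the algorithm
tolerates). X and Y are excluded by default (diploid-autosome model; a flag
includes them).

Microarray genotypes skip re-calling and depth floors; the per-flank
requirement becomes round(n_SNPs × 7×10⁻⁴), rounded half-up (906,600 SNPs →
635), compared with the same strict ">". Designs of ≤10,000 genotypes are
rejected. One known consequence of the flank rule (either data type): a
*pair* of erroneous heterozygotes closer together than the flank requirement
cannot be rescued — neither is isolated — so a single very long run is
occasionally split into two large regions around a short gap. This is
inherent to the published rule; the tests measure it rather than hide it.

Shared autozygosity is the interval intersection of all affected samples'
regions, optionally minus any unaffected sample's regions. Cross-sample
concordance at a site is binned by p, the largest fraction of called
genotypes sharing one homozygous state: p > 0.9 black, 0.8 ≤ p ≤ 0.9 orange,
p < 0.8 yellow (all-heterozygous sites are yellow; all-no-call is reported
as "uncalled"). Note 10 BB + 1 AB gives p = 10/11 ≈ 0.909 > 0.9 → black.

## Screens

All screens consume re-determined genotypes, never declared ones.
*Recessive*: BB in every affected and not BB in any non-affected with a
called genotype; an affected no-call excludes the site, a non-affected
no-call neither rescues nor excludes (permissive where data are absent).
*Novelty*: the site ID does not match an rs accession; no external dbSNP
lookup. Since pathogenic de novo variants are often rs-annotated, a warning
is logged when this filter removes >90% of a de novo result. *Locus*:
1-based inclusive containment in the shared intervals. *De novo*: affected
offspring AB with both parents and all unaffected full siblings strictly AA
— a no-call anywhere among them excludes the site, because a de novo claim
requires positively confirmed reference genotypes (without depth fill-in the
screen is empty, by design). *Unexpected homozygote*: an affected offspring
homozygous for an allele some called parent carries zero copies of;
sites are flagged individually, with no regional-clustering requirement.

## Annotation

Consequences are computed per overlapping transcript (deterministically
ordered by transcript id; no "worst consequence" collapsing). For a coding
SNV the reference codon is taken from the spliced, strand-aware CDS, the
base substituted, and both codons translated; protein changes use one-based
residue numbering from the initiating methionine (p.(Asp2Gly),
p.(Trp3*), p.(*11Gln), p.(Gly5=)). Indels are frameshift iff the length
difference is not a multiple of 3; no left/right normalisation is attempted
(input positions are taken as given — normalise VCFs upstream if needed).
Intronic variants within a configurable window of an exon boundary (default
8 bp, a pragmatic splice-region span) are reported as splice_region with
exact distance, and the canonical ±2 positions flagged separately. Exonic
non-CDS positions are classified 5'/3' UTR by strand and side.

## Synthetic pedigrees

The generator emulates the data regimes the method was designed for and
serves as the test bed in place of patient data.

*Genetics.* Founder haplotypes are dropped through the pedigree with
Poisson crossovers at 1 cM/Mb, uniform placement, no interference; truth
autozygosity is exactly the intervals where a sample's two haplotype
ancestries coincide. Offspring of first cousins are autozygous over ~1/16 of
the genome on average (checked over 200 unconditioned drops). When a
recessive causal variant is planted, whole-pedigree drops are
rejection-sampled until all affected children are autozygous for one shared
grandparental haplotype at a chosen coding position and no unaffected
individual is homozygous for it — the in-silico analogue of ascertaining
affected children. Founder marker alleles are independent
(no linkage disequilibrium), with MAF ~ U(0.15, 0.5): a family's unified
dataset is dominated by the common variation segregating in it.

*Default study conditions* (chosen once, before any acceptance
measurement): genome of 2 × 40 Mb autosomes — large enough for realistic
multi-megabase segment statistics while keeping hundreds of simulated
pedigrees cheap; exome markers from a two-state genic/intergenic process
(genic blocks mean 50 kb at 150 markers/Mb, intergenic mean 80 kb at
8 markers/Mb, ≈55/Mb overall — the genome-wide density of a family's merged
exome sites, with heavy-tailed gaps reproducing the uneven exome
distribution); 92% of markers rs-annotated; mean coverage 80× (negative
binomial, k = 8); heterozygote allelic balance N(0.5, 0.06); homozygote
stray-read fraction |N(0, 0.01)|; exome genotype error 10⁻³; array density
300 markers/Mb (a high-density chip scaled to the genome) with 2×10⁻³
miscalls and 5×10⁻³ no-calls. A `noiseless()` variant (constant coverage,
exact balance, zero errors) defines the error-free regime used for the
de novo recall check. The acceptance script uses batches of 40/40/25
pedigrees per block; the test suite uses 100-seed batches.

*What the simulator does not emulate* — and hence what passing tests do not
show about real data: LD and coalescent founder history, reference
alignment and mapping artefacts (duplicated regions, indel realignment),
batch effects between capture kits, population-level allele-frequency
structure, and real dbSNP annotation (rs status is a Bernoulli flag). The
reference genome is synthetic (uniform bases, gene CDSs drawn from non-stop
codons) and is labelled as such.

*Determinism.* All randomness derives from the configuration seed through
fixed-order child streams (genome design, gene drop, genotypes), so a fixed
seed yields byte-identical output files; the RNG seeds derived from the CLI
seed stay below 2³¹.

## Numerical and interface choices

- Region/interval arithmetic is 0-based half-open internally; VCF, depth
  tables and all reports are 1-based inclusive; BED output converts at the
  boundary.
- round-half-up for the array scaling (`floor(x + 0.5)`), pinned by test.
- Degenerate inputs: empty marker sequences yield no regions; an empty
  filter plan retains all sites; all-no-call concordance is "uncalled";
  empty VCF bodies are valid.
- Boundary-resolution comparison between data types measures, for each truth
  segment, the distance from each segment edge to the nearest edge of an
  overlapping detected region; array-derived boundaries are several-fold
  tighter than exome-derived ones on the same truth, as expected from marker
  density and evenness.

## Known limitations

- Compound heterozygotes, population-frequency filtering and quality-score
  recalibration are out of scope; ploidy ≠ 2 is not modelled.
- Very long runs can be split by adjacent heterozygote-error pairs (see
  above); downstream interval intersection still localises the causal
  variant, but region counts per sample are not a robust statistic.
- The splice-region window is a distance heuristic, not a splice-strength
  model.
- Haplotype phasing is not performed; the dataset export exists partly to
  feed external phasing/mapping tools.
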