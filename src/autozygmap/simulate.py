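"""Synthetic consanguineous pedigrees with known autozygosity and planted
causal variants.

The generator stands in for patient data: it gene-drops recombined founder
haplotypes through a pedigree (Poisson crossovers, 1 cM/Mb, no
interference), tracks identity-by-descent so the truth autozygous segments
are known exactly, and emits every input format the tool reads — per-sample
VCFs listing only non-reference genotypes, DepthOfCoverage-style depth
tables covering all marker positions, a microarray genotype table, a
pedigree file and refFlat gene models over a synthetic reference — plus a
machine-readable truth set.

Exome markers are placed by a two-state genic/intergenic process so that
inter-marker gaps are heavy-tailed, reproducing the uneven site distribution
that makes exome-defined loci larger than array-defined ones.  Genotype
noise is depth-based: per-site coverage is negative-binomial, heterozygote
allelic balance is jittered around 50%, homozygote reads carry a small
error fraction, and a small per-genotype error rate swaps calls outright.

When a recessive causal variant is planted, the pedigree drop is
rejection-sampled until all affected offspring are autozygous for a common
founder haplotype at the chosen coding position and no unaffected individual
is homozygous for it — the in-silico analogue of ascertaining affected
children.  With no planted recessive the drop is unconditioned (useful for
checking the inbreeding coefficient).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import annotate_variant
from .errors import PedigreeError
from .formats import (
    ArrayGenotypeTable, DepthTable, GeneModelRecord, PedigreeRecord,
    VcfSiteRecord, write_pedigree,
)
from .genotyping import CODE_TO_STATE
from .synthref import SyntheticReference, codes_to_seq

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
_NONSTOP = [c for c in _CODONS if c not in _STOPS]
_G_TO_STATE = {0: "AA", 1: "AB", 2: "BB"}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Individual:
    iid: str
    father: str | None = None
    mother: str | None = None
    status: str = "unknown"
    sources: tuple[str, ...] = ()

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass(frozen=True)
class PlantSpec:
    """A variant to plant: recessive_causal | de_novo | deletion_hom."""

    kind: str
    target: str = "affected"        # sample id, or "affected" for all affecteds
    with_rs: bool = False
    causal_type: str = "missense"   # missense | frameshift (recessive only)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated pedigree.

    Defaults model a scaled-down diploid autosomal genome (2 x 40 Mb) with
    exome-like site density (~55 segregating sites/Mb genome-wide, clustered
    into gene-sized blocks), founder minor-allele frequencies typical of the
    common variation that dominates a family's unified dataset, ~80x mean
    exome coverage, and SNP-array marker density of ~300/Mb (a high-density
    genotyping chip scaled to the genome).  A fixed seed yields
    byte-identical outputs.
    """

    seed: int = 0
    pedigree: tuple[Individual, ...] = ()
    pedigree_kind: str = "first_cousin"     # first_cousin | outbred | trio
    chromosomes: tuple[tuple[str, int], ...] = (("1", 40_000_000), ("2", 40_000_000))
    # exome marker placement (two-state genic/intergenic process)
    genic_mean_len: float = 50_000.0
    intergenic_mean_len: float = 80_000.0
    genic_marker_density: float = 150e-6        # markers per bp inside genic blocks
    intergenic_marker_density: float = 8e-6
    gene_prob: float = 0.9                      # probability a genic block hosts a gene
    # array design
    array_marker_density: float = 300e-6
    # founder variation
    maf_low: float = 0.15
    maf_high: float = 0.5
    rs_fraction: float = 0.92
    # depth / noise model
    mean_coverage: float = 80.0
    coverage_dispersion: float = 8.0            # negative-binomial k; inf => constant
    allelic_balance_sd: float = 0.06            # sd of het alt-read fraction about 0.5
    hom_error_sd: float = 0.01                  # sd of the stray-read fraction at homs
    exome_genotype_error: float = 1e-3
    array_genotype_error: float = 2e-3
    array_nocall_rate: float = 5e-3
    crossover_rate: float = 1e-8                # per bp per meiosis (1 cM/Mb)
    planted: tuple[PlantSpec, ...] = ()

    def __post_init__(self) -> None:
        for name in ("genic_marker_density", "intergenic_marker_density",
                     "array_marker_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("rs_fraction", "exome_genotype_error", "array_genotype_error",
                     "array_nocall_rate", "gene_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for ind in self.pedigree:
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(f"{ind.iid}: non-founders need both parents")

    def noiseless(self) -> "SimConfig":
        """Error-free conditions: constant coverage, exact allelic balance."""
        return replace(self, coverage_dispersion=float("inf"), allelic_balance_sd=0.0,
                       hom_error_sd=0.0, exome_genotype_error=0.0,
                       array_genotype_error=0.0, array_nocall_rate=0.0)


def first_cousin_pedigree(n_affected: int = 2, n_unaffected: int = 0,
                          array_for_affected: bool = False) -> tuple[Individual, ...]:
    """Consanguineous nuclear family whose parents are first cousins.

    Exome data for the nuclear family (both parents plus children); the
    grandparental loop individuals carry no data.
    """
    src_child = ("exome", "array") if array_for_affected else ("exome",)
    peds = [
        Individual("GF"), Individual("GM"), Individual("U1"), Individual("U2"),
        Individual("A1", "GF", "GM"), Individual("A2", "GF", "GM"),
        Individual("P1", "A1", "U1", status="unaffected", sources=("exome",)),
        Individual("P2", "A2", "U2", status="unaffected", sources=("exome",)),
    ]
    for k in range(n_affected):
        peds.append(Individual(f"C{k + 1:02d}", "P1", "P2",
                               status="affected", sources=src_child))
    for k in range(n_unaffected):
        peds.append(Individual(f"S{k + 1:02d}", "P1", "P2",
                               status="unaffected", sources=("exome",)))
    return tuple(peds)


def outbred_pedigree(n_affected: int = 2, n_unaffected: int = 2,
                     array_for_all: bool = False) -> tuple[Individual, ...]:
    """Non-consanguineous nuclear family (founder parents)."""
    src = ("exome", "array") if array_for_all else ("exome",)
    peds = [Individual("P1", status="unaffected", sources=src),
            Individual("P2", status="unaffected", sources=src)]
    for k in range(n_affected):
        peds.append(Individual(f"C{k + 1:02d}", "P1", "P2", status="affected", sources=src))
    for k in range(n_unaffected):
        peds.append(Individual(f"S{k + 1:02d}", "P1", "P2", status="unaffected", sources=src))
    return tuple(peds)


def trio_pedigree() -> tuple[Individual, ...]:
    """Founder parents and one affected child, all with exome data."""
    return (Individual("P1", status="unaffected", sources=("exome",)),
            Individual("P2", status="unaffected", sources=("exome",)),
            Individual("C01", "P1", "P2", status="affected", sources=("exome",)))


def first_cousin_config(seed: int, n_affected: int = 2, n_unaffected: int = 0,
                        array_for_affected: bool = False,
                        causal_type: str = "missense", **kw) -> SimConfig:
    """Consanguineous study conditions with a planted recessive causal variant."""
    return SimConfig(
        seed=seed,
        pedigree=first_cousin_pedigree(n_affected, n_unaffected, array_for_affected),
        pedigree_kind="first_cousin",
        planted=(PlantSpec("recessive_causal", causal_type=causal_type),),
        **kw,
    )


def outbred_config(seed: int, n_affected: int = 2, n_unaffected: int = 2,
                   plant_recessive: bool = False, **kw) -> SimConfig:
    planted = (PlantSpec("recessive_causal"),) if plant_recessive else ()
    return SimConfig(seed=seed, pedigree=outbred_pedigree(n_affected, n_unaffected),
                     pedigree_kind="outbred", planted=planted, **kw)


def trio_config(seed: int, with_rs: bool = False, **kw) -> SimConfig:
    return SimConfig(seed=seed, pedigree=trio_pedigree(), pedigree_kind="trio",
                     planted=(PlantSpec("de_novo", target="C01", with_rs=with_rs),), **kw)


def plant_de_novo(config: SimConfig, target: str, with_rs: bool = False) -> SimConfig:
    """Add a de novo heterozygous plant for ``target`` to a configuration."""
    ind = {i.iid: i for i in config.pedigree}.get(target)
    if ind is None:
        raise PedigreeError(f"unknown target sample {target!r}")
    if ind.is_founder:
        raise PedigreeError(f"{target!r} is a founder; de novo planting needs simulated parents")
    return replace(config, planted=config.planted + (PlantSpec("de_novo", target, with_rs),))


# ---------------------------------------------------------------------------
# Genome design
# ---------------------------------------------------------------------------

@dataclass
class ExomeMarkers:
    positions: np.ndarray       # 1-based, strictly increasing
    maf: np.ndarray
    rsids: list[str | None]
    ref: list[str]
    alt: list[str]


@dataclass
class ArrayMarkers:
    ids: list[str]
    positions: np.ndarray
    maf: np.ndarray


@dataclass
class GenomeDesign:
    ref: SyntheticReference
    genes: list[GeneModelRecord]
    exome: dict[str, ExomeMarkers]
    array: dict[str, ArrayMarkers]

    @property
    def n_array_snps(self) -> int:
        return sum(len(a.positions) for a in self.array.values())

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        return self.ref.fetch(chrom, start0, end0)


def _make_gene(ref: SyntheticReference, chrom: str, block: tuple[int, int],
               idx: int, rng: np.random.Generator) -> GeneModelRecord | None:
    b0, b1 = block
    if b1 - b0 < 6_000:
        return None
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    e1_start = b0 + 200
    e1_len = int(3 * rng.integers(100, 400))
    intron = int(rng.integers(500, 3000))
    e2_len = int(3 * rng.integers(150, 600))
    e2_start = e1_start + e1_len + intron
    e2_end = min(e2_start + e2_len, b1 - 200)
    if e2_end - e2_start < 300:
        return None
    cds_start = e1_start + 60
    cds_end = e2_end - 60
    cds_len = (e1_start + e1_len - cds_start) + (cds_end - e2_start)
    cds_end -= cds_len % 3
    cds_len -= cds_len % 3
    if cds_len < 300:
        return None
    rec = GeneModelRecord(
        gene_name=f"GENE{idx:04d}", transcript_id=f"TX{idx:04d}", chrom=chrom,
        strand=strand, exons=[(e1_start, e1_start + e1_len), (e2_start, e2_end)],
        cds_start=cds_start, cds_end=cds_end,
    )
    rec.validate()
    if not rec.valid:
        return None

    # Reference CDS drawn from non-stop codons: ATG ... TAA.
    n_codons = cds_len // 3
    middle = rng.integers(0, len(_NONSTOP), size=n_codons - 2)
    spliced = "ATG" + "".join(_NONSTOP[i] for i in middle) + "TAA"
    genomic = spliced
    if strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        genomic = spliced.translate(comp)[::-1]
    offset = 0
    for s, e in rec.cds_exon_chunks():
        ref.add_overlay(chrom, s, genomic[offset:offset + (e - s)])
        offset += e - s
    return rec


def build_genome(config: SimConfig) -> GenomeDesign:
    """Deterministic genome design for a configuration (keyed by its seed)."""
    rng = np.random.default_rng([config.seed, 0])
    ref = SyntheticReference(list(config.chromosomes), seed=config.seed)
    genes: list[GeneModelRecord] = []
    exome: dict[str, ExomeMarkers] = {}
    array: dict[str, ArrayMarkers] = {}
    gene_idx = 0
    rs_counter = 1_000_000
    ax_counter = 0

    for chrom, length in config.chromosomes:
        cur, genic = 0, False
        marker_pos: list[np.ndarray] = []
        while cur < length:
            mean = config.genic_mean_len if genic else config.intergenic_mean_len
            blk_len = max(1_000, int(rng.exponential(mean)))
            b0, b1 = cur, min(length, cur + blk_len)
            density = (config.genic_marker_density if genic
                       else config.intergenic_marker_density)
            n = rng.poisson((b1 - b0) * density)
            if n:
                marker_pos.append(rng.integers(b0 + 1, b1 + 1, size=n))
            if genic and rng.random() < config.gene_prob:
                gene = _make_gene(ref, chrom, (b0, b1), gene_idx, rng)
                if gene is not None:
                    genes.append(gene)
                    gene_idx += 1
            cur, genic = b1, not genic

        pos = np.unique(np.concatenate(marker_pos)) if marker_pos else np.empty(0, np.int64)
        maf = rng.uniform(config.maf_low, config.maf_high, size=len(pos))
        has_rs = rng.random(len(pos)) < config.rs_fraction
        rsids: list[str | None] = []
        for flagged in has_rs:
            rsids.append(f"rs{rs_counter}" if flagged else None)
            rs_counter += 1
        ref_codes = ref.base_codes_at(chrom, pos - 1)
        shift = rng.integers(1, 4, size=len(pos)).astype(np.uint8)
        alt_codes = (ref_codes + shift) % 4
        exome[chrom] = ExomeMarkers(
            positions=pos, maf=maf, rsids=rsids,
            ref=list(codes_to_seq(ref_codes)), alt=list(codes_to_seq(alt_codes)),
        )

        n_arr = rng.poisson(length * config.array_marker_density)
        apos = np.unique(rng.integers(1, length + 1, size=n_arr))
        array[chrom] = ArrayMarkers(
            ids=[f"AX-{ax_counter + k}" for k in range(len(apos))],
            positions=apos,
            maf=rng.uniform(config.maf_low, config.maf_high, size=len(apos)),
        )
        ax_counter += len(apos)

    return GenomeDesign(ref=ref, genes=genes, exome=exome, array=array)


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

# A haplotype along one chromosome: (segment start positions (0-based, first
# is 0), founder-haplotype ids per segment).
Hap = tuple[np.ndarray, np.ndarray]


def _meiosis(hap_a: Hap, hap_b: Hap, length: int, rate: float,
             rng: np.random.Generator) -> Hap:
    n_x = rng.poisson(length * rate)
    cuts = np.sort(rng.integers(1, length, size=n_x)).astype(np.int64)
    phase = int(rng.integers(0, 2))
    haps = (hap_a, hap_b)
    bounds = np.concatenate(([0], cuts, [length]))
    starts: list[int] = []
    ids: list[int] = []
    for k in range(len(bounds) - 1):
        s, e = int(bounds[k]), int(bounds[k + 1])
        if s >= e:
            continue
        hs, hi = haps[(phase + k) % 2]
        i0 = int(np.searchsorted(hs, s, side="right")) - 1
        i1 = int(np.searchsorted(hs, e, side="left"))
        for t in range(i0, i1):
            st = max(int(hs[t]), s)
            fid = int(hi[t])
            if ids and ids[-1] == fid:
                continue
            starts.append(st)
            ids.append(fid)
    return np.asarray(starts, dtype=np.int64), np.asarray(ids, dtype=np.int64)


def _ids_at(hap: Hap, positions0: np.ndarray) -> np.ndarray:
    starts, ids = hap
    idx = np.searchsorted(starts, positions0, side="right") - 1
    return ids[idx]


def _autozygous_segments(h1: Hap, h2: Hap, length: int) -> list[tuple[int, int]]:
    """Maximal 1-based inclusive intervals where both haplotype ids match."""
    bounds = np.unique(np.concatenate((h1[0], h2[0], [0, length])))
    out: list[tuple[int, int]] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if s >= length:
            break
        same = _ids_at(h1, np.array([s]))[0] == _ids_at(h2, np.array([s]))[0]
        if same:
            if out and out[-1][1] == s:
                out[-1] = (out[-1][0], int(e))
            else:
                out.append((int(s), int(e)))
    return [(s + 1, e) for s, e in out]


class _Drop:
    """One realised gene-drop: per-individual haplotypes by chromosome."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.by_id = {i.iid: i for i in config.pedigree}
        founders = [i.iid for i in config.pedigree if i.is_founder]
        self.founder_hap_ids = {iid: (2 * k, 2 * k + 1) for k, iid in enumerate(founders)}
        self.n_haps = 2 * len(founders)
        self.haps: dict[str, list[tuple[Hap, Hap]]] = {}

    def founder_haps(self, iid: str) -> list[tuple[Hap, Hap]]:
        a, b = self.founder_hap_ids[iid]
        zero = np.zeros(1, dtype=np.int64)
        return [((zero.copy(), np.array([a])), (zero.copy(), np.array([b])))
                for _ in self.config.chromosomes]

    def drop_individual(self, ind: Individual, rng: np.random.Generator) -> None:
        if ind.is_founder:
            self.haps[ind.iid] = self.founder_haps(ind.iid)
            return
        out = []
        for c, (_name, length) in enumerate(self.config.chromosomes):
            pat = _meiosis(*self.haps[ind.father][c], length,
                           self.config.crossover_rate, rng)
            mat = _meiosis(*self.haps[ind.mother][c], length,
                           self.config.crossover_rate, rng)
            out.append((pat, mat))
        self.haps[ind.iid] = out

    def ids_at(self, iid: str, chrom_idx: int, pos0: int) -> tuple[int, int]:
        h1, h2 = self.haps[iid][chrom_idx]
        p = np.array([pos0])
        return int(_ids_at(h1, p)[0]), int(_ids_at(h2, p)[0])

    def truth_segments(self, iid: str) -> dict[str, list[tuple[int, int]]]:
        out = {}
        for c, (name, length) in enumerate(self.config.chromosomes):
            h1, h2 = self.haps[iid][c]
            segs = _autozygous_segments(h1, h2, length)
            if segs:
                out[name] = segs
        return out


def _drop_pedigree(config: SimConfig, rng: np.random.Generator,
                   causal: tuple[int, int] | None,
                   max_tries: int = 200_000) -> tuple[_Drop, set[int] | None]:
    """Gene-drop the pedigree, conditioning on the causal locus if given.

    Returns the drop plus the carrier founder-haplotype ids (None when
    unconditioned).  Conditioning accepts a drop iff every affected offspring
    inherited carrier haplotypes from both parents at the locus and no
    unaffected individual did.
    """
    drop = _Drop(config)
    for ind in config.pedigree:
        if ind.is_founder:
            drop.drop_individual(ind, rng)
    non_founders = [i for i in config.pedigree if not i.is_founder]
    affected = [i.iid for i in config.pedigree if i.status == "affected"]

    if causal is None:
        for ind in non_founders:
            drop.drop_individual(ind, rng)
        return drop, None

    if not affected:
        raise PedigreeError("a recessive causal variant needs affected offspring")
    c_chrom, c_pos0 = causal

    if config.pedigree_kind == "outbred":
        aff_parents = {drop.by_id[a].father for a in affected} | \
                      {drop.by_id[a].mother for a in affected}
        if len(aff_parents) != 2:
            raise PedigreeError("affected offspring must share both parents")
        father = drop.by_id[affected[0]].father
        mother = drop.by_id[affected[0]].mother
        carriers = {drop.founder_hap_ids[father][0], drop.founder_hap_ids[mother][0]}
    else:
        carriers = None  # determined by the accepted drop (shared grandparental hap)

    gp_hap_ids: set[int] = set()
    if config.pedigree_kind == "first_cousin":
        # The shared founder couple are the founders appearing as parents of
        # two different non-founders (the sibling parents of the two cousins).
        parent_counts: dict[str, int] = {}
        for i in non_founders:
            for pid in (i.father, i.mother):
                if drop.by_id[pid].is_founder:
                    parent_counts[pid] = parent_counts.get(pid, 0) + 1
        shared = [pid for pid, n in parent_counts.items() if n >= 2]
        for pid in shared:
            gp_hap_ids.update(drop.founder_hap_ids[pid])
        if not gp_hap_ids:
            raise PedigreeError("first-cousin pedigree has no shared founder couple")

    for _ in range(max_tries):
        for ind in non_founders:
            drop.drop_individual(ind, rng)
        if config.pedigree_kind == "first_cousin":
            hs = set()
            ok = True
            for a in affected:
                ia, ib = drop.ids_at(a, c_chrom, c_pos0)
                if ia != ib or ia not in gp_hap_ids:
                    ok = False
                    break
                hs.add(ia)
            if not ok or len(hs) != 1:
                continue
            h = hs.pop()
            carriers = {h}
        else:
            ok = True
            for a in affected:
                ia, ib = drop.ids_at(a, c_chrom, c_pos0)
                if not ({ia, ib} <= carriers and ia != ib):
                    ok = False
                    break
            if not ok:
                continue
        # no unaffected individual may be homozygous for a carrier hap
        bad = False
        for iid in (i.iid for i in non_founders if i.status != "affected"):
            ia, ib = drop.ids_at(iid, c_chrom, c_pos0)
            if ia == ib and ia in carriers:
                bad = True
                break
        if bad:
            continue
        return drop, carriers
    raise RuntimeError("conditioning on the causal locus did not converge")


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedVariant:
    kind: str
    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None
    gene_name: str | None
    expected_genotypes: dict[str, str] = field(default_factory=dict, hash=False, compare=False)


@dataclass
class TruthSet:
    """Exact truth for one simulated pedigree."""

    segments: dict[str, dict[str, list[tuple[int, int]]]]   # sample -> chrom -> intervals
    planted: list[PlantedVariant]

    def segments_list(self, sample_id: str) -> list[tuple[str, int, int]]:
        return [(chrom, s, e)
                for chrom, ivs in self.segments.get(sample_id, {}).items()
                for s, e in ivs]


# ---------------------------------------------------------------------------
# Planted-variant placement
# ---------------------------------------------------------------------------

def _pick_coding_snv(genome: GenomeDesign, rng: np.random.Generator,
                     want: str = "missense",
                     avoid: set[tuple[str, int]] = frozenset(),
                     ) -> tuple[GeneModelRecord, int, str, str]:
    """A CDS position and alternate base with a protein-changing consequence.

    Returns (gene, 1-based pos, ref, alt).  ``want`` is "missense" (accepting
    nonsense as a fallback never happens: the base is re-drawn) or
    "frameshift" (a 1-bp deletion; ref is two bases, alt one).
    """
    if not genome.genes:
        raise RuntimeError("genome design contains no genes")
    for _ in range(10_000):
        gene = genome.genes[int(rng.integers(0, len(genome.genes)))]
        chunks = gene.cds_exon_chunks()
        s, e = chunks[int(rng.integers(0, len(chunks)))]
        pos0 = int(rng.integers(s, e))
        pos = pos0 + 1
        if (gene.chrom, pos) in avoid:
            continue
        ref_base = genome.fetch(gene.chrom, pos0, pos0 + 1)
        if want == "frameshift":
            if pos0 + 2 > e:   # keep the deleted base inside the CDS chunk
                continue
            ref = genome.fetch(gene.chrom, pos0, pos0 + 2)
            effects = annotate_variant(gene.chrom, pos, ref, ref_base,
                                       [gene], genome.fetch)
            if any(x.consequence == "frameshift" for x in effects):
                return gene, pos, ref, ref_base
            continue
        for alt in "ACGT":
            if alt == ref_base:
                continue
            effects = annotate_variant(gene.chrom, pos, ref_base, alt,
                                       [gene], genome.fetch)
            if any(x.consequence in ("missense", "nonsense") for x in effects):
                return gene, pos, ref_base, alt
    raise RuntimeError("could not place a coding variant")


# ---------------------------------------------------------------------------
# Simulation result
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """In-memory outputs of one simulated pedigree, plus writers."""

    config: SimConfig
    genome: GenomeDesign
    pedigree: list[PedigreeRecord]
    vcf_records: dict[str, list[VcfSiteRecord]]
    depth_tables: dict[str, DepthTable]
    array_table: ArrayGenotypeTable | None
    truth: TruthSet

    @property
    def exome_samples(self) -> list[str]:
        return sorted(self.vcf_records)

    def write(self, outdir: str | Path, write_reference: bool = False) -> dict[str, Path]:
        """Emit every input file the tool reads, plus the truth set."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        for sid in self.exome_samples:
            vp = outdir / f"{sid}.vcf"
            _write_vcf(vp, sid, self.vcf_records[sid], self.config.chromosomes)
            paths[f"vcf:{sid}"] = vp
            dt = self.depth_tables.get(sid)
            if dt is not None:
                tp = outdir / f"{sid}.txt"
                _write_depth_file(tp, dt)
                paths[f"depth:{sid}"] = tp

        ped_path = outdir / "pedigree.tsv"
        write_pedigree(self.pedigree, ped_path)
        paths["pedigree"] = ped_path

        if self.array_table is not None:
            ap = outdir / "array_genotypes.tsv"
            _write_array_table(ap, self.array_table)
            paths["array"] = ap

        gp = outdir / "genes.refFlat"
        _write_refflat(gp, self.genome.genes)
        paths["genes"] = gp

        tb = outdir / "truth_segments.bed"
        with open(tb, "w") as fh:
            for sid in sorted(self.truth.segments):
                for chrom, ivs in self.truth.segments[sid].items():
                    for s, e in ivs:
                        fh.write(f"{chrom}\t{s - 1}\t{e}\t{sid}\n")
        paths["truth_segments"] = tb

        tv = outdir / "truth_variants.tsv"
        with open(tv, "w") as fh:
            fh.write("#kind\tchrom\tpos\tref\talt\trsid\tgene\texpected_genotypes\n")
            for pv in self.truth.planted:
                exp = ";".join(f"{k}={v}" for k, v in sorted(pv.expected_genotypes.items()))
                fh.write(f"{pv.kind}\t{pv.chrom}\t{pv.pos}\t{pv.ref}\t{pv.alt}\t"
                         f"{pv.rsid or '.'}\t{pv.gene_name or '.'}\t{exp}\n")
        paths["truth_variants"] = tv

        if write_reference:
            fa = outdir / "reference.fa"
            self.genome.ref.write_fasta(fa)
            paths["reference"] = fa
        return paths


def _write_vcf(path: Path, sample_id: str, records: list[VcfSiteRecord],
               chromosomes) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=autozygmap-simulate (synthetic data)\n")
        for name, length in chromosomes:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref,alt)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_id}\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.id or '.'}\t{r.ref}\t{r.alt}\t.\t.\t.\t"
                     f"GT:AD\t{r.declared_genotype}:{r.ref_depth},{r.alt_depth}\n")


def _write_depth_file(path: Path, table: DepthTable) -> None:
    with open(path, "w") as fh:
        fh.write(f"Locus\tTotal_Depth\tAverage_Depth_sample\tDepth_for_{table.sample_id}\n")
        for (chrom, pos), depth in sorted(table.depths.items()):
            fh.write(f"{chrom}:{pos}\t{depth}\t{depth:.2f}\t{depth}\n")


def _write_array_table(path: Path, table: ArrayGenotypeTable) -> None:
    sids = table.sample_ids
    with open(path, "w") as fh:
        fh.write("marker\tchrom\tpos\t" + "\t".join(sids) + "\n")
        for k in range(len(table.markers)):
            calls = "\t".join(str(CODE_TO_STATE[table.calls[s][k]]) for s in sids)
            fh.write(f"{table.markers[k]}\t{table.chroms[k]}\t{table.positions[k]}\t{calls}\n")


def _write_refflat(path: Path, genes: list[GeneModelRecord]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            fh.write("\t".join([
                g.gene_name, g.transcript_id, g.chrom, g.strand,
                str(g.tx_start), str(g.tx_end), str(g.cds_start), str(g.cds_end),
                str(len(g.exons)), starts, ends,
            ]) + "\n")


# ---------------------------------------------------------------------------
# Main entry point
# ---------------------------------------------------------------------------

def _draw_depths(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if not np.isfinite(config.coverage_dispersion):
        return np.full(n, int(round(config.mean_coverage)), dtype=np.int64)
    k = config.coverage_dispersion
    p = k / (k + config.mean_coverage)
    return rng.negative_binomial(k, p, size=n).astype(np.int64)


def _alt_reads(g: np.ndarray, depths: np.ndarray, config: SimConfig,
               rng: np.random.Generator) -> np.ndarray:
    """Alternate-allele read counts given genotypes (0/1/2 alt copies)."""
    n = len(g)
    alt = np.zeros(n, dtype=np.int64)
    het = g == 1
    if het.any():
        if config.allelic_balance_sd > 0:
            f = np.clip(rng.normal(0.5, config.allelic_balance_sd, size=int(het.sum())),
                        0.0, 1.0)
        else:
            f = np.full(int(het.sum()), 0.5)
        alt[het] = np.rint(depths[het] * f).astype(np.int64)
    hom_alt = g == 2
    if hom_alt.any():
        stray = _stray_fraction(int(hom_alt.sum()), config, rng)
        alt[hom_alt] = depths[hom_alt] - np.rint(depths[hom_alt] * stray).astype(np.int64)
    hom_ref = g == 0
    if hom_ref.any():
        stray = _stray_fraction(int(hom_ref.sum()), config, rng)
        alt[hom_ref] = np.rint(depths[hom_ref] * stray).astype(np.int64)
    return np.clip(alt, 0, depths)


def _stray_fraction(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.hom_error_sd <= 0:
        return np.zeros(n)
    return np.abs(rng.normal(0.0, config.hom_error_sd, size=n))


def simulate_pedigree(config: SimConfig) -> SimResult:
    """Simulate one pedigree under the configured study conditions.

    Deterministic for a fixed config: the same seed yields byte-identical
    output files.  Raises if the pedigree is malformed or a planted variant's
    precondition fails (e.g. a de novo target without simulated parents).
    """
    if not config.pedigree:
        raise PedigreeError("empty pedigree")
    by_id = {i.iid: i for i in config.pedigree}
    if len(by_id) != len(config.pedigree):
        raise PedigreeError("duplicate sample ids in pedigree")
    for ind in config.pedigree:
        for pid in (ind.father, ind.mother):
            if pid is not None and pid not in by_id:
                raise PedigreeError(f"{ind.iid}: unknown parent {pid!r}")
    for spec in config.planted:
        if spec.kind not in ("recessive_causal", "de_novo", "deletion_hom"):
            raise ValueError(f"unknown planted-variant kind {spec.kind!r}")
        if spec.kind in ("de_novo", "deletion_hom") and spec.target != "affected":
            ind = by_id.get(spec.target)
            if ind is None:
                raise PedigreeError(f"unknown planted target {spec.target!r}")
            if ind.is_founder:
                raise PedigreeError(
                    f"{spec.target!r} is a founder; planting needs simulated parents")

    genome = build_genome(config)
    rng_drop = np.random.default_rng([config.seed, 1])
    rng_geno = np.random.default_rng([config.seed, 2])
    chrom_names = [name for name, _l in config.chromosomes]
    chrom_index = {name: i for i, name in enumerate(chrom_names)}

    # --- choose planted positions (before the drop: the recessive site
    # conditions it), avoiding collisions with designed markers ---
    marker_positions = {(c, int(p)) for c in chrom_names
                        for p in genome.exome[c].positions}
    recessive = [s for s in config.planted if s.kind == "recessive_causal"]
    if len(recessive) > 1:
        raise ValueError("at most one recessive causal variant may be planted")
    causal_site = None
    if recessive:
        want = "frameshift" if recessive[0].causal_type == "frameshift" else "missense"
        gene, pos, ref, alt = _pick_coding_snv(genome, rng_drop, want,
                                               avoid=marker_positions)
        causal_site = (gene, pos, ref, alt)

    causal_locus = None
    if causal_site is not None:
        causal_locus = (chrom_index[causal_site[0].chrom], causal_site[1] - 1)
    drop, carriers = _drop_pedigree(config, rng_drop, causal_locus)

    # --- founder alleles at designed markers ---
    founder_alleles_ex = {
        c: rng_geno.random((drop.n_haps, len(genome.exome[c].positions)))
           < genome.exome[c].maf
        for c in chrom_names
    }
    founder_alleles_ar = {
        c: rng_geno.random((drop.n_haps, len(genome.array[c].positions)))
           < genome.array[c].maf
        for c in chrom_names
    }

    # --- assemble per-chromosome exome site lists (markers + planted) ---
    site_pos = {c: genome.exome[c].positions.copy() for c in chrom_names}
    site_rsid = {c: list(genome.exome[c].rsids) for c in chrom_names}
    site_ref = {c: list(genome.exome[c].ref) for c in chrom_names}
    site_alt = {c: list(genome.exome[c].alt) for c in chrom_names}
    site_alleles = founder_alleles_ex
    overrides: dict[tuple[str, int], dict[str, int]] = {}
    planted_truth: list[PlantedVariant] = []

    def insert_site(chrom: str, pos: int, rsid: str | None, ref: str, alt: str,
                    hap_alleles: np.ndarray) -> None:
        k = int(np.searchsorted(site_pos[chrom], pos))
        site_pos[chrom] = np.insert(site_pos[chrom], k, pos)
        site_rsid[chrom].insert(k, rsid)
        site_ref[chrom].insert(k, ref)
        site_alt[chrom].insert(k, alt)
        site_alleles[chrom] = np.insert(site_alleles[chrom], k, hap_alleles, axis=1)

    rs_plant = 86_000_001
    affected_ids = [i.iid for i in config.pedigree if i.status == "affected"]
    data_samples = [i for i in config.pedigree if i.sources]
    exome_ids = sorted(i.iid for i in data_samples if "exome" in i.sources)
    array_ids = sorted(i.iid for i in data_samples if "array" in i.sources)

    if causal_site is not None:
        gene, pos, ref, alt = causal_site
        hap_alleles = np.array([h in carriers for h in range(drop.n_haps)])
        insert_site(gene.chrom, pos, None, ref, alt, hap_alleles)
        expected = {}
        for i in data_samples:
            if "exome" not in i.sources:
                continue
            ia, ib = drop.ids_at(i.iid, chrom_index[gene.chrom], pos - 1)
            g = int(ia in carriers) + int(ib in carriers)
            expected[i.iid] = _G_TO_STATE[g]
        planted_truth.append(PlantedVariant(
            kind="recessive_causal", chrom=gene.chrom, pos=pos, ref=ref, alt=alt,
            rsid=None, gene_name=gene.gene_name, expected_genotypes=expected,
        ))

    taken = set(marker_positions) | {(pv.chrom, pv.pos) for pv in planted_truth}
    for spec in config.planted:
        if spec.kind == "recessive_causal":
            continue
        targets = affected_ids if spec.target == "affected" else [spec.target]
        gene, pos, ref, alt = _pick_coding_snv(genome, rng_drop, "missense", avoid=taken)
        taken.add((gene.chrom, pos))
        rsid = None
        if spec.with_rs:
            rsid = f"rs{rs_plant}"
            rs_plant += 1
        insert_site(gene.chrom, pos, rsid, ref, alt,
                    np.zeros(drop.n_haps, dtype=bool))
        expected = {sid: "AA" for sid in exome_ids}
        for t in targets:
            if spec.kind == "de_novo":
                overrides.setdefault((gene.chrom, pos), {})[t] = 1
                expected[t] = "AB"
            else:  # deletion_hom: offspring homozygous-variant, one parent AA
                ind = by_id[t]
                overrides.setdefault((gene.chrom, pos), {})[t] = 2
                if ind.mother is not None:
                    overrides[(gene.chrom, pos)][ind.mother] = 1
                expected[t] = "BB"
                if ind.mother in expected:
                    expected[ind.mother] = "AB"
        planted_truth.append(PlantedVariant(
            kind=spec.kind, chrom=gene.chrom, pos=pos, ref=ref, alt=alt,
            rsid=rsid, gene_name=gene.gene_name, expected_genotypes=expected,
        ))

    # --- per-sample genotypes and data emission ---
    vcf_records: dict[str, list[VcfSiteRecord]] = {}
    depth_tables: dict[str, DepthTable] = {}
    for sid in exome_ids:
        recs: list[VcfSiteRecord] = []
        table = DepthTable(sample_id=sid)
        for c in chrom_names:
            pos = site_pos[c]
            if len(pos) == 0:
                continue
            h1, h2 = drop.haps[sid][chrom_index[c]]
            ids1 = _ids_at(h1, pos - 1)
            ids2 = _ids_at(h2, pos - 1)
            alleles = site_alleles[c]
            g = (alleles[ids1, np.arange(len(pos))].astype(np.int8)
                 + alleles[ids2, np.arange(len(pos))].astype(np.int8))
            # planted-genotype overrides, then random genotyping errors
            for k, p in enumerate(pos):
                ov = overrides.get((c, int(p)))
                if ov and sid in ov:
                    g[k] = ov[sid]
            if config.exome_genotype_error > 0:
                err = rng_geno.random(len(pos)) < config.exome_genotype_error
                if err.any():
                    g[err] = (g[err] + rng_geno.integers(1, 3, size=int(err.sum()))) % 3
            depths = _draw_depths(len(pos), config, rng_geno)
            alt_reads = _alt_reads(g, depths, config, rng_geno)
            for k in np.flatnonzero(g > 0):
                declared = "0/1" if g[k] == 1 else "1/1"
                recs.append(VcfSiteRecord(
                    chrom=c, pos=int(pos[k]), id=site_rsid[c][k],
                    ref=site_ref[c][k], alt=site_alt[c][k],
                    ref_depth=int(depths[k] - alt_reads[k]),
                    alt_depth=int(alt_reads[k]),
                    declared_genotype=declared,
                ))
            for k in range(len(pos)):
                table.depths[(c, int(pos[k]))] = int(depths[k])
        vcf_records[sid] = recs
        depth_tables[sid] = table

    array_table = None
    if array_ids:
        markers: list[str] = []
        chroms: list[str] = []
        positions: list[int] = []
        calls = {sid: [] for sid in array_ids}
        for c in chrom_names:
            am = genome.array[c]
            markers.extend(am.ids)
            chroms.extend([c] * len(am.positions))
            positions.extend(int(p) for p in am.positions)
            for sid in array_ids:
                h1, h2 = drop.haps[sid][chrom_index[c]]
                ids1 = _ids_at(h1, am.positions - 1)
                ids2 = _ids_at(h2, am.positions - 1)
                al = founder_alleles_ar[c]
                g = (al[ids1, np.arange(len(am.positions))].astype(np.int8)
                     + al[ids2, np.arange(len(am.positions))].astype(np.int8))
                if config.array_genotype_error > 0:
                    err = rng_geno.random(len(g)) < config.array_genotype_error
                    if err.any():
                        g[err] = (g[err] + rng_geno.integers(1, 3, size=int(err.sum()))) % 3
                codes = g.astype(np.int8)  # 0->AA,1->AB,2->BB matches state codes
                if config.array_nocall_rate > 0:
                    nc = rng_geno.random(len(g)) < config.array_nocall_rate
                    codes[nc] = 3
                calls[sid].append(codes)
        array_table = ArrayGenotypeTable(
            markers=markers,
            chroms=np.array(chroms, dtype=object),
            positions=np.array(positions, dtype=np.int64),
            calls={sid: np.concatenate(calls[sid]) for sid in array_ids},
            n_snps=len(markers),
        )

    truth_segments = {
        i.iid: drop.truth_segments(i.iid)
        for i in data_samples
    }

    pedigree_records = [
        PedigreeRecord(sample_id=i.iid, father_id=i.father, mother_id=i.mother,
                       status=i.status if i.status != "unknown" else "unknown",
                       sources=i.sources or ())
        for i in config.pedigree
    ]

    return SimResult(
        config=config, genome=genome, pedigree=pedigree_records,
        vcf_records=vcf_records, depth_tables=depth_tables,
        array_table=array_table,
        truth=TruthSet(segments=truth_segments, planted=planted_truth),
    )


def simulate_truth(config: SimConfig) -> TruthSet:
    """Gene-drop only (no genotype emission): truth segments for all samples.

    Unconditioned unless a recessive variant is planted; handy for checking
    pedigree-level expectations such as the inbreeding coefficient.
    """
    if config.planted:
        raise ValueError("simulate_truth is for unconditioned drops; remove plants")
    rng = np.random.default_rng([config.seed, 1])
    drop, _ = _drop_pedigree(config, rng, None)
    segments = {i.iid: drop.truth_segments(i.iid) for i in config.pedigree
                if not i.is_founder}
    return TruthSet(segments=segments, planted=[])
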