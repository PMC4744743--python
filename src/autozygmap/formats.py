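"""Readers and writers for every external file the tool touches.

Input formats:

* per-sample VCF 4.x with per-genotype allele depths (read via cyvcf2),
* GATK DepthOfCoverage-style read-depth tables (``chrom:pos<TAB>depth``),
* tab-delimited microarray genotype tables,
* refFlat/genePred gene-model tables plus an indexed genome FASTA,
* a pedigree/status table.

Output formats: the unified-dataset TSV (also read back) and BED for regions.

Coordinate conventions: VCF, depth tables and all user-facing reports are
1-based; gene-model coordinates are converted to 0-based half-open on read;
BED output is 0-based half-open.  Chromosome names are normalised by
stripping any ``chr`` prefix so that mixed-source inputs match.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataFormatError
from .genotyping import AA, AB, BB, NOCALL, STATES, STATE_TO_CODE, CODE_TO_STATE

logger = logging.getLogger(__name__)


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix (case-insensitive)."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def chrom_sort_key(chrom: str):
    """Numeric chromosomes first in numeric order, then others lexically."""
    c = normalize_chrom(chrom)
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VcfSiteRecord:
    """One biallelic variant record from a single-sample VCF.

    Multi-allelic lines are split into one record per alternate allele; each
    split record carries the shared reference depth and that allele's own
    alternate depth.  ``declared_genotype`` is retained verbatim but never
    trusted.  ``depth_missing`` flags records whose allele depths could not
    be parsed; they are kept (not dropped) with zero depths.
    """

    chrom: str
    pos: int
    id: str | None
    ref: str
    alt: str
    ref_depth: int
    alt_depth: int
    declared_genotype: str = "./."
    depth_missing: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError(f"invalid alleles ref={self.ref!r} alt={self.alt!r}")
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("allele depths must be >= 0")


def read_vcf(path: str | Path,
             fallback_depth_fields: tuple[str, str] | None = ("RO", "AO"),
             ) -> tuple[list[VcfSiteRecord], str]:
    """Read a single-sample VCF into sorted, split-normalised site records.

    Allele depths are taken from the per-genotype ``AD`` field; if a record
    lacks ``AD`` and ``fallback_depth_fields`` (reference-observation /
    alternate-observation counts) are present, those are used instead.
    Records with no parseable depths are returned flagged rather than
    dropped.  If *no* record in the file has parseable depths, that is a hard
    error naming the file.

    Returns the records plus the sample id from the VCF header.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare exceptions
        raise DataFormatError(f"{path}: cannot open as VCF: {exc}") from exc
    if len(vcf.samples) != 1:
        raise DataFormatError(
            f"{path}: expected a single-sample VCF, found {len(vcf.samples)} samples"
        )
    sample_id = vcf.samples[0]

    records: list[VcfSiteRecord] = []
    n_with_depth = 0
    line_no = 0
    try:
        for v in vcf:
            line_no += 1
            alts = [a for a in (v.ALT or []) if a and a != "."]
            if not alts:
                continue
            gt = v.genotypes[0] if v.genotypes else [-1, -1, False]
            sep = "|" if gt[-1] else "/"
            declared = sep.join("." if a < 0 else str(a) for a in gt[:-1])
            rsid = v.ID if v.ID and v.ID != "." else None

            ad = None
            try:
                raw = v.format("AD")
            except Exception:
                raw = None
            if raw is not None:
                row = np.asarray(raw[0]).ravel()
                if row.size >= 1 + len(alts) and (row[: 1 + len(alts)] >= 0).all():
                    ad = [int(x) for x in row[: 1 + len(alts)]]
            if ad is None and fallback_depth_fields is not None:
                try:
                    ro = v.format(fallback_depth_fields[0])
                    ao = v.format(fallback_depth_fields[1])
                except Exception:
                    ro = ao = None
                if ro is not None and ao is not None:
                    aod = np.asarray(ao[0]).ravel()
                    rod = int(np.asarray(ro[0]).ravel()[0])
                    if rod >= 0 and aod.size >= len(alts) and (aod[: len(alts)] >= 0).all():
                        ad = [rod] + [int(x) for x in aod[: len(alts)]]

            for i, alt in enumerate(alts):
                if ad is not None:
                    rec = VcfSiteRecord(
                        chrom=normalize_chrom(v.CHROM), pos=v.POS, id=rsid,
                        ref=v.REF, alt=alt, ref_depth=ad[0], alt_depth=ad[1 + i],
                        declared_genotype=declared,
                    )
                    n_with_depth += 1
                else:
                    rec = VcfSiteRecord(
                        chrom=normalize_chrom(v.CHROM), pos=v.POS, id=rsid,
                        ref=v.REF, alt=alt, ref_depth=0, alt_depth=0,
                        declared_genotype=declared, depth_missing=True,
                    )
                records.append(rec)
    except DataFormatError:
        raise
    except Exception as exc:
        raise DataFormatError(
            f"{path}: malformed VCF record near data line {line_no + 1}: {exc}"
        ) from exc

    if records and n_with_depth == 0:
        raise DataFormatError(
            f"{path}: no record carries a parseable allele-depth field "
            "(AD or configured fallback)"
        )
    records.sort(key=lambda r: (chrom_sort_key(r.chrom), r.pos, r.ref, r.alt))
    return records, sample_id


# ---------------------------------------------------------------------------
# Read-depth tables
# ---------------------------------------------------------------------------

@dataclass
class DepthTable:
    """Per-sample total read depth keyed by (chrom, 1-based pos)."""

    sample_id: str
    depths: dict[tuple[str, int], int] = field(default_factory=dict)

    def get(self, chrom: str, pos: int) -> int | None:
        return self.depths.get((normalize_chrom(chrom), pos))


_LOCUS_RE = re.compile(r"^(\S+):(\d+)$")


def read_depth_file(path: str | Path, sample_id: str | None = None) -> DepthTable:
    """Read a DepthOfCoverage-style table: ``chrom:pos<TAB>total_depth ...``.

    A header row on the first line is skipped.  Duplicate loci are logged and
    the last value wins.
    """
    path = Path(path)
    table = DepthTable(sample_id=sample_id or path.stem)
    n_dup = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            m = _LOCUS_RE.match(parts[0])
            if m is None:
                if line_no == 1:  # DepthOfCoverage header ("Locus  Total_Depth ...")
                    continue
                raise DataFormatError(f"{path}: unparseable locus on line {line_no}: {parts[0]!r}")
            if len(parts) < 2:
                raise DataFormatError(f"{path}: missing depth column on line {line_no}")
            try:
                depth = int(parts[1])
            except ValueError as exc:
                if line_no == 1:
                    continue
                raise DataFormatError(f"{path}: bad depth on line {line_no}: {parts[1]!r}") from exc
            if depth < 0:
                raise DataFormatError(f"{path}: negative depth on line {line_no}")
            key = (normalize_chrom(m.group(1)), int(m.group(2)))
            if key in table.depths:
                n_dup += 1
            table.depths[key] = depth
    if n_dup:
        logger.warning("%s: %d duplicate loci (last value kept)", path, n_dup)
    return table


def pair_vcf_and_depth_files(folder: str | Path) -> list[tuple[Path, Path | None]]:
    """Pair ``*.vcf`` files with same-stem ``*.txt`` read-depth files.

    Deterministic (sorted by file name) and independent of directory listing
    order.  Unpaired ``*.txt`` files are logged and ignored; a folder with no
    VCF files is a hard error.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise DataFormatError(f"{folder}: not a directory")
    vcfs = sorted(folder.glob("*.vcf"))
    txts = {p.stem: p for p in folder.glob("*.txt")}
    if not vcfs:
        raise DataFormatError(f"{folder}: no VCF files found")
    pairs = [(v, txts.pop(v.stem, None)) for v in vcfs]
    for leftover in sorted(txts.values()):
        logger.warning("unpaired read-depth file ignored: %s", leftover)
    return pairs


# ---------------------------------------------------------------------------
# Microarray genotype tables
# ---------------------------------------------------------------------------

_ARRAY_TOKEN_MAP = {
    "AA": AA, "AB": AB, "BA": AB, "BB": BB,
    "NC": NOCALL, "NOCALL": NOCALL, "NO CALL": NOCALL, "--": NOCALL, "NN": NOCALL,
}


@dataclass
class ArrayGenotypeTable:
    """Microarray SNP genotypes: one call per marker per sample.

    Calls are stored as int8 codes (see :mod:`autozygmap.genotyping`);
    ``n_snps`` is the number of genotypes on the array *design*, which sets
    the interrupting-heterozygote run requirement.
    """

    markers: list[str]
    chroms: np.ndarray          # object array of normalised chromosome names
    positions: np.ndarray       # int64, 1-based
    calls: dict[str, np.ndarray]  # sample -> int8 codes
    n_snps: int

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls)

    def states(self, sample_id: str) -> list[str]:
        return [str(s) for s in CODE_TO_STATE[self.calls[sample_id]]]


def read_array_genotypes(path: str | Path, n_snps_on_design: int,
                         min_array_size: int = 10_000) -> ArrayGenotypeTable:
    """Read a tab-delimited array genotype table.

    Layout: ``marker  chrom  pos  <sample1> <sample2> ...`` with calls in
    {AA, AB, BB} plus assorted no-call spellings (``NC``, ``NoCall``,
    ``--``, ``NN``).  Rows are sorted by (chrom, pos).  Arrays whose design
    holds no more than ``min_array_size`` genotypes are rejected: the
    run-length scaling (n_snps x 7e-4) is meaningless below that.
    """
    if n_snps_on_design <= min_array_size:
        raise DataFormatError(
            f"array design has {n_snps_on_design} genotypes; analysis is limited to "
            f"microarrays with more than {min_array_size} genotypes"
        )
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 4:
        raise DataFormatError(f"{path}: expected marker, chrom, pos + >=1 sample column")
    marker_col, chrom_col, pos_col = df.columns[:3]
    sample_cols = list(df.columns[3:])
    try:
        pos = df[pos_col].astype(np.int64)
    except ValueError as exc:
        raise DataFormatError(f"{path}: non-integer position in column {pos_col!r}") from exc
    df = df.assign(__pos=pos, __chrom=df[chrom_col].map(normalize_chrom))
    df = df.sort_values(
        by=["__chrom", "__pos"],
        key=lambda col: col.map(chrom_sort_key) if col.name == "__chrom" else col,
        kind="mergesort",
    ).reset_index(drop=True)
    if n_snps_on_design < len(df):
        raise DataFormatError(
            f"{path}: {len(df)} markers present exceeds design size {n_snps_on_design}"
        )

    calls: dict[str, np.ndarray] = {}
    for col in sample_cols:
        tokens = df[col].fillna("NC").str.strip().str.upper()
        mapped = tokens.map(_ARRAY_TOKEN_MAP)
        if mapped.isna().any():
            bad = tokens[mapped.isna()].iloc[0]
            raise DataFormatError(f"{path}: unknown genotype token {bad!r} in column {col!r}")
        calls[col] = np.array([STATE_TO_CODE[s] for s in mapped], dtype=np.int8)

    return ArrayGenotypeTable(
        markers=df[marker_col].tolist(),
        chroms=df["__chrom"].to_numpy(dtype=object),
        positions=df["__pos"].to_numpy(dtype=np.int64),
        calls=calls,
        n_snps=n_snps_on_design,
    )


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedigreeRecord:
    """One individual's pedigree role and data sources."""

    sample_id: str
    father_id: str | None = None
    mother_id: str | None = None
    status: str = "unknown"          # affected | unaffected | unknown
    sources: tuple[str, ...] = ("exome",)

    def __post_init__(self) -> None:
        if self.status not in ("affected", "unaffected", "unknown"):
            raise ValueError(f"bad status {self.status!r}")
        for s in self.sources:
            if s not in ("exome", "array"):
                raise ValueError(f"bad data source {s!r}")

    @property
    def source(self) -> str:
        return self.sources[0] if self.sources else "exome"


def read_pedigree(path: str | Path) -> list[PedigreeRecord]:
    """Read a pedigree/status table.

    Tab-delimited columns: sample_id, father_id, mother_id, status, source
    (``.`` for a missing parent; source may be a comma list, e.g.
    ``exome,array``).  A ``#`` header line is allowed.  Parent ids must refer
    to samples in the same file.
    """
    records: list[PedigreeRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise DataFormatError(f"{path}: expected 5 columns on line {line_no}")
            sid, father, mother, status, source = parts[:5]
            try:
                records.append(PedigreeRecord(
                    sample_id=sid,
                    father_id=None if father in (".", "") else father,
                    mother_id=None if mother in (".", "") else mother,
                    status=status,
                    sources=tuple(s.strip() for s in source.split(",") if s.strip()),
                ))
            except ValueError as exc:
                raise DataFormatError(f"{path}: line {line_no}: {exc}") from exc
    ids = {r.sample_id for r in records}
    if len(ids) != len(records):
        raise DataFormatError(f"{path}: duplicate sample ids")
    for r in records:
        for pid in (r.father_id, r.mother_id):
            if pid is not None and pid not in ids:
                raise DataFormatError(
                    f"{path}: parent {pid!r} of {r.sample_id!r} is not in the pedigree"
                )
    return records


def write_pedigree(records: Iterable[PedigreeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample_id\tfather_id\tmother_id\tstatus\tsource\n")
        for r in records:
            fh.write("\t".join([
                r.sample_id, r.father_id or ".", r.mother_id or ".",
                r.status, ",".join(r.sources),
            ]) + "\n")


# ---------------------------------------------------------------------------
# Unified dataset TSV
# ---------------------------------------------------------------------------

def write_unified_dataset(dataset, path: str | Path) -> None:
    """Write the site-by-sample genotype matrix as a TSV.

    Header: ``#chrom pos rsid ref alt <sample1> <sample2> ...`` with genotype
    tokens AA/AB/BB/NC.  The format is bit-exact and deterministic, so
    re-exporting a read-back dataset reproduces identical bytes.  Read depths
    are not part of the export.
    """
    sites = dataset.sites
    tokens = CODE_TO_STATE[dataset.states]
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\trsid\tref\talt\t" + "\t".join(dataset.sample_ids) + "\n")
        for i in range(len(sites)):
            row = sites.iloc[i]
            rsid = row.rsid if isinstance(row.rsid, str) and row.rsid else "."
            fh.write(f"{row.chrom}\t{row.pos}\t{rsid}\t{row.ref}\t{row.alt}\t"
                     + "\t".join(tokens[i]) + "\n")


def read_unified_dataset(path: str | Path):
    """Read a unified-dataset TSV back into a :class:`UnifiedDataset`.

    Only the exported fields are recoverable: read depths are zeroed and
    pedigree roles default to unknown (re-attach them with
    ``UnifiedDataset.with_pedigree``).
    """
    from .dataset import UnifiedDataset  # local import to avoid a cycle

    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#chrom"):
            raise DataFormatError(f"{path}: missing unified-dataset header")
        cols = header.lstrip("#").split("\t")
        sample_ids = cols[5:]
        if not sample_ids:
            raise DataFormatError(f"{path}: no sample columns")
        rows = []
        states = []
        for line_no, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5 + len(sample_ids):
                raise DataFormatError(f"{path}: wrong column count on line {line_no}")
            chrom, pos, rsid, ref, alt = parts[:5]
            rows.append((chrom, int(pos), None if rsid == "." else rsid, ref, alt))
            try:
                states.append([STATE_TO_CODE[t] for t in parts[5:]])
            except KeyError as exc:
                raise DataFormatError(f"{path}: bad genotype token on line {line_no}") from exc

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "rsid", "ref", "alt"])
    st = np.array(states, dtype=np.int8) if states else np.zeros((0, len(sample_ids)), np.int8)
    return UnifiedDataset(
        sites=sites,
        samples=[PedigreeRecord(sample_id=s) for s in sample_ids],
        states=st,
        ref_depth=np.zeros_like(st, dtype=np.int32),
        alt_depth=np.zeros_like(st, dtype=np.int32),
        provenance={"path": str(path)},
    )


# ---------------------------------------------------------------------------
# Gene models + genome sequence
# ---------------------------------------------------------------------------

@dataclass
class GeneModelRecord:
    """One transcript's structure, in 0-based half-open coordinates."""

    gene_name: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    valid: bool = True
    issues: list[str] = field(default_factory=list)

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start

    def validate(self) -> None:
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                self.issues.append(f"empty exon ({s},{e})")
            if s < prev_end:
                self.issues.append("exons overlap or are unsorted")
            prev_end = e
        if self.is_coding:
            if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
                self.issues.append("CDS outside exon span")
            else:
                # CDS boundaries must fall inside exons
                for bound in (self.cds_start, self.cds_end - 1):
                    if not any(s <= bound < e for s, e in self.exons):
                        self.issues.append("CDS boundary not inside an exon")
                        break
        if self.issues:
            self.valid = False

    def cds_exon_chunks(self) -> list[tuple[int, int]]:
        """Exon-CDS intersections, in genomic order."""
        out = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs < ce:
                out.append((cs, ce))
        return out


def read_gene_models(genepred_path: str | Path, fasta_path: str | Path | None = None,
                     ) -> tuple[list[GeneModelRecord], Callable[[str, int, int], str] | None]:
    """Read refFlat (11-column) or genePred (10-column) transcript models.

    Returns the records plus a sequence accessor ``fetch(chrom, start0,
    end0) -> str`` backed by pyfaidx, or ``None`` when no FASTA is given.
    Transcripts with malformed exon lists raise; transcripts on chromosomes
    absent from the FASTA, or with a CDS outside their exons, are flagged
    (``valid=False``) rather than dropped.
    """
    fasta = None
    fasta_chroms: set[str] = set()
    if fasta_path is not None:
        from pyfaidx import Fasta

        fasta = Fasta(str(fasta_path), rebuild=True)
        fasta_by_norm = {normalize_chrom(name): name for name in fasta.keys()}
        fasta_chroms = set(fasta_by_norm)

    records: list[GeneModelRecord] = []
    with open(genepred_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 11:        # refFlat: geneName then genePred columns
                gene_name, rest = parts[0], parts[1:11]
            elif len(parts) == 10:      # bare genePred
                gene_name, rest = parts[0], parts[:10]
            else:
                raise DataFormatError(
                    f"{genepred_path}: expected 10 or 11 columns on line {line_no}"
                )
            (tx_id, chrom, strand, tx_start, tx_end,
             cds_start, cds_end, exon_count, exon_starts, exon_ends) = rest
            try:
                starts = [int(x) for x in exon_starts.rstrip(",").split(",")]
                ends = [int(x) for x in exon_ends.rstrip(",").split(",")]
                n = int(exon_count)
                if len(starts) != n or len(ends) != n:
                    raise ValueError("exon count does not match exon lists")
                rec = GeneModelRecord(
                    gene_name=gene_name, transcript_id=tx_id,
                    chrom=normalize_chrom(chrom), strand=strand,
                    exons=list(zip(starts, ends)),
                    cds_start=int(cds_start), cds_end=int(cds_end),
                )
            except ValueError as exc:
                raise DataFormatError(
                    f"{genepred_path}: malformed exon list for transcript {tx_id!r} "
                    f"(line {line_no}): {exc}"
                ) from exc
            rec.validate()
            if fasta is not None and rec.chrom not in fasta_chroms:
                rec.valid = False
                rec.issues.append("chromosome absent from FASTA")
            records.append(rec)

    accessor = None
    if fasta is not None:
        def accessor(chrom: str, start0: int, end0: int) -> str:
            name = fasta_by_norm[normalize_chrom(chrom)]
            return str(fasta[name][start0:end0]).upper()

    return records, accessor


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_regions_bed(regions, path: str | Path) -> None:
    """Write autozygous regions as 6-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t"
                     f"{r.sample_id}|{r.source}\t{r.n_variants}\t.\n")
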