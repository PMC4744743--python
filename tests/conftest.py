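"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import textwrap
from pathlib import Path

import numpy as np
import pytest

from autozygmap.formats import GeneModelRecord, PedigreeRecord


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; never share code with the package)
# ---------------------------------------------------------------------------

def oracle_genotype(ref_depth: int, alt_depth: int) -> str:
    """Direct transliteration of the four printed genotype rules."""
    total = ref_depth + alt_depth
    if total == 0:
        return "NC"
    if ref_depth / total > 0.8:
        return "AA"
    if alt_depth / total > 0.8:
        return "BB"
    if 0.4 <= alt_depth / total <= 0.6:
        return "AB"
    return "NC"


HOM, HET, NC = 0, 1, 2


def oracle_runs(states, min_run: int = 25, iterations: int = 4):
    """Naive quadratic rescanner for homozygous-run construction.

    HET breaks a run, NOCALL is transparent; a HET whose neighbouring runs
    (no other HET in between) each hold strictly more than ``min_run``
    homozygous markers is set to NOCALL — all such HETs at once — and the
    scan repeats, ``iterations`` times.
    Returns (first_hom_index, last_hom_index, n_hom) tuples.
    """
    st = list(states)

    def scan(st):
        out, cur = [], None
        for i, s in enumerate(st):
            if s == HOM:
                if cur is None:
                    cur = [i, i, 1]
                else:
                    cur[1] = i
                    cur[2] += 1
            elif s == HET and cur is not None:
                out.append(tuple(cur))
                cur = None
        if cur is not None:
            out.append(tuple(cur))
        return out

    for _ in range(iterations):
        to_clear = []
        for h, s in enumerate(st):
            if s != HET:
                continue
            left = 0
            i = h - 1
            while i >= 0 and st[i] != HET:
                if st[i] == HOM:
                    left += 1
                i -= 1
            right = 0
            i = h + 1
            while i < len(st) and st[i] != HET:
                if st[i] == HOM:
                    right += 1
                i += 1
            if left > min_run and right > min_run:
                to_clear.append(h)
        if not to_clear:
            break
        for h in to_clear:
            st[h] = NC
    return scan(st)


def oracle_protein_consequence(model: GeneModelRecord, fetch, pos: int, alt: str):
    """Full-CDS rebuild oracle for SNV consequences: substitute the base in
    the genome, rebuild and translate both complete proteins, and compare.

    No codon-index arithmetic: the only shared assumption with the
    implementation is the gene model itself.
    """
    from Bio.Seq import Seq

    ref_chunks, alt_chunks = [], []
    for s, e in model.cds_exon_chunks():
        seq = fetch(model.chrom, s, e)
        ref_chunks.append(seq)
        if s <= pos - 1 < e:
            k = pos - 1 - s
            seq = seq[:k] + alt + seq[k + 1:]
        alt_chunks.append(seq)
    ref_cds, alt_cds = "".join(ref_chunks), "".join(alt_chunks)
    if model.strand == "-":
        ref_cds = str(Seq(ref_cds).reverse_complement())
        alt_cds = str(Seq(alt_cds).reverse_complement())
    prot_ref = str(Seq(ref_cds).translate())
    prot_alt = str(Seq(alt_cds).translate())
    if prot_ref == prot_alt:
        return "synonymous"
    diffs = [k for k, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b]
    k = diffs[0]
    if prot_alt[k] == "*":
        return "nonsense"
    if prot_ref[k] == "*":
        return "stop_loss"
    return "missense"


# ---------------------------------------------------------------------------
# File-writing helpers
# ---------------------------------------------------------------------------

VCF_HEADER = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=1,length=10000000>
    ##contig=<ID=2,length=10000000>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
    """)


@pytest.fixture
def write_vcf(tmp_path):
    def _write(name: str, body_lines: list[str], sample: str = "S1") -> Path:
        path = tmp_path / name
        path.write_text(VCF_HEADER.format(sample=sample)
                        + "".join(line + "\n" for line in body_lines))
        return path

    return _write


@pytest.fixture
def toy_gene(tmp_path):
    """A 2-exon plus-strand gene over a hand-written 200 bp FASTA.

    CDS is ATG GAT TGG TAC ... TAA split across the exons; returns
    (gene_models_path, fasta_path, expected CDS string).
    """
    # exon1: [10, 31) holds ATG GAT TGG TAC GGA TCC AAA  (21 bases)
    # intron: [31, 60)
    # exon2: [60, 72) holds CTG TTG GCA TAA (12 bases)
    cds = "ATGGATTGGTACGGATCCAAA" + "CTGTTGGCATAA"
    seq = ["A"] * 200
    seq[10:31] = list(cds[:21])
    seq[60:72] = list(cds[21:])
    fasta = tmp_path / "toy.fa"
    fasta.write_text(">1\n" + "".join(seq) + "\n")
    refflat = tmp_path / "toy.refFlat"
    refflat.write_text("GENEA\tTXA\t1\t+\t10\t72\t10\t72\t2\t10,60,\t31,72,\n")
    return refflat, fasta, cds


@pytest.fixture
def quartet_pedigree():
    return [
        PedigreeRecord("P1", status="unaffected"),
        PedigreeRecord("P2", status="unaffected"),
        PedigreeRecord("C1", "P1", "P2", status="affected"),
        PedigreeRecord("C2", "P1", "P2", status="affected"),
    ]
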