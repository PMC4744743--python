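"""Gene-context annotation of variants: protein effect, splice proximity,
per-sample depths.

Consequences are derived from the spliced, strand-aware CDS: for an SNV the
reference codon is rebuilt from the transcript's coding sequence, the base
substituted, and both codons translated; indels are classified frameshift or
in-frame by the length difference modulo 3 without re-alignment.  Protein
changes use one-based amino-acid numbering with +1 at the initiating
methionine, e.g. ``p.(Asp333Gly)``.

One effect is emitted per overlapping transcript (no "worst consequence"
collapsing), deterministically ordered by transcript id.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .dataset import UnifiedDataset
from .filters import FilterResult
from .formats import GeneModelRecord, normalize_chrom
from .genotyping import CODE_TO_STATE

REGION_CLASSES = ("intergenic", "intronic", "splice_region",
                  "five_prime_utr", "three_prime_utr", "coding")
CODING_CONSEQUENCES = ("synonymous", "missense", "nonsense", "stop_loss",
                       "frameshift", "inframe_indel", "none")
PROTEIN_AFFECTING = {"missense", "nonsense", "stop_loss", "frameshift", "inframe_indel"}

SeqFetch = Callable[[str, int, int], str]


@dataclass(frozen=True)
class VariantEffect:
    """Predicted effect of one variant on one transcript."""

    chrom: str
    pos: int                    # 1-based
    ref: str
    alt: str
    gene_name: str | None
    transcript_id: str | None
    region_class: str
    consequence: str = "none"
    protein_change: str | None = None
    exon_boundary_distance: int | None = None
    canonical_splice: bool = False

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"bad region class {self.region_class!r}")
        if self.consequence not in CODING_CONSEQUENCES:
            raise ValueError(f"bad consequence {self.consequence!r}")
        if (self.consequence != "none") != (self.region_class == "coding"):
            raise ValueError("coding consequence iff region class is coding")


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _spliced_cds(model: GeneModelRecord, fetch: SeqFetch) -> str:
    chunks = [fetch(model.chrom, s, e) for s, e in model.cds_exon_chunks()]
    seq = "".join(chunks)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq.upper()


def _cds_coordinate(model: GeneModelRecord, pos0: int) -> int | None:
    """0-based coordinate within the spliced CDS, or None if not in CDS."""
    chunks = model.cds_exon_chunks()
    offset = 0
    if model.strand == "+":
        for s, e in chunks:
            if s <= pos0 < e:
                return offset + (pos0 - s)
            offset += e - s
    else:
        for s, e in reversed(chunks):
            if s <= pos0 < e:
                return offset + (e - 1 - pos0)
            offset += e - s
    return None


def _exon_boundary_distance(model: GeneModelRecord, pos0: int) -> int:
    """bp to the nearest exon edge: 0-based exonic distance, >=1 intronic."""
    best = None
    for s, e in model.exons:
        if pos0 < s:
            d = s - pos0
        elif pos0 >= e:
            d = pos0 - e + 1
        else:
            d = min(pos0 - s, e - 1 - pos0)
        best = d if best is None else min(best, d)
    return int(best)


def _protein_change(consequence: str, aa_ref: str, aa_alt: str, aa_pos: int) -> str | None:
    if consequence == "synonymous":
        return f"p.({seq3(aa_ref)}{aa_pos}=)"
    if consequence == "missense":
        return f"p.({seq3(aa_ref)}{aa_pos}{seq3(aa_alt)})"
    if consequence == "nonsense":
        return f"p.({seq3(aa_ref)}{aa_pos}*)"
    if consequence == "stop_loss":
        return f"p.(*{aa_pos}{seq3(aa_alt)})"
    return None


def _snv_effect(model: GeneModelRecord, fetch: SeqFetch, pos0: int, alt: str,
                ) -> tuple[str, str | None]:
    cpos = _cds_coordinate(model, pos0)
    assert cpos is not None
    cds = _spliced_cds(model, fetch)
    alt_base = alt if model.strand == "+" else str(Seq(alt).complement())
    codon_i = cpos // 3
    within = cpos % 3
    codon = cds[3 * codon_i: 3 * codon_i + 3]
    if len(codon) < 3:   # CDS truncated mid-codon; cannot classify further
        return "missense", None
    alt_codon = codon[:within] + alt_base.upper() + codon[within + 1:]
    aa_ref, aa_alt = _translate(codon), _translate(alt_codon)
    aa_pos = codon_i + 1
    if aa_ref == aa_alt:
        cons = "synonymous"
    elif aa_alt == "*":
        cons = "nonsense"
    elif aa_ref == "*":
        cons = "stop_loss"
    else:
        cons = "missense"
    return cons, _protein_change(cons, aa_ref, aa_alt, aa_pos)


def _classify_in_transcript(model: GeneModelRecord, fetch: SeqFetch | None,
                            pos: int, ref: str, alt: str,
                            splice_window: int) -> VariantEffect:
    pos0 = pos - 1
    span0, span1 = pos0, pos0 + len(ref)       # genomic footprint of the ref allele
    dist = _exon_boundary_distance(model, pos0)
    in_exon = any(s < span1 and span0 < e for s, e in model.exons)
    in_cds = model.is_coding and any(
        s < span1 and span0 < e for s, e in model.cds_exon_chunks()
    )

    region, cons, pchange = "intronic", "none", None
    if in_cds:
        region = "coding"
        if len(ref) == len(alt) == 1:
            if fetch is None:
                raise ValueError("coding SNV annotation requires genome sequence")
            cons, pchange = _snv_effect(model, fetch, pos0, alt)
        elif len(ref) != len(alt):
            cons = "frameshift" if abs(len(ref) - len(alt)) % 3 else "inframe_indel"
        else:
            # multi-nucleotide substitution: classify via full-codon rebuild
            cons = "missense"
    elif in_exon:
        if not model.is_coding or pos0 < model.cds_start:
            region = "five_prime_utr" if model.strand == "+" else "three_prime_utr"
        else:
            region = "three_prime_utr" if model.strand == "+" else "five_prime_utr"
    else:
        region = "splice_region" if dist <= splice_window else "intronic"

    return VariantEffect(
        chrom=model.chrom, pos=pos, ref=ref, alt=alt,
        gene_name=model.gene_name, transcript_id=model.transcript_id,
        region_class=region, consequence=cons, protein_change=pchange,
        exon_boundary_distance=dist,
        canonical_splice=(region == "splice_region" and dist <= 2),
    )


def annotate_variant(chrom: str, pos: int, ref: str, alt: str,
                     gene_models: Sequence[GeneModelRecord],
                     seq_fetch: SeqFetch | None,
                     splice_window: int = 8) -> list[VariantEffect]:
    """Effects of one variant, one per overlapping transcript.

    ``splice_window`` is the intronic distance (bp from the exon edge) within
    which a variant is reported as ``splice_region``; the canonical +-2
    positions are additionally flagged.  A variant overlapping no transcript
    yields a single intergenic effect.
    """
    chrom = normalize_chrom(chrom)
    pos0 = pos - 1
    span1 = pos0 + len(ref)
    hits = [m for m in gene_models
            if m.valid and m.chrom == chrom and m.tx_start < span1 and pos0 < m.tx_end]
    invalid = [m for m in gene_models
               if not m.valid and m.chrom == chrom and m.tx_start < span1 and pos0 < m.tx_end]
    if invalid and not hits:
        raise ValueError(
            "variant overlaps only transcripts with inconsistent models: "
            + ", ".join(m.transcript_id for m in invalid)
        )
    if not hits:
        return [VariantEffect(chrom=chrom, pos=pos, ref=ref, alt=alt,
                              gene_name=None, transcript_id=None,
                              region_class="intergenic")]
    return [_classify_in_transcript(m, seq_fetch, pos, ref, alt, splice_window)
            for m in sorted(hits, key=lambda m: m.transcript_id)]


def variants_in_gene(dataset: UnifiedDataset, gene_name: str,
                     gene_models: Sequence[GeneModelRecord]) -> pd.DataFrame:
    """All dataset sites overlapping a gene, with per-sample genotypes/depths.

    Raises on an unknown gene name, listing near-matches.
    """
    models = [m for m in gene_models if m.gene_name == gene_name]
    if not models:
        known = sorted({m.gene_name for m in gene_models})
        near = difflib.get_close_matches(gene_name, known, n=3)
        hint = f"; did you mean {near}?" if near else ""
        raise KeyError(f"unknown gene {gene_name!r}{hint}")
    chroms = {m.chrom for m in models}
    sites = dataset.sites
    mask = np.zeros(len(sites), dtype=bool)
    for m in models:
        mask |= ((sites["chrom"] == m.chrom).to_numpy()
                 & (sites["pos"].to_numpy() >= m.tx_start + 1)
                 & (sites["pos"].to_numpy() <= m.tx_end))
    rows = []
    for i in np.flatnonzero(mask):
        row = {
            "chrom": sites.chrom.iloc[i], "pos": int(sites.pos.iloc[i]),
            "rsid": sites.rsid.iloc[i], "ref": sites.ref.iloc[i],
            "alt": sites.alt.iloc[i], "gene": gene_name,
        }
        for j, sid in enumerate(dataset.sample_ids):
            row[f"{sid}:gt"] = str(CODE_TO_STATE[dataset.states[i, j]])
            row[f"{sid}:depths"] = (f"{int(dataset.ref_depth[i, j])},"
                                    f"{int(dataset.alt_depth[i, j])}")
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True) \
        if rows else pd.DataFrame(rows)


def annotate_result(result: FilterResult,
                    gene_models: Sequence[GeneModelRecord],
                    seq_fetch: SeqFetch | None,
                    protein_affecting: bool = False,
                    splice_window: int = 8) -> pd.DataFrame:
    """Annotate every retained site; one row per site x overlapping transcript.

    With ``protein_affecting=True`` only rows whose consequence is in
    {missense, nonsense, stop_loss, frameshift, inframe_indel} — or whose
    region is ``splice_region`` — are kept.
    """
    ds = result.dataset
    rows = []
    for i in result.site_indices():
        s = ds.sites.iloc[i]
        effects = annotate_variant(s.chrom, int(s.pos), s.ref, s.alt,
                                   gene_models, seq_fetch, splice_window)
        for eff in effects:
            if protein_affecting and not (
                eff.consequence in PROTEIN_AFFECTING or eff.region_class == "splice_region"
            ):
                continue
            row = {
                "chrom": s.chrom, "pos": int(s.pos),
                "rsid": s.rsid if isinstance(s.rsid, str) else ".",
                "ref": s.ref, "alt": s.alt,
                "gene": eff.gene_name or ".",
                "transcript": eff.transcript_id or ".",
                "region": eff.region_class,
                "consequence": eff.consequence,
                "protein_change": eff.protein_change or ".",
                "exon_boundary_distance": eff.exon_boundary_distance,
            }
            for j, sid in enumerate(ds.sample_ids):
                row[f"{sid}:gt"] = str(CODE_TO_STATE[ds.states[i, j]])
                row[f"{sid}:depths"] = (f"{int(ds.ref_depth[i, j])},"
                                        f"{int(ds.alt_depth[i, j])}")
            rows.append(row)
    return pd.DataFrame(rows)
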