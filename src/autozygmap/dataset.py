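"""Merging per-sample VCF records and depth tables into a unified dataset.

Single-sample exome VCFs only list non-reference genotypes, so a site seen in
one sibling's VCF is simply absent from another's — which could mean either
homozygous reference or no usable coverage.  The unified dataset resolves
this with the optional per-sample read-depth tables: a missing genotype is
filled in as homozygous reference (AA) when the sample's total depth at the
position reaches the user-chosen retention threshold (``display_min_depth``),
and left as a no-call otherwise.  Fill-in can therefore never create a
heterozygous or homozygous-variant genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PedigreeError
from .formats import DepthTable, PedigreeRecord, VcfSiteRecord, chrom_sort_key
from .genotyping import (
    CODE_AA, CODE_NOCALL, CODE_TO_STATE, DEFAULT_THRESHOLDS, GenotypeCall,
    Thresholds, is_rs_id, recall_genotypes,
)


@dataclass
class UnifiedDataset:
    """Ordered site-by-sample genotype matrix with site and sample metadata.

    ``sites`` is a DataFrame with columns chrom, pos, rsid, ref, alt, sorted
    by (chrom, pos, ref, alt) and unique; ``states`` / ``ref_depth`` /
    ``alt_depth`` are (n_sites, n_samples) matrices; samples are ordered
    alphabetically by id.
    """

    sites: pd.DataFrame
    samples: list[PedigreeRecord]
    states: np.ndarray
    ref_depth: np.ndarray
    alt_depth: np.ndarray
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @cached_property
    def sample_index(self) -> dict[str, int]:
        return {s.sample_id: j for j, s in enumerate(self.samples)}

    @cached_property
    def has_rs(self) -> np.ndarray:
        """Per-site boolean: does the ID column carry an rs accession?"""
        return np.array([is_rs_id(r) for r in self.sites["rsid"]], dtype=bool)

    def sample(self, sample_id: str) -> PedigreeRecord:
        return self.samples[self.sample_index[sample_id]]

    def column(self, sample_id: str) -> np.ndarray:
        return self.states[:, self.sample_index[sample_id]]

    def call(self, site_idx: int, sample_id: str) -> GenotypeCall:
        j = self.sample_index[sample_id]
        return GenotypeCall(
            state=str(CODE_TO_STATE[self.states[site_idx, j]]),
            ref_depth=int(self.ref_depth[site_idx, j]),
            alt_depth=int(self.alt_depth[site_idx, j]),
            has_rs=bool(self.has_rs[site_idx]),
        )

    def with_pedigree(self, pedigree: Sequence[PedigreeRecord]) -> "UnifiedDataset":
        """Re-attach pedigree roles (e.g. after reading a dataset TSV)."""
        by_id = {p.sample_id: p for p in pedigree}
        missing = [s.sample_id for s in self.samples if s.sample_id not in by_id]
        if missing:
            raise PedigreeError(f"pedigree lacks dataset samples: {missing}")
        return replace(self, samples=[by_id[s.sample_id] for s in self.samples])


def build_unified_dataset(
    vcf_records: Mapping[str, Sequence[VcfSiteRecord]],
    depth_tables: Mapping[str, DepthTable] | None,
    pedigree: Sequence[PedigreeRecord],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> UnifiedDataset:
    """Merge per-sample VCF records (plus optional depth tables) into a matrix.

    For sample *s* at site *v*: if *s*'s VCF carries *v*, the genotype is
    re-determined from its allele depths; otherwise, if *s* has depth data
    covering the position at >= ``thresholds.display_min_depth``, the cell is
    filled in as AA with that depth; otherwise it is a no-call.  Building is
    invariant to input ordering: sites are sorted by (chrom, pos, ref, alt)
    and samples alphabetically.
    """
    depth_tables = depth_tables or {}
    ped_ids = [p.sample_id for p in pedigree]
    if len(set(ped_ids)) != len(ped_ids):
        raise PedigreeError("duplicate sample ids in pedigree")
    ped_by_id = {p.sample_id: p for p in pedigree}
    for p in pedigree:
        for pid in (p.father_id, p.mother_id):
            if pid is not None and pid not in ped_by_id:
                raise PedigreeError(f"pedigree references unknown sample {pid!r}")

    sample_ids = sorted(vcf_records)
    if not sample_ids:
        raise ValueError("at least one sample with VCF data is required")
    if len(set(sample_ids)) != len(sample_ids):
        raise PedigreeError("duplicate sample ids in VCF inputs")
    unknown = [s for s in sample_ids if s not in ped_by_id]
    if unknown:
        raise PedigreeError(f"VCF samples missing from pedigree: {unknown}")

    # Union of sites across all samples; an rs id from any sample wins.
    site_rsid: dict[tuple[str, int, str, str], str | None] = {}
    for sid in sample_ids:
        for rec in vcf_records[sid]:
            key = (rec.chrom, rec.pos, rec.ref, rec.alt)
            if key not in site_rsid or (site_rsid[key] is None and rec.id is not None):
                site_rsid[key] = rec.id
    keys = sorted(site_rsid, key=lambda k: (chrom_sort_key(k[0]), k[1], k[2], k[3]))
    key_index = {k: i for i, k in enumerate(keys)}
    n_sites, n_samples = len(keys), len(sample_ids)

    states = np.full((n_sites, n_samples), CODE_NOCALL, dtype=np.int8)
    ref_depth = np.zeros((n_sites, n_samples), dtype=np.int32)
    alt_depth = np.zeros((n_sites, n_samples), dtype=np.int32)

    for j, sid in enumerate(sample_ids):
        recs = vcf_records[sid]
        idx = np.fromiter((key_index[(r.chrom, r.pos, r.ref, r.alt)] for r in recs),
                          dtype=np.int64, count=len(recs))
        rd = np.fromiter((r.ref_depth for r in recs), dtype=np.int64, count=len(recs))
        ad = np.fromiter((r.alt_depth for r in recs), dtype=np.int64, count=len(recs))
        missing = np.fromiter((r.depth_missing for r in recs), dtype=bool, count=len(recs))
        called = recall_genotypes(rd, ad, thresholds)
        called[missing] = CODE_NOCALL
        states[idx, j] = called
        ref_depth[idx, j] = rd
        alt_depth[idx, j] = ad

        # Homozygous-reference fill-in at sites absent from this sample's VCF.
        table = depth_tables.get(sid)
        if table is not None:
            in_vcf = np.zeros(n_sites, dtype=bool)
            in_vcf[idx] = True
            for i, (chrom, pos, _ref, _alt) in enumerate(keys):
                if in_vcf[i]:
                    continue
                depth = table.depths.get((chrom, pos))
                if depth is not None and depth >= thresholds.display_min_depth:
                    states[i, j] = CODE_AA
                    ref_depth[i, j] = depth

    sites = pd.DataFrame(keys, columns=["chrom", "pos", "ref", "alt"]).assign(
        rsid=[site_rsid[k] for k in keys]
    )[["chrom", "pos", "rsid", "ref", "alt"]]

    return UnifiedDataset(
        sites=sites,
        samples=[ped_by_id[s] for s in sample_ids],
        states=states,
        ref_depth=ref_depth,
        alt_depth=alt_depth,
        provenance={"samples": ",".join(sample_ids)},
    )


def missingness_report(dataset: UnifiedDataset) -> pd.DataFrame:
    """Per-sample genotype-state counts (AA/AB/BB/NC); rows sum to n_sites."""
    counts = {
        sid: np.bincount(dataset.states[:, j], minlength=4)
        for j, sid in enumerate(dataset.sample_ids)
    }
    return pd.DataFrame.from_dict(counts, orient="index", columns=list(CODE_TO_STATE))
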