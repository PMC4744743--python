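"""Candidate-variant screens over the unified dataset.

Four screens, chainable into a cascade with per-stage counts:

* recessive: homozygous-variant in every affected sample and in no other
  sample with a called genotype,
* novelty: no rs identifier on the site,
* locus: position inside a shared autozygous interval,
* non-Mendelian: de novo heterozygotes (affected AB, parents and unaffected
  siblings confirmed AA) and Mendelian-impossible homozygotes (an offspring
  homozygous for an allele a parent demonstrably does not carry — the
  footprint of a deletion uncovering one allele).

All screens consume re-determined genotypes, never the VCF's declared ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import intervals as iv
from .dataset import UnifiedDataset
from .errors import PedigreeError
from .genotyping import CODE_AA, CODE_AB, CODE_BB, CODE_NOCALL

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StageCount:
    name: str
    n_before: int
    n_after: int


@dataclass
class FilterResult:
    """Sites retained after a (possibly chained) sequence of screens."""

    dataset: UnifiedDataset
    retained: np.ndarray                       # bool per site
    stages: list[StageCount] = field(default_factory=list)
    removed_by: np.ndarray | None = None       # object array: stage name or None

    @classmethod
    def all_sites(cls, dataset: UnifiedDataset) -> "FilterResult":
        return cls(dataset=dataset,
                   retained=np.ones(dataset.n_sites, dtype=bool),
                   removed_by=np.full(dataset.n_sites, None, dtype=object))

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def site_indices(self) -> np.ndarray:
        return np.flatnonzero(self.retained)

    def site_keys(self) -> list[tuple[str, int, str, str]]:
        s = self.dataset.sites
        return [(s.chrom.iloc[i], int(s.pos.iloc[i]), s.ref.iloc[i], s.alt.iloc[i])
                for i in self.site_indices()]

    def reason_trail(self) -> list[str]:
        return [st.name for st in self.stages]

    def _apply(self, name: str, keep_mask: np.ndarray) -> "FilterResult":
        before = self.n_retained
        retained = self.retained & keep_mask
        removed_by = self.removed_by.copy()
        newly_removed = self.retained & ~keep_mask
        removed_by[newly_removed] = name
        return FilterResult(
            dataset=self.dataset, retained=retained,
            stages=self.stages + [StageCount(name, before, int(retained.sum()))],
            removed_by=removed_by,
        )


def _as_result(dataset_or_result: UnifiedDataset | FilterResult) -> FilterResult:
    if isinstance(dataset_or_result, FilterResult):
        return dataset_or_result
    return FilterResult.all_sites(dataset_or_result)


def _status_columns(ds: UnifiedDataset, status: str) -> np.ndarray:
    return np.array([j for j, s in enumerate(ds.samples) if s.status == status], dtype=int)


def filter_affected_homozygous(dataset_or_result: UnifiedDataset | FilterResult,
                               ) -> FilterResult:
    """Retain sites homozygous-variant in affecteds only.

    Every affected sample must be BB (an affected no-call excludes the site)
    and no non-affected sample with a called genotype may be BB (a
    non-affected no-call neither rescues nor excludes).
    """
    res = _as_result(dataset_or_result)
    ds = res.dataset
    aff = _status_columns(ds, "affected")
    if len(aff) == 0:
        raise PedigreeError("no affected samples in the dataset")
    non_aff = np.array([j for j in range(len(ds.samples)) if j not in set(aff)], dtype=int)
    keep = (ds.states[:, aff] == CODE_BB).all(axis=1)
    if len(non_aff):
        keep &= ~(ds.states[:, non_aff] == CODE_BB).any(axis=1)
    return res._apply("affected_homozygous", keep)


def filter_no_rs(dataset_or_result: UnifiedDataset | FilterResult) -> FilterResult:
    """Retain sites whose ID column carries no rs identifier.

    De novo pathogenic variants frequently *do* carry rs ids, so when this
    screen follows a de novo screen and removes more than 90% of it, a
    warning is logged.
    """
    res = _as_result(dataset_or_result)
    keep = ~res.dataset.has_rs
    out = res._apply("no_rs", keep)
    prior = [st.name for st in res.stages]
    if "de_novo_het" in prior and res.n_retained > 0:
        frac_removed = 1.0 - out.n_retained / res.n_retained
        if frac_removed > 0.9:
            logger.warning(
                "no_rs removed %.0f%% of de novo candidates; pathogenic de novo "
                "variants are often rs-annotated, so rs-based filtering may be "
                "inappropriate here", 100 * frac_removed,
            )
    return out


def filter_in_regions(dataset_or_result: UnifiedDataset | FilterResult,
                      regions: Sequence[tuple[str, int, int]]) -> FilterResult:
    """Retain sites inside any interval (1-based inclusive containment)."""
    res = _as_result(dataset_or_result)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in regions:
        by_chrom.setdefault(chrom, []).append((s, e))
    sites = res.dataset.sites
    keep = np.array(
        [iv.contains(by_chrom.get(c, []), p)
         for c, p in zip(sites["chrom"], sites["pos"])],
        dtype=bool,
    ) if len(sites) else np.zeros(0, dtype=bool)
    return res._apply("in_regions", keep)


def _trio_columns(ds: UnifiedDataset) -> tuple[list[tuple[int, int, int]], dict[tuple[str, str], list[int]]]:
    """(affected, father, mother) column triples plus unaffected-sib columns."""
    idx = ds.sample_index
    trios = []
    sibs: dict[tuple[str, str], list[int]] = {}
    for j, s in enumerate(ds.samples):
        if s.father_id and s.mother_id and s.father_id in idx and s.mother_id in idx:
            if s.status == "affected":
                trios.append((j, idx[s.father_id], idx[s.mother_id]))
            elif s.status == "unaffected":
                sibs.setdefault((s.father_id, s.mother_id), []).append(j)
    return trios, sibs


def find_de_novo_het(dataset_or_result: UnifiedDataset | FilterResult) -> FilterResult:
    """Screen for de novo heterozygous candidates.

    A site is retained iff every affected offspring (with both parents in the
    dataset) is AB while both parents and all unaffected full siblings are
    confirmed AA.  A no-call in a parent or sibling excludes the site: a de
    novo claim needs positively confirmed reference genotypes, which in
    practice requires the read-depth fill-in.
    """
    res = _as_result(dataset_or_result)
    ds = res.dataset
    trios, sibs = _trio_columns(ds)
    if not trios:
        raise PedigreeError(
            "de novo screening needs at least one affected offspring with both "
            "parents in the dataset"
        )
    keep = np.ones(ds.n_sites, dtype=bool)
    for child, father, mother in trios:
        keep &= ds.states[:, child] == CODE_AB
        keep &= ds.states[:, father] == CODE_AA
        keep &= ds.states[:, mother] == CODE_AA
        child_rec = ds.samples[child]
        for sib in sibs.get((child_rec.father_id, child_rec.mother_id), []):
            keep &= ds.states[:, sib] == CODE_AA
    return res._apply("de_novo_het", keep)


def find_unexpected_hom(dataset_or_result: UnifiedDataset | FilterResult) -> FilterResult:
    """Screen for Mendelian-impossible homozygotes (possible deletions).

    A site is retained iff some affected offspring is homozygous while at
    least one of its called parents carries zero copies of that allele
    (offspring BB with an AA parent, or offspring AA with a BB parent).
    """
    res = _as_result(dataset_or_result)
    ds = res.dataset
    trios, _ = _trio_columns(ds)
    if not trios:
        raise PedigreeError(
            "unexpected-homozygote screening needs at least one affected "
            "offspring with both parents in the dataset"
        )
    keep = np.zeros(ds.n_sites, dtype=bool)
    for child, father, mother in trios:
        c = ds.states[:, child]
        for parent in (father, mother):
            p = ds.states[:, parent]
            keep |= (c == CODE_BB) & (p == CODE_AA)
            keep |= (c == CODE_AA) & (p == CODE_BB)
    return res._apply("unexpected_hom", keep)


_REGISTRY: dict[str, Callable] = {
    "affected_homozygous": filter_affected_homozygous,
    "affected-hom": filter_affected_homozygous,
    "no_rs": filter_no_rs,
    "no-rs": filter_no_rs,
    "in_regions": filter_in_regions,
    "in-regions": filter_in_regions,
    "de_novo_het": find_de_novo_het,
    "de-novo": find_de_novo_het,
    "unexpected_hom": find_unexpected_hom,
    "unexpected-hom": find_unexpected_hom,
}


def run_cascade(dataset: UnifiedDataset,
                plan: Sequence[str | tuple[str, dict]]) -> FilterResult:
    """Apply a named filter plan in order, recording per-stage counts.

    Plan entries are filter names or ``(name, kwargs)`` pairs, e.g.
    ``[("affected_homozygous", {}), ("in_regions", {"regions": shared})]``.
    An empty plan retains every site.
    """
    result = FilterResult.all_sites(dataset)
    for entry in plan:
        name, kwargs = (entry, {}) if isinstance(entry, str) else entry
        fn = _REGISTRY.get(name)
        if fn is None:
            raise ValueError(f"unknown filter {name!r}; known: {sorted(set(_REGISTRY))}")
        result = fn(result, **kwargs)
    return result
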