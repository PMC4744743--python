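"""Autozygous-region detection from exome or microarray genotypes.

A sample's genotypes along a chromosome are reduced to a marker sequence of
HOM / HET / NOCALL states.  Maximal stretches of homozygous markers form
runs; a heterozygous marker breaks a run while no-calls are transparent
(they neither support nor interrupt).  A single heterozygote interrupting
two runs that each contain more than ``min_run_variants`` homozygous markers
is almost always a genotyping error: it is reassigned to no-call and the
runs recomputed.  This pass is iterated (four times by default), after which
runs spanning more than ``min_region_length`` bp are reported as autozygous
regions.

For exome data only depth-qualified calls enter the sequence (rs-dependent
floors, see :mod:`autozygmap.genotyping`).  Microarray calls are used as-is —
array genotyping is consistent enough that re-calling is unnecessary — but
the per-flank run requirement scales with the array design:
``round(n_snps * 7e-4)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from . import intervals as iv
from .dataset import UnifiedDataset
from .errors import DataFormatError
from .formats import ArrayGenotypeTable, chrom_sort_key
from .genotyping import (
    AA, BB, NOCALL, CODE_AA, CODE_AB, CODE_BB, CODE_NOCALL,
    DEFAULT_THRESHOLDS, Thresholds, min_depth_for,
)

# Marker-sequence state codes.
M_HOM, M_HET, M_NOCALL = 0, 1, 2


@dataclass
class MarkerSeq:
    """Genotype states at strictly increasing positions on one chromosome."""

    chrom: str
    positions: np.ndarray   # int64, 1-based, strictly increasing
    states: np.ndarray      # int8 in {M_HOM, M_HET, M_NOCALL}

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.states = np.asarray(self.states, dtype=np.int8)
        if len(self.positions) != len(self.states):
            raise ValueError("positions and states differ in length")
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError(f"{self.chrom}: positions not strictly increasing")


class Run(NamedTuple):
    """A homozygous run, as indices into the marker sequence."""

    first: int      # index of first supporting HOM marker
    last: int       # index of last supporting HOM marker
    n_hom: int      # number of HOM markers in the run


@dataclass(frozen=True)
class AutozygousRegion:
    """A genomic interval of inferred autozygosity for one sample.

    ``start``/``end`` are the 1-based positions of the first and last
    supporting homozygous marker (inclusive).
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    n_variants: int
    source: str          # "exome" | "array"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _runs_and_isolated(states: np.ndarray, min_run_variants: int,
                       ) -> tuple[list[Run], np.ndarray]:
    """Current runs plus the HETs qualifying for reassignment.

    A HET qualifies when the runs immediately to its left and right (no other
    HET in between; no-calls are transparent) each hold strictly more than
    ``min_run_variants`` homozygous markers.
    """
    hom_idx = np.flatnonzero(states == M_HOM)
    het_idx = np.flatnonzero(states == M_HET)
    n = len(states)

    # Gap k lies between het_idx[k-1] and het_idx[k] (virtual hets at -1, n).
    bounds = np.concatenate(([-1], het_idx, [n]))
    lo = np.searchsorted(hom_idx, bounds[:-1], side="right")
    hi = np.searchsorted(hom_idx, bounds[1:], side="left")
    counts = hi - lo

    runs = [Run(int(hom_idx[l]), int(hom_idx[h - 1]), int(h - l))
            for l, h in zip(lo, hi) if h > l]
    qualifying = het_idx[(counts[:-1] > min_run_variants) & (counts[1:] > min_run_variants)]
    return runs, qualifying


def find_runs(seq: MarkerSeq | np.ndarray | Sequence[int],
              min_run_variants: int = 25, n_iterations: int = 4) -> list[Run]:
    """Homozygous runs after iterative reassignment of isolated heterozygotes.

    Within one iteration every qualifying isolated HET is identified against
    the current run structure, all are reassigned to no-call simultaneously,
    and the runs are recomputed once; this is repeated ``n_iterations`` times
    (stopping early at a fixed point, which changes nothing).  Reassignment
    only ever converts HET to NOCALL.
    """
    states = seq.states if isinstance(seq, MarkerSeq) else np.asarray(seq, dtype=np.int8)
    work = states.copy()
    for _ in range(n_iterations):
        _, qualifying = _runs_and_isolated(work, min_run_variants)
        if len(qualifying) == 0:
            break
        work[qualifying] = M_NOCALL
    runs, _ = _runs_and_isolated(work, min_run_variants)
    return runs


def runs_to_regions(runs: Iterable[Run], seq: MarkerSeq, min_region_length: int,
                    sample_id: str, source: str) -> list[AutozygousRegion]:
    """Convert runs to regions, keeping spans strictly over the length floor."""
    out = []
    for run in runs:
        start = int(seq.positions[run.first])
        end = int(seq.positions[run.last])
        if end - start + 1 > min_region_length:
            out.append(AutozygousRegion(
                sample_id=sample_id, chrom=seq.chrom, start=start, end=end,
                n_variants=run.n_hom, source=source,
            ))
    return out


# ---------------------------------------------------------------------------
# Exome pipeline
# ---------------------------------------------------------------------------

def to_marker_seq_exome(dataset: UnifiedDataset, sample_id: str,
                        thresholds: Thresholds = DEFAULT_THRESHOLDS,
                        include_x: bool = False,
                        depth_floors: bool = True) -> dict[str, MarkerSeq]:
    """Depth-qualified marker sequences, one per chromosome.

    Calls failing their rs-dependent depth floor — and no-calls — are dropped
    outright: they neither support nor interrupt runs.  Both homozygous
    states count as HOM (autozygosity is the absence of heterozygosity; with
    read-depth fill-in most supporting markers are AA).  When one position
    carries several alternate alleles the states collapse to one marker, a
    heterozygous call taking precedence.

    ``depth_floors=False`` admits every called genotype; use it for datasets
    re-read from the genotype-only TSV export, which carries no depths.
    """
    if sample_id not in dataset.sample_index:
        raise KeyError(f"unknown sample {sample_id!r}")
    j = dataset.sample_index[sample_id]
    states = dataset.states[:, j]
    is_het = states == CODE_AB
    is_called = states != CODE_NOCALL
    if depth_floors:
        total = dataset.ref_depth[:, j].astype(np.int64) + dataset.alt_depth[:, j]
        has_rs = dataset.has_rs
        floors = np.array(
            [[min_depth_for(AA, False, thresholds), min_depth_for(AA, True, thresholds)],
             [min_depth_for("AB", False, thresholds), min_depth_for("AB", True, thresholds)]]
        )
        floor = floors[is_het.astype(int), has_rs.astype(int)]
        qualified = is_called & (total >= floor)
    else:
        qualified = is_called

    chroms = dataset.sites["chrom"].to_numpy()
    pos = dataset.sites["pos"].to_numpy(dtype=np.int64)
    out: dict[str, MarkerSeq] = {}
    for chrom in sorted(set(chroms), key=chrom_sort_key):
        if not include_x and chrom.upper() in ("X", "Y"):
            continue
        mask = (chroms == chrom) & qualified
        p = pos[mask]
        s = np.where(is_het[mask], M_HET, M_HOM).astype(np.int8)
        if len(p) == 0:
            continue
        # Collapse split multi-allelic records at one position: het wins.
        uniq, inverse = np.unique(p, return_inverse=True)
        if len(uniq) != len(p):
            collapsed = np.zeros(len(uniq), dtype=np.int8)
            np.maximum.at(collapsed, inverse, s)
            p, s = uniq, collapsed
        out[chrom] = MarkerSeq(chrom=chrom, positions=p, states=s)
    return out


def find_regions_exome(dataset: UnifiedDataset, sample_id: str,
                       thresholds: Thresholds = DEFAULT_THRESHOLDS,
                       include_x: bool = False,
                       depth_floors: bool = True) -> list[AutozygousRegion]:
    """Full exome pipeline: qualify calls, find runs, report regions."""
    regions: list[AutozygousRegion] = []
    for chrom, seq in to_marker_seq_exome(dataset, sample_id, thresholds, include_x,
                                          depth_floors).items():
        runs = find_runs(seq, thresholds.min_run_variants, thresholds.n_iterations)
        regions.extend(runs_to_regions(runs, seq, thresholds.min_region_length,
                                       sample_id, "exome"))
    return regions


# ---------------------------------------------------------------------------
# Microarray pipeline
# ---------------------------------------------------------------------------

def array_min_run_variants(n_snps: int, factor: float = 7e-4) -> int:
    """Per-flank run requirement for an array design: round(n_snps * factor).

    Rounded half-up to an integer (906,600 SNPs -> 634.62 -> 635).
    """
    return int(math.floor(n_snps * factor + 0.5))


def to_marker_seq_array(table: ArrayGenotypeTable, sample_id: str,
                        include_x: bool = False) -> dict[str, MarkerSeq]:
    """Array calls per chromosome, used as-is (no re-genotyping, no floors)."""
    if sample_id not in table.calls:
        raise KeyError(f"unknown array sample {sample_id!r}")
    codes = table.calls[sample_id]
    m_states = np.full(len(codes), M_NOCALL, dtype=np.int8)
    m_states[(codes == CODE_AA) | (codes == CODE_BB)] = M_HOM
    m_states[codes == CODE_AB] = M_HET
    out: dict[str, MarkerSeq] = {}
    for chrom in sorted(set(table.chroms), key=chrom_sort_key):
        if not include_x and str(chrom).upper() in ("X", "Y"):
            continue
        mask = table.chroms == chrom
        out[str(chrom)] = MarkerSeq(chrom=str(chrom),
                                    positions=table.positions[mask],
                                    states=m_states[mask])
    return out


def find_regions_array(table: ArrayGenotypeTable, sample_id: str,
                       thresholds: Thresholds = DEFAULT_THRESHOLDS,
                       include_x: bool = False) -> list[AutozygousRegion]:
    """Array pipeline: identical run logic with the scaled flank requirement."""
    if table.n_snps <= thresholds.min_array_size:
        raise DataFormatError(
            f"array design has {table.n_snps} genotypes; analysis is limited to "
            f"microarrays with more than {thresholds.min_array_size} genotypes"
        )
    min_run = array_min_run_variants(table.n_snps, thresholds.array_run_factor)
    regions: list[AutozygousRegion] = []
    for chrom, seq in to_marker_seq_array(table, sample_id, include_x).items():
        runs = find_runs(seq, min_run, thresholds.n_iterations)
        regions.extend(runs_to_regions(runs, seq, thresholds.min_region_length,
                                       sample_id, "array"))
    return regions


# ---------------------------------------------------------------------------
# Cross-sample operations
# ---------------------------------------------------------------------------

def shared_autozygosity(regions_by_sample: Mapping[str, Sequence[AutozygousRegion]],
                        affected_ids: Sequence[str],
                        unaffected_ids: Sequence[str] = (),
                        subtract_unaffected: bool = False,
                        ) -> list[tuple[str, int, int]]:
    """Genomic intervals autozygous in every affected sample.

    Optionally subtracts intervals autozygous in any unaffected sample
    (mirroring the affected/unaffected display distinction).  Returns
    (chrom, start, end) tuples, 1-based inclusive, sorted.
    """
    affected = [a for a in affected_ids]
    if not affected:
        raise ValueError("at least one affected sample with regions is required")

    def per_chrom(ids: Sequence[str]) -> dict[str, list[list[tuple[int, int]]]]:
        out: dict[str, list[list[tuple[int, int]]]] = {}
        for sid in ids:
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for r in regions_by_sample.get(sid, []):
                by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
            for chrom, ivs in by_chrom.items():
                out.setdefault(chrom, []).append(ivs)
        return out

    aff = per_chrom(affected)
    shared: list[tuple[str, int, int]] = []
    unaff_union: dict[str, list[tuple[int, int]]] = {}
    if subtract_unaffected:
        for chrom, sets in per_chrom(unaffected_ids).items():
            unaff_union[chrom] = iv.merge([t for s in sets for t in s])
    for chrom in sorted(aff, key=chrom_sort_key):
        if len(aff[chrom]) < len(affected):
            continue  # some affected sample has no region on this chromosome
        common = iv.intersect_many(aff[chrom])
        if subtract_unaffected and chrom in unaff_union:
            common = iv.subtract(common, unaff_union[chrom])
        shared.extend((chrom, s, e) for s, e in common)
    return shared


def concordance_class(states: Sequence[str],
                      thresholds: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """Classify cross-sample genotype concordance at one site.

    With p the largest fraction of called genotypes sharing the same
    homozygous state: p > 0.9 -> "black", 0.8 <= p <= 0.9 -> "orange",
    p < 0.8 -> "yellow" (all-heterozygous sites are "yellow" too, matching
    the display convention).  All-no-call input yields "uncalled".
    """
    called = [s for s in states if s != NOCALL]
    if not called:
        return "uncalled"
    n = len(called)
    p = max(called.count(AA), called.count(BB)) / n
    if p > thresholds.concord_black:
        return "black"
    if p >= thresholds.concord_orange:
        return "orange"
    return "yellow"
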