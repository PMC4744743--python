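"""Genotype re-determination from allele read depths.

Exome variant callers disagree on genotype conventions, so every variant's
genotype is re-derived from its reference/alternate read depths before any
autozygosity analysis:

* >80% of reads reference        -> homozygous reference (``AA``)
* >80% of reads the alternate    -> homozygous variant (``BB``)
* 40-60% of reads the alternate  -> heterozygous (``AB``)
* anything else, or no reads     -> no call (``NC``)

A call additionally carries a *depth qualification* used only by the
autozygosity run detector: variants with an rs identifier need >=15 reads
(homozygous) or >=30 reads (heterozygous); variants without one need >=75 or
>=150 reads respectively.  This floor is independent of the user-chosen
minimum depth at which variants are retained in the unified dataset
(``display_min_depth``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import re

import numpy as np

# Genotype state tokens.  NOCALL is spelled "NC", matching the unified
# dataset's on-disk token.
AA = "AA"
AB = "AB"
BB = "BB"
NOCALL = "NC"

STATES = (AA, AB, BB, NOCALL)

# Integer codes used by the matrix representation of a unified dataset.
CODE_AA, CODE_AB, CODE_BB, CODE_NOCALL = 0, 1, 2, 3
CODE_TO_STATE = np.array([AA, AB, BB, NOCALL])
STATE_TO_CODE = {AA: CODE_AA, AB: CODE_AB, BB: CODE_BB, NOCALL: CODE_NOCALL}

_RS_RE = re.compile(r"^rs\d+")


def is_rs_id(identifier: str | None) -> bool:
    """True iff ``identifier`` is a dbSNP-style rs accession (``rs`` + digits)."""
    return bool(identifier) and bool(_RS_RE.match(identifier))


@dataclass(frozen=True)
class Thresholds:
    """Every numeric constant of the mapping algorithms, in one record.

    Defaults are the published operating point of the method; any of them can
    be overridden from the CLI or programmatically.

    Attributes
    ----------
    hom_fraction
        Strict lower bound on the majority-allele read fraction for a
        homozygous call (">80% of reads").
    het_low, het_high
        Inclusive alternate-read-fraction band for a heterozygous call
        ("40-60% of reads").
    depth_hom_rs, depth_het_rs
        Minimum total depth (inclusive) for rs-annotated homozygous /
        heterozygous variants to enter run detection.
    depth_hom_novel, depth_het_novel
        The same floors for variants without an rs identifier.
    min_run_variants
        Strict per-flank homozygous-variant count required before an isolated
        interrupting heterozygote is reassigned to no-call (">25 variants").
    n_iterations
        Number of reassign-and-recompute passes over the runs.
    min_region_length
        Strict lower bound, in bp, on a reported autozygous region
        (">500 kb").
    array_run_factor
        Per-flank run requirement for microarray data is
        ``round(n_snps * array_run_factor)``.
    min_array_size
        Arrays with no more than this many genotypes on the design are
        rejected.
    concord_black, concord_orange
        Concordance-fraction bin edges: >0.9 black, 0.8-0.9 orange,
        <0.8 yellow.
    display_min_depth
        User-chosen minimum read depth at which a homozygous-reference
        genotype is filled in from the depth tables.  Independent of the
        autozygosity floors above.
    """

    hom_fraction: float = 0.8
    het_low: float = 0.4
    het_high: float = 0.6
    depth_hom_rs: int = 15
    depth_het_rs: int = 30
    depth_hom_novel: int = 75
    depth_het_novel: int = 150
    min_run_variants: int = 25
    n_iterations: int = 4
    min_region_length: int = 500_000
    array_run_factor: float = 7e-4
    min_array_size: int = 10_000
    concord_black: float = 0.9
    concord_orange: float = 0.8
    display_min_depth: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.het_low < self.het_high < self.hom_fraction < 1.0):
            raise ValueError(
                "require 0 < het_low < het_high < hom_fraction < 1, got "
                f"{self.het_low}, {self.het_high}, {self.hom_fraction}"
            )
        for name in ("depth_hom_rs", "depth_het_rs", "depth_hom_novel", "depth_het_novel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's re-determined genotype at one site."""

    state: str
    ref_depth: int
    alt_depth: int
    has_rs: bool = False
    depth_qualified: bool = False

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown genotype state {self.state!r}")
        if self.state == NOCALL and self.depth_qualified:
            raise ValueError("a no-call genotype can never be depth-qualified")

    @property
    def total_depth(self) -> int:
        return self.ref_depth + self.alt_depth


def recall_genotype(ref_depth: int, alt_depth: int,
                    thresholds: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """Re-determine a genotype from its allele read depths.

    The four published rules are applied in order; fraction comparisons are
    strict for the 80% rules and inclusive for the 40-60% band.  Reads from
    other alternate alleles at a split multi-allelic site are excluded from
    the denominator.
    """
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError(f"negative read depth ({ref_depth}, {alt_depth})")
    total = ref_depth + alt_depth
    if total == 0:
        return NOCALL
    f = alt_depth / total
    if 1.0 - f > thresholds.hom_fraction:
        return AA
    if f > thresholds.hom_fraction:
        return BB
    if thresholds.het_low <= f <= thresholds.het_high:
        return AB
    return NOCALL


def recall_genotypes(ref_depths: np.ndarray, alt_depths: np.ndarray,
                     thresholds: Thresholds = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Vectorised :func:`recall_genotype`; returns int8 state codes."""
    r = np.asarray(ref_depths, dtype=np.int64)
    a = np.asarray(alt_depths, dtype=np.int64)
    if (r < 0).any() or (a < 0).any():
        raise ValueError("negative read depth")
    total = r + a
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, a / np.maximum(total, 1), np.nan)
    out = np.full(r.shape, CODE_NOCALL, dtype=np.int8)
    called = total > 0
    out[called & (1.0 - f > thresholds.hom_fraction)] = CODE_AA
    out[called & (f > thresholds.hom_fraction)] = CODE_BB
    out[called
        & ~(1.0 - f > thresholds.hom_fraction)
        & ~(f > thresholds.hom_fraction)
        & (f >= thresholds.het_low) & (f <= thresholds.het_high)] = CODE_AB
    return out


def min_depth_for(state: str, has_rs: bool,
                  thresholds: Thresholds = DEFAULT_THRESHOLDS) -> int:
    """Minimum total read depth for a call to enter autozygosity analysis."""
    if state == NOCALL:
        raise ValueError("no-call genotypes have no depth floor")
    if state not in STATES:
        raise ValueError(f"unknown genotype state {state!r}")
    hom = state in (AA, BB)
    if has_rs:
        return thresholds.depth_hom_rs if hom else thresholds.depth_het_rs
    return thresholds.depth_hom_novel if hom else thresholds.depth_het_novel


def qualify_call(call: GenotypeCall,
                 thresholds: Thresholds = DEFAULT_THRESHOLDS) -> GenotypeCall:
    """Return ``call`` with ``depth_qualified`` set.

    Depth floors are inclusive; a no-call is never qualified.
    """
    if call.state == NOCALL:
        return replace(call, depth_qualified=False)
    floor = min_depth_for(call.state, call.has_rs, thresholds)
    return replace(call, depth_qualified=call.total_depth >= floor)
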