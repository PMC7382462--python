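"""Shared domain types for the matched-control evolutionary-signature framework.

The pipeline operates on trait-associated genomic regions (a lead GWAS variant
plus its high-LD partners) and compares each region's median value of an
evolutionary measure against the distribution of medians over MAF/LD-matched
control regions. The types here are the common currency of every stage.

Coordinates are 1-based inclusive everywhere after ingestion; haplotype
matrices are {0,1} with one row per phased haplotype and one column per
variant, columns sorted by (chrom, pos).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: explicit missing marker for score lookups and medians (never 0)
MISSING = None


class InputError(ValueError):
    """Malformed or inconsistent user input (maps to CLI exit code 1)."""


@dataclass(frozen=True)
class Variant:
    """A biallelic variant; the atomic unit of regions.

    ``id`` is an rsID or a ``chrom:pos:ref:alt`` string and must be unique
    within a panel. ``pos`` is 1-based.
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise InputError(f"variant {self.id}: ref == alt ({self.ref})")


@dataclass
class HaplotypePanel:
    """Phased haplotypes for one population.

    ``haplotypes`` has shape (2 * n_diploids, n_variants) with entries in
    {0, 1}; row 2i and 2i+1 are the two haplotypes of diploid i.
    """

    population: str
    variants: list[Variant]
    haplotypes: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        h = self.haplotypes
        if h.ndim != 2 or h.shape[1] != len(self.variants):
            raise InputError(
                f"haplotype matrix shape {h.shape} inconsistent with "
                f"{len(self.variants)} variants"
            )
        if h.shape[0] % 2 != 0:
            raise InputError("haplotype row count must be even (phased diploids)")
        if h.size and (h.min() < 0 or h.max() > 1):
            raise InputError("haplotype entries must be 0/1")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate variant ids in panel")
        keys = [(v.chrom, v.pos) for v in self.variants]
        if keys != sorted(keys):
            raise InputError("panel columns must be sorted by (chrom, pos)")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        """Physical bp per column (1-based)."""
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants], dtype=object)

    def index_of(self, variant_id: str) -> int:
        try:
            return self._id_index[variant_id]
        except AttributeError:
            self._id_index = {v.id: i for i, v in enumerate(self.variants)}
            return self._id_index[variant_id]

    def alt_frequency(self, i: int) -> float:
        return float(self.haplotypes[:, i].mean())

    def maf(self, i: int) -> float:
        """Folded (minor) allele frequency min(p, 1-p)."""
        p = self.alt_frequency(i)
        return min(p, 1.0 - p)

    def is_polymorphic(self, i: int) -> bool:
        col = self.haplotypes[:, i]
        return bool(col.any() and not col.all())

    def variant_index(self) -> dict[str, tuple[str, int]]:
        """Mapping variant id -> (chrom, pos) for track lookups."""
        return {v.id: (v.chrom, v.pos) for v in self.variants}


@dataclass(frozen=True)
class GwasRecord:
    """One row of GWAS summary statistics."""

    variant_id: str
    chrom: str
    pos: int
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise InputError(
                f"GWAS p-value for {self.variant_id} must be in (0,1], "
                f"got {self.p_value}"
            )


@dataclass
class TraitRegion:
    """A lead variant plus its LD partners; named by the lead variant id."""

    lead: Variant
    members: list[Variant]
    r2_to_lead: dict[str, float]

    def __post_init__(self) -> None:
        member_ids = {v.id for v in self.members}
        if self.lead.id not in member_ids:
            raise InputError(f"region {self.lead.id}: lead not among members")

    @property
    def region_id(self) -> str:
        return self.lead.id

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ScoreTrack:
    """Per-variant values of one evolutionary measure.

    ``tail`` is ``"upper"`` for uni-directional measures (F_ST, |iHS|,
    XP-EHH, iES, Beta, PhastCons, GERP, LINSIGHT) and ``"two_sided"`` for
    bi-directional ones (PhyloP, TMRCA, alignment block age). Lookups at
    positions absent from the track return the explicit missing marker
    ``None``, never 0.
    """

    measure_name: str
    values: dict[tuple[str, int], float]
    tail: str = "upper"
    provenance: str = "ingested"

    def __post_init__(self) -> None:
        if self.tail not in ("upper", "two_sided"):
            raise InputError(f"unknown tail convention {self.tail!r}")
        if self.provenance not in ("computed", "ingested"):
            raise InputError(f"unknown provenance {self.provenance!r}")

    def lookup(self, chrom: str, pos: int) -> float | None:
        return self.values.get((chrom, int(pos)), MISSING)


@dataclass
class RegionMeasureResult:
    """Outcome of one region x measure comparison against its matched null."""

    region_id: str
    measure_name: str
    observed_median: float | None
    n_controls_used: int
    n_controls_marked: int
    empirical_p: float | None
    z: float | None
    removed: bool

    def __post_init__(self) -> None:
        if self.removed and self.empirical_p is not None:
            raise InputError("removed region cannot carry an empirical p")


def fold(p: float) -> float:
    """Fold an allele frequency: min(p, 1 - p)."""
    return min(p, 1.0 - p)


def is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))
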