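"""Greedy LD clumping of GWAS summary statistics into trait regions.

A region is a lead variant (smallest association p-value not yet assigned)
plus every unassigned variant within ``window_bp`` whose haplotype r² with
the lead exceeds ``r2_region`` and whose p-value passes ``p_member``.
Regions are disjoint and named by their lead variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import GwasRecord, HaplotypePanel, InputError, TraitRegion

log = logging.getLogger(__name__)


@dataclass
class ClumpConfig:
    """Thresholds for region construction.

    Defaults follow the nominal-association clumping convention: lead and
    member p-value cutoff 1e-4, region LD r² > 0.9, 250 kb window.
    """

    p_lead: float = 1e-4
    p_member: float = 1e-4
    r2_region: float = 0.9
    window_bp: int = 250_000

    def __post_init__(self) -> None:
        for name in ("p_lead", "p_member"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise InputError(f"{name} must be in (0,1], got {v}")
        if not (0.0 <= self.r2_region <= 1.0):
            raise InputError(f"r2_region must be in [0,1], got {self.r2_region}")
        if self.window_bp <= 0:
            raise InputError(f"window_bp must be > 0, got {self.window_bp}")


def r_squared(panel: HaplotypePanel, i: int, j: int) -> float:
    """Haplotype r² between columns i and j.

    r² = (p_AB − p_A p_B)² / (p_A(1−p_A) p_B(1−p_B)), computed from phased
    haplotype counts. Symmetric, and invariant under relabelling alleles at
    either site. Monomorphic columns have undefined LD.
    """
    return float(r_squared_block(panel.haplotypes, i, np.array([j]))[0])


def r_squared_block(haps: np.ndarray, i: int, js: np.ndarray) -> np.ndarray:
    """Vectorised haplotype r² between column ``i`` and columns ``js``."""
    x = haps[:, i].astype(np.float64)
    p_a = x.mean()
    if p_a in (0.0, 1.0):
        raise InputError(f"column {i} is monomorphic: LD undefined")
    Y = haps[:, js].astype(np.float64)
    p_b = Y.mean(axis=0)
    if ((p_b == 0.0) | (p_b == 1.0)).any():
        bad = int(np.asarray(js)[(p_b == 0.0) | (p_b == 1.0)][0])
        raise InputError(f"column {bad} is monomorphic: LD undefined")
    p_ab = (x @ Y) / haps.shape[0]
    d = p_ab - p_a * p_b
    return np.square(d) / (p_a * (1.0 - p_a) * p_b * (1.0 - p_b))


def clump_regions(gwas: list[GwasRecord], panel: HaplotypePanel,
                  cfg: ClumpConfig | None = None) -> list[TraitRegion]:
    """Greedy clumping by ascending p-value.

    GWAS variants absent from the panel are logged and skipped. Ties in p
    are broken by (chrom, pos) ascending, making the output independent of
    input row order. Returns an empty list when nothing passes ``p_lead``.
    """
    cfg = cfg or ClumpConfig()
    ids = {v.id: k for k, v in enumerate(panel.variants)}
    present, absent = [], []
    for rec in gwas:
        (present if rec.variant_id in ids else absent).append(rec)
    if absent:
        log.info("skipped %d GWAS variants absent from panel", len(absent))

    order = sorted(present, key=lambda r: (r.p_value, r.chrom, r.pos))
    assigned: set[str] = set()
    positions = panel.positions
    chroms = panel.chroms
    p_by_id = {r.variant_id: r.p_value for r in present}
    regions: list[TraitRegion] = []

    for rec in order:
        if rec.variant_id in assigned or rec.p_value > cfg.p_lead:
            continue
        li = ids[rec.variant_id]
        lead = panel.variants[li]
        in_window = np.flatnonzero(
            (chroms == lead.chrom)
            & (np.abs(positions - lead.pos) <= cfg.window_bp)
        )
        members = [lead]
        r2_map = {lead.id: 1.0}
        # candidate partners: unassigned GWAS variants in the window passing p_member
        cand = [k for k in in_window
                if k != li
                and panel.variants[k].id in p_by_id
                and panel.variants[k].id not in assigned
                and p_by_id[panel.variants[k].id] <= cfg.p_member
                and panel.is_polymorphic(k)]
        if cand and panel.is_polymorphic(li):
            r2s = r_squared_block(panel.haplotypes, li, np.array(cand))
            for k, r2 in zip(cand, r2s):
                if r2 > cfg.r2_region:
                    v = panel.variants[k]
                    members.append(v)
                    r2_map[v.id] = float(r2)
        members.sort(key=lambda v: (v.chrom, v.pos))
        regions.append(TraitRegion(lead=lead, members=members, r2_to_lead=r2_map))
        assigned.update(v.id for v in members)

    return regions
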