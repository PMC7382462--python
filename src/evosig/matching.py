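"""MAF/LD/gene-architecture-matched control regions.

For each trait region, candidate control lead variants are drawn from the
panel-wide pool under four matching windows on the lead's annotation —
minor allele frequency (±0.05 absolute), number of LD buddies (±10%
relative), gene density and distance to nearest gene (±500% relative,
clipped at 0) — then each control lead is grown into a control region with
the same member count as the trait region by sampling LD partners at
r² > 0.9, relaxing to r² > 0.6 for unfilled slots. Shortfalls are recorded
as the region's match fraction, not errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .clump import r_squared_block
from .core import HaplotypePanel, InputError, TraitRegion

log = logging.getLogger(__name__)


@dataclass
class VariantAnnotation:
    """Matching covariates for one pool variant."""

    variant_id: str
    maf: float
    n_ld_buddies: int
    gene_density: int
    gene_distance: int

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise InputError(f"{self.variant_id}: maf must be in (0,0.5], got {self.maf}")
        if min(self.n_ld_buddies, self.gene_density, self.gene_distance) < 0:
            raise InputError(f"{self.variant_id}: counts must be >= 0")


@dataclass
class ControlRegion:
    lead_id: str
    member_ids: list[str]          # ids actually filled (lead first)
    matched_at: list[float]        # per member: 0.9 (strict) or 0.6 (relaxed); lead 0.9
    match_fraction: float


@dataclass
class ControlSuite:
    """Matched control regions for one trait region."""

    region_id: str
    control_regions: list[ControlRegion]
    n_requested: int = 5000
    seed: int | None = None
    shortfall: int = 0

    @property
    def match_fractions(self) -> np.ndarray:
        return np.array([c.match_fraction for c in self.control_regions])


@dataclass
class AnnotatedPool:
    """Annotations plus cached LD-buddy index lists, reused during assembly."""

    annotations: list[VariantAnnotation]
    buddies_strict: list[np.ndarray] = field(default_factory=list)  # r² > 0.9
    buddies_relaxed: list[np.ndarray] = field(default_factory=list)  # 0.6 < r² <= 0.9

    def by_id(self) -> dict[str, VariantAnnotation]:
        return {a.variant_id: a for a in self.annotations}

    def arrays(self, panel: HaplotypePanel):
        """Columnar view of the annotations for vectorised window tests."""
        try:
            return self._arrays
        except AttributeError:
            ids = np.array([a.variant_id for a in self.annotations], dtype=object)
            self._arrays = (
                ids,
                np.array([a.maf for a in self.annotations]),
                np.array([a.n_ld_buddies for a in self.annotations], dtype=float),
                np.array([a.gene_density for a in self.annotations], dtype=float),
                np.array([a.gene_distance for a in self.annotations], dtype=float),
                np.array([panel.variants[panel.index_of(a.variant_id)].chrom
                          for a in self.annotations], dtype=object),
                np.array([panel.variants[panel.index_of(a.variant_id)].pos
                          for a in self.annotations], dtype=np.int64),
            )
            return self._arrays


def _gene_distance(chrom: str, pos: int, genes: list[tuple[str, int, int]]) -> int:
    """bp to nearest gene on the same chrom; 0 if genic. Ties toward lower coordinate."""
    best = None
    for gc, gs, ge in genes:
        if gc != chrom:
            continue
        if gs <= pos <= ge:
            return 0
        d = gs - pos if pos < gs else pos - ge
        if best is None or d < best:
            best = d
    if best is None:
        raise InputError(f"no genes on {chrom}: gene_distance undefined")
    return int(best)


def _gene_density(chrom: str, pos: int, genes: list[tuple[str, int, int]],
                  window_bp: int) -> int:
    lo, hi = pos - window_bp // 2, pos + window_bp // 2
    return sum(1 for gc, gs, ge in genes
               if gc == chrom and gs <= hi and ge >= lo)


def annotate_pool(panel: HaplotypePanel, genes: list[tuple[str, int, int]],
                  density_window_bp: int = 100_000,
                  ld_window_bp: int = 250_000,
                  r2_buddy: float = 0.9,
                  r2_relaxed: float = 0.6) -> AnnotatedPool:
    """Annotate every polymorphic panel variant with the four matching covariates.

    ``n_ld_buddies`` counts panel variants within ``ld_window_bp`` at
    r² > ``r2_buddy`` (self excluded). Buddy index lists at the strict and
    relaxed thresholds are cached for control-region assembly.

    Genes are 1-based inclusive intervals (chrom, start, end); an empty gene
    set makes gene_distance undefined and is an error.
    """
    if not genes:
        raise InputError("empty gene set: gene_distance undefined")
    positions = panel.positions
    chroms = panel.chroms
    poly = np.array([panel.is_polymorphic(i) for i in range(panel.n_variants)])

    annotations: list[VariantAnnotation] = []
    strict: list[np.ndarray] = []
    relaxed: list[np.ndarray] = []
    empty = np.array([], dtype=np.int64)
    for i in range(panel.n_variants):
        if not poly[i]:
            strict.append(empty)
            relaxed.append(empty)
            continue
        v = panel.variants[i]
        in_window = np.flatnonzero(
            (chroms == v.chrom)
            & (np.abs(positions - v.pos) <= ld_window_bp)
            & poly
        )
        in_window = in_window[in_window != i]
        if in_window.size:
            r2 = r_squared_block(panel.haplotypes, i, in_window)
            s = in_window[r2 > r2_buddy]
            r = in_window[(r2 > r2_relaxed) & (r2 <= r2_buddy)]
        else:
            s = r = empty
        strict.append(s)
        relaxed.append(r)
        annotations.append(VariantAnnotation(
            variant_id=v.id,
            maf=panel.maf(i),
            n_ld_buddies=int(s.size),
            gene_density=_gene_density(v.chrom, v.pos, genes, density_window_bp),
            gene_distance=_gene_distance(v.chrom, v.pos, genes),
        ))
    return AnnotatedPool(annotations=annotations,
                         buddies_strict=strict, buddies_relaxed=relaxed)


def matches_windows(lead: VariantAnnotation, cand: VariantAnnotation,
                    maf_window: float = 0.05,
                    buddy_rel: float = 0.10,
                    gene_rel: float = 5.0) -> bool:
    """The four SNPSNAP-style matching window tests.

    MAF is absolute (±0.05 percentage-point window on the folded frequency);
    buddies/density/distance are relative windows around the lead's value,
    lower bound clipped at 0. A lead value of 0 therefore only matches 0.
    """
    if abs(cand.maf - lead.maf) > maf_window:
        return False
    if abs(cand.n_ld_buddies - lead.n_ld_buddies) > buddy_rel * lead.n_ld_buddies:
        return False
    for lv, cv in ((lead.gene_density, cand.gene_density),
                   (lead.gene_distance, cand.gene_distance)):
        lo = max(0.0, lv - gene_rel * lv)
        hi = lv + gene_rel * lv
        if not (lo <= cv <= hi):
            return False
    return True


def select_control_leads(lead_ann: VariantAnnotation,
                         pool: list[VariantAnnotation],
                         n: int, seed: int,
                         maf_window: float = 0.05,
                         buddy_rel: float = 0.10,
                         gene_rel: float = 5.0) -> list[str]:
    """Pick up to ``n`` matched control leads from the pool, without replacement.

    The caller must already have excluded the trait region's own members and
    anything within the clump window of the lead. If fewer than ``n``
    candidates qualify, all are returned and the shortfall logged.
    """
    if not pool:
        raise InputError("empty control pool")
    qualified = [a.variant_id for a in pool
                 if matches_windows(lead_ann, a, maf_window, buddy_rel, gene_rel)]
    if len(qualified) <= n:
        if len(qualified) < n:
            log.info("control shortfall for %s: %d of %d requested",
                     lead_ann.variant_id, len(qualified), n)
        return qualified
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(qualified), size=n, replace=False)
    return [qualified[k] for k in sorted(picked)]


def assemble_control_regions(control_leads: list[str], k: int,
                             panel: HaplotypePanel, seed: int,
                             pool: AnnotatedPool | None = None,
                             region_id: str = "",
                             n_requested: int = 5000,
                             window_bp: int = 250_000,
                             exclude_ids: set[str] | None = None) -> ControlSuite:
    """Grow each control lead into a control region of up to ``k`` partners.

    Partners are sampled without replacement at r² > 0.9 within the clump
    window of the control lead; unfilled slots are retried at r² > 0.6;
    slots still unfilled become missing members. match_fraction =
    (filled members incl. lead) / (k + 1).
    """
    rng = np.random.default_rng(seed)
    exclude_ids = exclude_ids or set()
    regions: list[ControlRegion] = []
    for lead_id in control_leads:
        li = panel.index_of(lead_id)
        if pool is not None:
            strict = pool.buddies_strict[li]
            relaxed = pool.buddies_relaxed[li]
        else:
            strict, relaxed = _buddy_indices(panel, li, window_bp)
        strict = np.array([j for j in strict
                           if panel.variants[j].id not in exclude_ids], dtype=np.int64)
        relaxed = np.array([j for j in relaxed
                            if panel.variants[j].id not in exclude_ids], dtype=np.int64)
        members = [lead_id]
        matched_at = [0.9]
        take_strict = min(k, strict.size)
        if take_strict:
            idx = rng.choice(strict.size, size=take_strict, replace=False)
            for j in strict[np.sort(idx)]:
                members.append(panel.variants[j].id)
                matched_at.append(0.9)
        unfilled = k - take_strict
        take_relaxed = min(unfilled, relaxed.size)
        if take_relaxed:
            idx = rng.choice(relaxed.size, size=take_relaxed, replace=False)
            for j in relaxed[np.sort(idx)]:
                members.append(panel.variants[j].id)
                matched_at.append(0.6)
        regions.append(ControlRegion(
            lead_id=lead_id, member_ids=members, matched_at=matched_at,
            match_fraction=len(members) / (k + 1),
        ))
    return ControlSuite(region_id=region_id, control_regions=regions,
                        n_requested=n_requested, seed=seed,
                        shortfall=max(0, n_requested - len(control_leads)))


def _buddy_indices(panel: HaplotypePanel, i: int, window_bp: int):
    positions = panel.positions
    chroms = panel.chroms
    v = panel.variants[i]
    in_window = np.flatnonzero(
        (chroms == v.chrom) & (np.abs(positions - v.pos) <= window_bp)
    )
    in_window = np.array([j for j in in_window
                          if j != i and panel.is_polymorphic(j)], dtype=np.int64)
    if not in_window.size:
        e = np.array([], dtype=np.int64)
        return e, e
    r2 = r_squared_block(panel.haplotypes, i, in_window)
    return in_window[r2 > 0.9], in_window[(r2 > 0.6) & (r2 <= 0.9)]


def build_control_suite(region: TraitRegion, panel: HaplotypePanel,
                        pool: AnnotatedPool, n_controls: int, seed: int,
                        window_bp: int = 250_000,
                        maf_window: float = 0.05,
                        buddy_rel: float = 0.10,
                        gene_rel: float = 5.0) -> ControlSuite:
    """End-to-end matched suite for one trait region.

    Excludes the trait region's members and anything within the clump window
    of the lead from the candidate pool, then selects matched leads and
    assembles control regions. The same pool variant may serve different
    trait regions, but sampling is without replacement within a region.
    """
    ann_by_id = pool.by_id()
    lead_ann = ann_by_id.get(region.lead.id)
    if lead_ann is None:
        raise InputError(f"lead {region.lead.id} missing from annotated pool")
    member_ids = {v.id for v in region.members}
    lead = region.lead
    # vectorised equivalent of filtering the pool then select_control_leads
    ids, maf, bud, den, dis, chroms, pos = pool.arrays(panel)
    if ids.size == 0:
        raise InputError("empty control pool")
    mask = np.abs(maf - lead_ann.maf) <= maf_window
    mask &= np.abs(bud - lead_ann.n_ld_buddies) <= \
        buddy_rel * lead_ann.n_ld_buddies
    for lv, col in ((lead_ann.gene_density, den),
                    (lead_ann.gene_distance, dis)):
        mask &= (col >= max(0.0, lv - gene_rel * lv)) & (col <= lv + gene_rel * lv)
    mask &= ~((chroms == lead.chrom)
              & (np.abs(pos - lead.pos) <= window_bp))
    if member_ids:
        mask &= np.array([i not in member_ids for i in ids])
    qualified = list(ids[mask])
    if len(qualified) > n_controls:
        rng = np.random.default_rng(seed)
        picked = rng.choice(len(qualified), size=n_controls, replace=False)
        leads = [qualified[k] for k in sorted(picked)]
    else:
        if len(qualified) < n_controls:
            log.info("control shortfall for %s: %d of %d requested",
                     region.region_id, len(qualified), n_controls)
        leads = qualified
    return assemble_control_regions(
        leads, k=region.size - 1, panel=panel, seed=seed + 1, pool=pool,
        region_id=region.region_id, n_requested=n_controls,
        exclude_ids=member_ids, window_bp=window_bp,
    )


def _within_window(panel, vid, chrom, pos, window_bp) -> bool:
    v = panel.variants[panel.index_of(vid)]
    return v.chrom == chrom and abs(v.pos - pos) <= window_bp


def write_control_suite(suite: ControlSuite, path) -> None:
    """TSV: region_id, control_index, member_id, matched_at_r2."""
    with open(path, "w") as fh:
        fh.write("region_id\tcontrol_index\tmember_id\tmatched_at_r2\n")
        for i, cr in enumerate(suite.control_regions):
            for mid, at in zip(cr.member_ids, cr.matched_at):
                fh.write(f"{suite.region_id}\t{i}\t{mid}\t{at}\n")
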