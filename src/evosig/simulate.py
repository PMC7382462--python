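"""Synthetic pipeline inputs with known planted structure.

Haplotypes are mosaic copies of a small founder set: each simulated
haplotype walks along the chromosome copying one founder and switches
founder with a per-bp probability at each inter-variant gap, then receives
independent per-site mutations. Founder allele patterns repeat across runs
of adjacent sites, which yields the block LD structure the clumping,
matching and EHH machinery need. This is deliberately not a coalescent
simulation: frequency spectra and recombination heterogeneity of real
panels are not reproduced, which is documented and acceptable for testing
the framework's statistical machinery.

Planted signals give the framework detectable targets: a sweep (one founder
haplotype driven to high frequency in one population), a balanced locus
(folded frequencies pinned near 0.5 with frequency-matched neighbours),
a differentiated locus (allele-frequency shift in one population), or a
conserved-track shift (additive offset on an ingested-style score track).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clump import ClumpConfig, clump_regions, r_squared_block
from .core import GwasRecord, HaplotypePanel, InputError, ScoreTrack, Variant
from .io import ensure_dir, write_gwas, write_score_track, write_vcf_panel

#: a small time-calibrated primate tree (branch lengths Myr) for block-age
#: and parsimony fixtures
DEFAULT_TREE_NEWICK = (
    "((((human:6.7,chimp:6.7):2.2,gorilla:8.9):6.5,orangutan:15.4):13.6,"
    "macaque:29.0);"
)


@dataclass
class PlantedSignal:
    """One planted evolutionary signal.

    ``locus`` is the lead column index; ``span`` columns starting there are
    affected. ``kind`` is one of sweep / balanced / differentiated /
    conserved_track; ``effect`` is the target frequency (sweep), the
    frequency shift (differentiated), or the track offset in track-sd units
    (conserved_track).
    """

    locus: int
    kind: str
    effect: float
    span: int = 5
    population: str | None = None
    columns: list[int] | None = None  # explicit columns override locus/span

    def __post_init__(self) -> None:
        if self.kind not in ("sweep", "balanced", "differentiated",
                             "conserved_track"):
            raise InputError(f"unknown signal kind {self.kind!r}")


@dataclass
class SimConfig:
    """Generator settings; the seed is mandatory.

    Defaults give two populations of 50 diploids each over a ~400 kb
    chromosome with ~4000 variants in LD blocks of a few kb — small enough
    to evaluate quickly, structured enough that clumping, matching and the
    haplotype statistics all have something to work with.
    """

    seed: int
    n_pops: int = 2
    n_diploids: int = 50
    n_variants: int = 4000
    n_founders: int = 8
    recomb_per_bp: float = 2e-5
    mutation_rate: float = 0.002
    pattern_repeat: float = 0.9
    mean_gap_bp: int = 100
    chrom: str = "chr1"
    planted_signals: list[PlantedSignal] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InputError("seed is mandatory")
        for p in (self.recomb_per_bp, self.mutation_rate, self.pattern_repeat):
            if not (0.0 <= p <= 1.0):
                raise InputError(f"probability out of [0,1]: {p}")
        for s in self.planted_signals:
            if not (0 <= s.locus < self.n_variants):
                raise InputError(f"signal locus {s.locus} out of range")


def _population_names(n: int) -> list[str]:
    return [f"POP{k + 1}" for k in range(n)]


def simulate_panels(cfg: SimConfig
                    ) -> tuple[dict[str, HaplotypePanel], dict[str, int]]:
    """Simulate one HaplotypePanel per population plus the true ancestral map.

    The reference allele (0) is ancestral at every site; founder patterns
    carry the derived allele. Returns ({population: panel}, {variant id: 0}).
    Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    V, F = cfg.n_variants, cfg.n_founders

    gaps = rng.integers(cfg.mean_gap_bp // 2, cfg.mean_gap_bp * 3 // 2 + 1,
                        size=V)
    positions = np.cumsum(gaps) + 1000

    # founder allele patterns, repeated over runs of adjacent sites
    founders = np.zeros((F, V), dtype=np.int8)
    pattern = np.zeros(F, dtype=np.int8)
    for j in range(V):
        if j == 0 or rng.random() >= cfg.pattern_repeat:
            pattern = np.zeros(F, dtype=np.int8)
            k = int(rng.integers(1, F)) if F > 1 else 1
            pattern[rng.choice(F, size=min(k, F), replace=False)] = 1
        founders[:, j] = pattern

    p_switch = 1.0 - np.exp(-cfg.recomb_per_bp * gaps)
    variants = [Variant(f"v{j:06d}", cfg.chrom, int(positions[j]), "A", "G")
                for j in range(V)]

    panels: dict[str, HaplotypePanel] = {}
    for pop in _population_names(cfg.n_pops):
        n_hap = 2 * cfg.n_diploids
        H = np.empty((n_hap, V), dtype=np.int8)
        for h in range(n_hap):
            switches = rng.random(V) < p_switch
            switches[0] = True
            seg = np.cumsum(switches) - 1
            founder_ids = rng.integers(0, F, size=int(seg[-1]) + 1)
            H[h] = founders[founder_ids[seg], np.arange(V)]
        if cfg.mutation_rate > 0.0:
            flips = rng.random(H.shape) < cfg.mutation_rate
            H ^= flips.astype(np.int8)
        panels[pop] = HaplotypePanel(population=pop, variants=list(variants),
                                     haplotypes=H,
                                     samples=[f"{pop}_S{i}"
                                              for i in range(cfg.n_diploids)])

    ancestral = {v.id: 0 for v in variants}
    for sig in cfg.planted_signals:
        plant_signal(panels, sig, rng)
    return panels, ancestral


def _shift_column_frequency(H: np.ndarray, j: int, target: float,
                            rng: np.random.Generator) -> None:
    """Flip entries in column j until its allele-1 frequency reaches target."""
    n = H.shape[0]
    want = int(round(target * n))
    have = int(H[:, j].sum())
    if want > have:
        zeros = np.flatnonzero(H[:, j] == 0)
        pick = rng.choice(zeros, size=want - have, replace=False)
        H[pick, j] = 1
    elif want < have:
        ones = np.flatnonzero(H[:, j] == 1)
        pick = rng.choice(ones, size=have - want, replace=False)
        H[pick, j] = 0


def plant_signal(panels: dict[str, HaplotypePanel], sig: PlantedSignal,
                 rng: np.random.Generator) -> None:
    """Modify panels in place to carry one planted signal.

    sweep: one existing haplotype's segment over the span is copied into a
    ``effect`` fraction of haplotypes in the target population (long shared
    haplotype, elevated iHH contrast and F_ST).
    balanced: folded frequencies over the span pinned near 0.5 in every
    population with frequency-matched neighbours (elevated Beta).
    differentiated: allele frequency over the span shifted by ``effect`` in
    the target population (elevated F_ST).
    conserved_track signals act on tracks, not panels — see
    :func:`plant_track_signal`.
    """
    pops = list(panels)
    target_pop = sig.population or pops[-1]
    if sig.columns is not None:
        cols = list(sig.columns)
    else:
        cols = range(sig.locus, min(sig.locus + sig.span,
                                    panels[pops[0]].n_variants))
    if sig.kind == "differentiated":
        H = panels[target_pop].haplotypes
        for j in cols:
            f = float(H[:, j].mean())
            # shift in whichever direction leaves room for the full delta
            target = f + sig.effect if f + sig.effect <= 0.98 \
                else max(0.02, f - sig.effect)
            _shift_column_frequency(H, j, min(0.98, max(0.02, target)), rng)
    elif sig.kind == "sweep":
        H = panels[target_pop].haplotypes
        donor = int(rng.integers(0, H.shape[0]))
        n_carriers = int(round(sig.effect * H.shape[0]))
        carriers = rng.choice(H.shape[0], size=n_carriers, replace=False)
        lo, hi = sig.locus, max(c for c in cols) + 1
        H[np.ix_(carriers, range(lo, hi))] = H[donor, lo:hi]
    elif sig.kind == "balanced":
        for pop in pops:
            H = panels[pop].haplotypes
            for j in cols:
                jitter = float(rng.uniform(-0.04, 0.04))
                _shift_column_frequency(H, j, 0.5 + jitter, rng)
    elif sig.kind == "conserved_track":
        raise InputError("conserved_track signals apply to tracks; "
                         "use plant_track_signal")


def plant_track_signal(track: ScoreTrack, panel: HaplotypePanel,
                       sig: PlantedSignal) -> None:
    """Add the signal offset to the track over the span's positions."""
    if sig.kind != "conserved_track":
        raise InputError(f"expected conserved_track signal, got {sig.kind}")
    cols = sig.columns if sig.columns is not None else \
        range(sig.locus, min(sig.locus + sig.span, panel.n_variants))
    for j in cols:
        v = panel.variants[j]
        key = (v.chrom, v.pos)
        if key in track.values:
            track.values[key] += sig.effect


def gaussian_track(panel: HaplotypePanel, rng: np.random.Generator,
                   measure_name: str, tail: str = "upper",
                   mean: float = 0.0, sd: float = 1.0) -> ScoreTrack:
    """iid Normal(mean, sd) track covering every panel position."""
    vals = rng.normal(mean, sd, size=panel.n_variants)
    return ScoreTrack(
        measure_name=measure_name,
        values={(v.chrom, v.pos): float(vals[j])
                for j, v in enumerate(panel.variants)},
        tail=tail, provenance="ingested")


def choose_region_leads(cfg: SimConfig, n_regions: int,
                        window_bp: int) -> list[int]:
    """Evenly spaced lead column indices, >= 2*window_bp apart."""
    spacing_cols = max(1, (2 * window_bp) // cfg.mean_gap_bp + 5)
    leads = list(range(spacing_cols // 2, cfg.n_variants - 2,
                       spacing_cols))[:n_regions]
    if len(leads) < n_regions:
        raise InputError(
            f"panel too small for {n_regions} regions at window {window_bp}")
    return leads


def gwas_for_leads(panel: HaplotypePanel, leads: list[int],
                   rng: np.random.Generator,
                   cfg_clump: ClumpConfig) -> list[GwasRecord]:
    """GWAS p-values constructed so clumping recovers exactly the leads.

    Each lead gets a distinct p-value well under the lead threshold; its
    strict-LD partners inside the window get member-level p-values; all
    other variants get null p-values above the threshold.
    """
    positions = panel.positions
    p = rng.uniform(0.01, 1.0, size=panel.n_variants)
    for rank, li in enumerate(leads):
        p[li] = 1e-8 * (1 + rank)
        in_win = np.flatnonzero(
            np.abs(positions - positions[li]) <= cfg_clump.window_bp)
        in_win = np.array([j for j in in_win
                           if j != li and panel.is_polymorphic(j)])
        if in_win.size and panel.is_polymorphic(li):
            r2 = r_squared_block(panel.haplotypes, li, in_win)
            for j in in_win[r2 > cfg_clump.r2_region]:
                p[j] = 5e-5
    return [GwasRecord(v.id, v.chrom, v.pos, float(p[j]))
            for j, v in enumerate(panel.variants)]


def random_genes(cfg: SimConfig, rng: np.random.Generator,
                 n_genes: int = 30) -> list[tuple[str, int, int]]:
    """Random gene intervals (1-based inclusive) tiling the chromosome."""
    length = cfg.n_variants * cfg.mean_gap_bp + 2000
    genes = []
    for _ in range(n_genes):
        start = int(rng.integers(1, max(2, length - 5000)))
        genes.append((cfg.chrom, start, start + int(rng.integers(500, 5000))))
    return sorted(genes)


def random_tip_state_table(rng: np.random.Generator, n_sites: int = 20,
                           species: tuple[str, ...] = ("human", "chimp",
                                                       "gorilla", "orangutan",
                                                       "macaque")) -> list[dict]:
    """Per-site tip alleles over the default tree's species, some with gaps."""
    rows = []
    states = "ACGT"
    for s in range(n_sites):
        base = states[rng.integers(0, 4)]
        site = {}
        for sp in species:
            r = rng.random()
            if r < 0.1:
                site[sp] = "-"
            elif r < 0.3:
                site[sp] = states[rng.integers(0, 4)]
            else:
                site[sp] = base
        rows.append({"site_id": f"s{s:03d}", "states": site})
    return rows


def write_fixture_bundle(cfg: SimConfig, outdir,
                         n_regions: int = 10,
                         window_bp: int = 5000) -> dict:
    """Write a complete input bundle and return the truth record.

    Produces: panel VCF (all populations) + sample map, GWAS TSV, gene BED,
    score-track TSVs (one per ingested-style measure, with planted shifts
    applied), newick tree, tip-state TSV, and truth.json listing the
    planted loci, signal kinds and the expected region leads.
    """
    out = ensure_dir(outdir)
    rng = np.random.default_rng(cfg.seed + 1)
    panels, ancestral = simulate_panels(cfg)
    pops = list(panels)

    # combined VCF over all populations
    first = panels[pops[0]]
    all_samples = []
    blocks = []
    for pop in pops:
        all_samples += panels[pop].samples
        blocks.append(panels[pop].haplotypes)
    combined = HaplotypePanel(population="ALL", variants=list(first.variants),
                              haplotypes=np.vstack(blocks),
                              samples=all_samples)
    write_vcf_panel(combined, out / "panel.vcf")
    with open(out / "samples.tsv", "w") as fh:
        for pop in pops:
            for s in panels[pop].samples:
                fh.write(f"{s}\t{pop}\n")

    clump_cfg = ClumpConfig(window_bp=window_bp)
    anchor = panels[pops[0]]
    leads = choose_region_leads(cfg, n_regions, window_bp)
    gwas = gwas_for_leads(anchor, leads, rng, clump_cfg)
    write_gwas(gwas, out / "gwas.tsv")

    genes = random_genes(cfg, rng)
    with open(out / "genes.bed", "w") as fh:
        for chrom, start, end in genes:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")  # back to 0-based

    track = gaussian_track(anchor, rng, "phastcons", tail="upper")
    for sig in cfg.planted_signals:
        if sig.kind == "conserved_track":
            plant_track_signal(track, anchor, sig)
    write_score_track(track, out / "phastcons.tsv")
    tmrca = gaussian_track(anchor, rng, "tmrca", tail="two_sided",
                           mean=10.0, sd=3.0)
    write_score_track(tmrca, out / "tmrca.tsv")

    (out / "tree.nwk").write_text(DEFAULT_TREE_NEWICK + "\n")
    tip_rows = random_tip_state_table(rng)
    with open(out / "tip_states.tsv", "w") as fh:
        fh.write("site_id\tspecies\tstate\n")
        for row in tip_rows:
            for sp, st in row["states"].items():
                fh.write(f"{row['site_id']}\t{sp}\t{st}\n")

    with open(out / "ancestral.tsv", "w") as fh:
        fh.write("variant_id\tancestral_allele\n")
        for vid, a in ancestral.items():
            fh.write(f"{vid}\t{a}\n")

    truth = {
        "seed": cfg.seed,
        "populations": pops,
        "n_variants": cfg.n_variants,
        "region_lead_ids": [anchor.variants[li].id for li in leads],
        "planted_signals": [
            {"locus": s.locus, "lead_id": anchor.variants[s.locus].id,
             "kind": s.kind, "effect": s.effect, "span": s.span,
             "population": s.population}
            for s in cfg.planted_signals],
        "window_bp": window_bp,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
        fh.write("\n")
    return truth
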