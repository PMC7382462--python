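"""End-to-end orchestration: clump -> match -> measure -> evaluate -> cluster -> enrich.

Every stage writes a self-describing TSV plus a run-metadata JSON carrying
the seed and a parameter hash, so a rerun with the same configuration is
byte-identical and each stage can also be run standalone on the previous
stage's files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clump import ClumpConfig, clump_regions
from .cluster import (build_z_matrix, cluster_regions, extreme_regions,
                      genomewide_enrichment, matched_enrichment,
                      write_clusters, write_enrichment)
from .core import HaplotypePanel, InputError, ScoreTrack, TraitRegion
from .empirical import build_null, empirical_p, evaluate_all, region_median
from .io import (ensure_dir, read_genes_bed, read_gwas, read_sample_map,
                 read_score_track, read_vcf_panel, write_regions,
                 write_results_tsv, write_run_metadata, write_score_track)
from .matching import (AnnotatedPool, annotate_pool, build_control_suite,
                       write_control_suite)
from .measures import (DEFAULT_REGISTRY, apply_registry_transform, beta_track,
                       fst_track, ihs_scores, lookup_track_values,
                       xpehh_scores)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults mirror the framework's stated
    parameters (5000 controls, alpha 0.05, |z| threshold 1.5, dendrogram cut
    height 7, 5000 random regions x 1000 iterations for enrichment)."""

    vcf: str = ""
    sample_map: str = ""
    gwas: str = ""
    genes_bed: str = ""
    track_files: dict = field(default_factory=dict)  # name -> path
    anchor_population: str = "POP1"
    populations: list = field(default_factory=list)
    clump: ClumpConfig = field(default_factory=ClumpConfig)
    n_controls: int = 5000
    maf_window: float = 0.05
    buddy_rel: float = 0.10
    gene_rel: float = 5.0
    density_window_bp: int = 100_000
    alpha: float = 0.05
    z_threshold: float = 1.5
    cut_height: float = 7.0
    n_random: int = 5000
    n_iter: int = 1000
    n_null_regions_for_matched: int = 0   # 0: same size as trait set
    compute_measures: list = field(
        default_factory=lambda: ["fst", "xpehh", "beta"])
    compute_ihs: bool = False             # slow on large panels; opt in
    ancestral_map: str = ""
    seed: int = 0
    registry: dict = field(default_factory=lambda: dict(DEFAULT_REGISTRY))

    def parameter_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineState:
    """In-memory artefacts shared by the stages."""

    panels: dict[str, HaplotypePanel]
    regions: list[TraitRegion] = field(default_factory=list)
    pool: AnnotatedPool | None = None
    suites: dict = field(default_factory=dict)
    tracks: dict[str, ScoreTrack] = field(default_factory=dict)
    results: list = field(default_factory=list)


def load_inputs(cfg: RunConfig) -> PipelineState:
    sample_map = read_sample_map(cfg.sample_map)
    pops = cfg.populations or sorted(set(sample_map.values()))
    panels = {p: read_vcf_panel(cfg.vcf, sample_map, p) for p in pops}
    state = PipelineState(panels=panels)
    for name, path in cfg.track_files.items():
        entry = cfg.registry.get(name, {})
        state.tracks[name] = read_score_track(
            path, name, tail=entry.get("tail", "upper"))
    return state


def stage_clump(cfg: RunConfig, state: PipelineState) -> None:
    gwas = read_gwas(cfg.gwas)
    anchor = state.panels[cfg.anchor_population]
    state.regions = clump_regions(gwas, anchor, cfg.clump)
    log.info("clumped %d GWAS variants into %d regions",
             len(gwas), len(state.regions))


def stage_annotate(cfg: RunConfig, state: PipelineState) -> None:
    genes = read_genes_bed(cfg.genes_bed)
    anchor = state.panels[cfg.anchor_population]
    state.pool = annotate_pool(anchor, genes,
                               density_window_bp=cfg.density_window_bp,
                               ld_window_bp=cfg.clump.window_bp)


def stage_match(cfg: RunConfig, state: PipelineState) -> None:
    anchor = state.panels[cfg.anchor_population]
    for i, region in enumerate(state.regions):
        state.suites[region.region_id] = build_control_suite(
            region, anchor, state.pool, cfg.n_controls,
            seed=cfg.seed + 7919 * (i + 1),
            window_bp=cfg.clump.window_bp, maf_window=cfg.maf_window,
            buddy_rel=cfg.buddy_rel, gene_rel=cfg.gene_rel)


def stage_measures(cfg: RunConfig, state: PipelineState) -> None:
    """Compute the haplotype-based measures and fold in ingested tracks."""
    pops = sorted(state.panels)
    anchor = state.panels[cfg.anchor_population]
    if "fst" in cfg.compute_measures and len(pops) >= 2:
        others = [p for p in pops if p != cfg.anchor_population]
        for other in others:
            name = "fst" if len(others) == 1 else f"fst_{other.lower()}"
            tr = fst_track(anchor, state.panels[other], measure_name=name)
            state.tracks[name] = tr
    if "xpehh" in cfg.compute_measures and len(pops) >= 2:
        other = [p for p in pops if p != cfg.anchor_population][0]
        scores = xpehh_scores(anchor, state.panels[other])
        vi = anchor.variant_index()
        state.tracks["xpehh"] = ScoreTrack(
            "xpehh",
            {vi[vid]: s for vid, s in scores.items() if s is not None},
            tail="upper", provenance="computed")
    if "beta" in cfg.compute_measures:
        state.tracks["beta"] = beta_track(anchor)
    if cfg.compute_ihs:
        if not cfg.ancestral_map:
            raise InputError("compute_ihs requires ancestral_map (TSV: "
                             "variant_id, ancestral_allele)")
        anc = _read_ancestral_map(cfg.ancestral_map)
        scores = ihs_scores(anchor, anc)
        vi = anchor.variant_index()
        state.tracks["ihs"] = ScoreTrack(
            "ihs", {vi[vid]: s for vid, s in scores.items() if s is not None},
            tail="upper", provenance="computed")
    for name, track in list(state.tracks.items()):
        entry = cfg.registry.get(name, cfg.registry.get(
            name.split("_")[0], {}))
        state.tracks[name] = apply_registry_transform(track, entry)


def _read_ancestral_map(path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            vid, a = line.split()
            out[vid] = int(a)
    return out


def stage_evaluate(cfg: RunConfig, state: PipelineState) -> None:
    anchor = state.panels[cfg.anchor_population]
    vi = anchor.variant_index()
    registry = dict(cfg.registry)
    for name, track in state.tracks.items():
        registry.setdefault(name, {"tail": track.tail})
    state.results = evaluate_all(state.regions, state.suites, state.tracks,
                                 registry, vi)


def stage_cluster(cfg: RunConfig, state: PipelineState, outdir: Path) -> None:
    try:
        zm = build_z_matrix(state.results)
    except InputError:
        log.info("no measures survived missingness filter; skipping clustering")
        return
    extreme = extreme_regions(zm, cfg.z_threshold)
    sub = zm.values.loc[extreme] if extreme else zm.values
    from .cluster import ZMatrix
    zm_extreme = ZMatrix(values=sub, imputation_mask=zm.imputation_mask.loc[sub.index])
    labels = cluster_regions(zm_extreme, cfg.cut_height) if len(sub) else {}
    write_clusters(labels, outdir / "clusters.tsv")
    zm.values.to_csv(outdir / "zmatrix.tsv", sep="\t")
    with open(outdir / "extreme_regions.tsv", "w") as fh:
        fh.write("region_id\n")
        for rid in extreme:
            fh.write(rid + "\n")


def _random_region_medians(panel: HaplotypePanel, track: ScoreTrack,
                           size: int, n_regions: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Medians of contiguous random regions, the genome-wide pool."""
    out = np.empty(n_regions)
    vi = panel.variant_index()
    n = panel.n_variants
    for i in range(n_regions):
        start = int(rng.integers(0, max(1, n - size)))
        vals = [track.lookup(*vi[panel.variants[j].id])
                for j in range(start, start + size)]
        med = region_median(vals)
        out[i] = med if med is not None else np.nan
    return out[~np.isnan(out)]


def stage_enrich(cfg: RunConfig, state: PipelineState, outdir: Path) -> None:
    anchor = state.panels[cfg.anchor_population]
    rng_seed = cfg.seed + 104729
    reports_gw, reports_matched = [], []
    by_measure: dict[str, dict[str, "object"]] = {}
    for r in state.results:
        by_measure.setdefault(r.measure_name, {})[r.region_id] = r
    mean_size = max(1, round(np.mean([r.size for r in state.regions])))
    for mi, (measure, res) in enumerate(sorted(by_measure.items())):
        track = state.tracks[measure]
        medians = {rid: rr.observed_median for rid, rr in res.items()
                   if not rr.removed}
        pool_n = max(cfg.n_random + 500, 2 * cfg.n_random)
        rng = np.random.default_rng(rng_seed + mi)
        pool = _random_region_medians(anchor, track, mean_size, pool_n, rng)
        reports_gw.append(genomewide_enrichment(
            medians, pool, n_random=min(cfg.n_random, pool.shape[0]),
            n_iter=cfg.n_iter, seed=rng_seed + 31 * mi, measure=measure))
        pvals = {rid: rr.empirical_p for rid, rr in res.items()}
        sampler = _matched_null_sampler(cfg, state, measure, len(pvals))
        reports_matched.append(matched_enrichment(
            pvals, sampler, n_iter=cfg.n_iter, alpha=cfg.alpha,
            seed=rng_seed + 63 * mi + 1, measure=measure))
    write_enrichment(reports_gw, outdir / "enrichment_genomewide.tsv")
    write_enrichment(reports_matched, outdir / "enrichment_matched.tsv")


def _matched_null_sampler(cfg: RunConfig, state: PipelineState,
                          measure: str, set_size: int):
    """Random region sets evaluated against their own matched controls.

    Reuses the full matching machinery: each null region is a random pool
    variant grown into a region of the trait regions' typical size, matched
    and evaluated exactly like a trait region.
    """
    anchor = state.panels[cfg.anchor_population]
    track = state.tracks[measure]
    vi = anchor.variant_index()
    registry_tail = cfg.registry.get(measure, {}).get("tail", track.tail)
    pool_ids = [a.variant_id for a in state.pool.annotations]
    k = max(0, round(np.mean([r.size for r in state.regions])) - 1)

    def sampler(iteration: int, rng: np.random.Generator):
        ps = []
        picks = rng.choice(len(pool_ids), size=set_size, replace=False)
        for pi in picks:
            lead_id = pool_ids[pi]
            li = anchor.index_of(lead_id)
            lead = anchor.variants[li]
            strict = state.pool.buddies_strict[li]
            members = [lead] + [anchor.variants[j] for j in strict[:k]]
            members.sort(key=lambda v: (v.chrom, v.pos))
            region = TraitRegion(lead=lead, members=members,
                                 r2_to_lead={v.id: 1.0 for v in members})
            try:
                suite = build_control_suite(
                    region, anchor, state.pool, cfg.n_controls,
                    seed=cfg.seed + 13 * iteration + int(pi),
                    window_bp=cfg.clump.window_bp, maf_window=cfg.maf_window,
                    buddy_rel=cfg.buddy_rel, gene_rel=cfg.gene_rel)
            except InputError:
                ps.append(None)
                continue
            if not suite.control_regions:
                ps.append(None)
                continue
            null = build_null(suite, track, vi)
            obs = region_median(lookup_track_values(track, region))
            if null.removed or obs is None:
                ps.append(None)
            else:
                ps.append(empirical_p(obs, null, registry_tail))
        return ps

    return sampler


class StageError(InputError):
    """An error raised inside a pipeline stage, prefixed with the stage name."""


def _run_stage(name: str, fn, *args) -> None:
    try:
        fn(*args)
    except InputError as exc:
        raise StageError(f"stage {name}: {exc}") from exc


def run_pipeline(cfg: RunConfig, outdir) -> Path:
    """Run every stage in order and write all outputs under ``outdir``."""
    out = ensure_dir(outdir)
    state = load_inputs(cfg)
    _run_stage("clump", stage_clump, cfg, state)
    gwas_p = {r.variant_id: r.p_value for r in read_gwas(cfg.gwas)}
    write_regions(state.regions, gwas_p, out / "regions.tsv")
    _run_stage("annotate", stage_annotate, cfg, state)
    _run_stage("match", stage_match, cfg, state)
    suites_dir = ensure_dir(out / "controls")
    for rid, suite in state.suites.items():
        write_control_suite(suite, suites_dir / f"{rid}.tsv")
    _run_stage("measure", stage_measures, cfg, state)
    tracks_dir = ensure_dir(out / "tracks")
    for name, track in state.tracks.items():
        if track.provenance == "computed":
            write_score_track(track, tracks_dir / f"{name}.tsv")
    _run_stage("evaluate", stage_evaluate, cfg, state)
    write_results_tsv(state.results, out / "results.tsv")
    _run_stage("cluster", stage_cluster, cfg, state, out)
    _run_stage("enrich", stage_enrich, cfg, state, out)
    write_run_metadata(out / "run_metadata.json",
                       seed=cfg.seed, parameter_hash=cfg.parameter_hash(),
                       version=__version__,
                       n_regions=len(state.regions),
                       measures=sorted(state.tracks))
    return out
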