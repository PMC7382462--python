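"""Readers and writers for the standard formats the pipeline touches.

VCF 4.x with phased GT (read via cyvcf2), sample-map TSV, GWAS summary TSV,
score tracks as 3-column TSV or 4-column bedGraph, gene annotations as BED,
and TSV outputs with a header line. bedGraph and BED are 0-based half-open on
disk and converted to 1-based inclusive on read.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import GwasRecord, HaplotypePanel, InputError, ScoreTrack, TraitRegion, Variant

log = logging.getLogger(__name__)


def read_sample_map(path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, population)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    if df.empty:
        raise InputError(f"empty sample map: {path}")
    return dict(zip(df["sample"], df["population"]))


def read_vcf_panel(vcf_path, sample_map, population: str) -> HaplotypePanel:
    """Load the phased haplotypes of one population from a VCF.

    Only biallelic SNV/indel records are retained (others are skipped and
    counted); variant columns containing any missing genotype are dropped.
    An unphased genotype in a retained record is an error.

    Parameters
    ----------
    vcf_path : path to a VCF 4.x file with GT fields.
    sample_map : path to a sample->population TSV, or an in-memory dict.
    population : population label to extract.
    """
    if not isinstance(sample_map, dict):
        sample_map = read_sample_map(sample_map)
    wanted = [s for s, p in sample_map.items() if p == population]
    if not wanted:
        raise InputError(f"population {population!r} absent from sample map")

    vcf = VCF(str(vcf_path), samples=wanted, gts012=False)
    found = list(vcf.samples)
    missing_samples = set(wanted) - set(found)
    if missing_samples:
        raise InputError(
            f"samples {sorted(missing_samples)} of population {population!r} "
            f"absent from VCF {vcf_path}"
        )

    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    n_skipped_multi = 0
    n_dropped_missing = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped_multi += 1
            continue
        gts = np.array(rec.genotypes)  # (n_samples, 3): a0, a1, phased
        alleles = gts[:, :2]
        if (alleles < 0).any():
            n_dropped_missing += 1
            continue
        if not gts[:, 2].all():
            raise InputError(
                f"unphased genotype at {rec.CHROM}:{rec.POS} ({rec.ID or '.'})"
            )
        vid = rec.ID if rec.ID not in (None, ".") else \
            f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        variants.append(Variant(vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        columns.append(alleles.reshape(-1).astype(np.int8))
    vcf.close()

    if n_skipped_multi:
        log.info("skipped %d non-biallelic records", n_skipped_multi)
    if n_dropped_missing:
        log.info("dropped %d variants with missing genotypes", n_dropped_missing)
    if not variants:
        raise InputError(f"no variants retained from {vcf_path}")

    order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos))
    variants = [variants[i] for i in order]
    matrix = np.stack([columns[i] for i in order], axis=1)
    return HaplotypePanel(population=population, variants=variants,
                          haplotypes=matrix, samples=found)


def write_vcf_panel(panel: HaplotypePanel, path) -> None:
    """Write a panel as a minimal phased VCF 4.2 (round-trips through the reader)."""
    samples = panel.samples or [f"{panel.population}_S{i}"
                                for i in range(panel.n_haplotypes // 2)]
    chroms = sorted({v.chrom for v in panel.variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        H = panel.haplotypes
        for j, v in enumerate(panel.variants):
            gts = "\t".join(f"{H[2 * i, j]}|{H[2 * i + 1, j]}"
                            for i in range(len(samples)))
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_score_track(path, measure_name: str, tail: str = "upper",
                     provenance: str = "ingested") -> ScoreTrack:
    """Read a per-variant score track.

    Accepts a 3-column TSV (chrom, pos, value; pos 1-based) or a 4-column
    bedGraph (chrom, start, end, value; 0-based half-open intervals expanded
    to per-position 1-based values). A duplicate position with a conflicting
    value is an error.
    """
    values: dict[tuple[str, int], float] = {}

    def put(chrom: str, pos: int, val: float) -> None:
        key = (chrom, pos)
        if key in values and values[key] != val:
            raise InputError(
                f"conflicting values for {chrom}:{pos} in {path}: "
                f"{values[key]} vs {val}"
            )
        values[key] = val

    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 3:
                chrom, pos, val = parts
                put(chrom, int(pos), float(val))
            elif len(parts) == 4:
                chrom, start, end, val = parts
                for pos in range(int(start) + 1, int(end) + 1):
                    put(chrom, pos, float(val))
            else:
                raise InputError(
                    f"{path}:{line_no}: expected 3 (TSV) or 4 (bedGraph) "
                    f"columns, got {len(parts)}"
                )
    return ScoreTrack(measure_name=measure_name, values=values,
                      tail=tail, provenance=provenance)


def write_score_track(track: ScoreTrack, path) -> None:
    """Write a track as 3-column TSV sorted by (chrom, pos)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tvalue\n")
        for (chrom, pos), val in sorted(track.values.items()):
            fh.write(f"{chrom}\t{pos}\t{val:.10g}\n")


def read_gwas(path) -> list[GwasRecord]:
    """Read GWAS summary statistics TSV: variant_id, chrom, pos, p."""
    df = pd.read_csv(path, sep="\t", comment=None)
    expected = {"variant_id", "chrom", "pos", "p"}
    if not expected.issubset(df.columns):
        raise InputError(f"GWAS TSV {path} must have columns {sorted(expected)}")
    return [GwasRecord(str(r.variant_id), str(r.chrom), int(r.pos), float(r.p))
            for r in df.itertuples()]


def write_gwas(records: list[GwasRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tchrom\tpos\tp\n")
        for r in records:
            fh.write(f"{r.variant_id}\t{r.chrom}\t{r.pos}\t{r.p_value:.6g}\n")


def read_genes_bed(path) -> list[tuple[str, int, int]]:
    """Read gene intervals from BED (0-based half-open) as 1-based inclusive."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            genes.append((chrom, start + 1, end))
    if not genes:
        raise InputError(f"no gene intervals in {path}")
    return genes


def write_regions(regions: list[TraitRegion], gwas_p: dict[str, float], path) -> None:
    """Write clumped regions TSV: region_id, member_id, r2_to_lead, p."""
    with open(path, "w") as fh:
        fh.write("region_id\tmember_id\tr2_to_lead\tp\n")
        for reg in regions:
            for m in reg.members:
                p = gwas_p.get(m.id, float("nan"))
                fh.write(f"{reg.region_id}\t{m.id}\t"
                         f"{reg.r2_to_lead[m.id]:.6f}\t{p:.6g}\n")


def write_results_tsv(results, path) -> None:
    """Write RegionMeasureResult rows: identical schema for trait and random regions."""
    def fmt(x, spec=".6g"):
        return "NA" if x is None else format(x, spec)

    with open(path, "w") as fh:
        fh.write("region_id\tmeasure\tobserved_median\tn_used\tn_marked\tp\tz\tremoved\n")
        for r in results:
            fh.write(f"{r.region_id}\t{r.measure_name}\t{fmt(r.observed_median)}\t"
                     f"{r.n_controls_used}\t{r.n_controls_marked}\t"
                     f"{fmt(r.empirical_p)}\t{fmt(r.z)}\t{int(r.removed)}\n")


def write_run_metadata(path, **fields) -> None:
    """Write run metadata JSON (seed, parameters, versions)."""
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
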