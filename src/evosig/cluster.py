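"""Clustering of region z-signatures and set-level enrichment tests.

Regions are clustered on their z-score vectors (hierarchical agglomerative,
Euclidean distance, complete linkage, dendrogram cut at a fixed height).
Set-level enrichment compares the number of trait regions in the top 5th
percentile of a genome-wide random-region distribution (with a
Binomial(n, 0.05) analytic null) and, separately, the number of regions
significant against their own matched nulls versus random region sets
evaluated the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import binom

from .core import InputError, RegionMeasureResult

log = logging.getLogger(__name__)


@dataclass
class ZMatrix:
    """Regions x measures z-scores with an imputation mask.

    Missing entries are imputed as 0 for clustering geometry only; the mask
    records where imputation happened and those cells never count as
    extreme.
    """

    values: pd.DataFrame          # rows: region ids; columns: measures
    imputation_mask: pd.DataFrame  # bool, True where imputed

    @property
    def region_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def measures(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class EnrichmentReport:
    """Observed vs null significant-region counts for one measure."""

    measure: str
    observed_count: float
    null_mean: float
    null_q05: float
    null_q95: float
    binomial_expected: float
    binomial_p: float
    significant: bool = False
    count_q05: float = 0.0   # spread of the observed count over iterations
    count_q95: float = 0.0

    def __post_init__(self) -> None:
        if not (self.null_q05 <= self.null_mean <= self.null_q95):
            raise InputError("null quantiles inconsistent with mean")


def build_z_matrix(results: list[RegionMeasureResult],
                   max_missing_fraction: float = 0.5) -> ZMatrix:
    """Pivot results into a z-matrix, dropping sparse measures.

    Measures missing (no z) in more than ``max_missing_fraction`` of regions
    are dropped and logged; remaining missing cells are imputed 0 with the
    mask set. All measures dropped is an error.
    """
    df = pd.DataFrame([(r.region_id, r.measure_name, r.z) for r in results],
                      columns=["region", "measure", "z"])
    wide = df.pivot(index="region", columns="measure", values="z")
    wide = wide.loc[sorted(wide.index), sorted(wide.columns)]
    keep = []
    for m in wide.columns:
        frac_missing = wide[m].isna().mean()
        if frac_missing > max_missing_fraction:
            log.info("dropping measure %s: missing in %.0f%% of regions",
                     m, 100 * frac_missing)
        else:
            keep.append(m)
    if not keep:
        raise InputError("all measures dropped for missingness")
    wide = wide[keep]
    mask = wide.isna()
    return ZMatrix(values=wide.fillna(0.0), imputation_mask=mask)


def extreme_regions(zm: ZMatrix, threshold: float = 1.5) -> list[str]:
    """Regions whose max |z| over unimputed entries reaches the threshold."""
    absz = zm.values.abs().where(~zm.imputation_mask, other=-np.inf)
    return [rid for rid in zm.region_ids
            if float(absz.loc[rid].max()) >= threshold]


def cluster_regions(zm: ZMatrix, cut_height: float = 7.0,
                    method: str = "complete",
                    metric: str = "euclidean") -> dict[str, int]:
    """Hierarchical clustering of region z-vectors cut at a fixed height.

    Labels are renumbered by first region occurrence (row order of the
    z-matrix), so the partition is deterministic and invariant — up to
    label names — under row permutation.
    """
    ids = zm.region_ids
    if len(ids) == 1:
        return {ids[0]: 1}
    Z = linkage(zm.values.to_numpy(), method=method, metric=metric)
    raw = fcluster(Z, t=cut_height, criterion="distance")
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for rid, lab in zip(ids, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        out[rid] = relabel[lab]
    return out


def genomewide_enrichment(trait_medians: dict[str, float],
                          random_pool: np.ndarray,
                          n_random: int = 5000,
                          n_iter: int = 1000,
                          seed: int = 0,
                          measure: str = "") -> EnrichmentReport:
    """Enrichment of trait regions in the top 5th percentile genome-wide.

    Per iteration, ``n_random`` random-region medians are drawn from the
    pool, their 95th percentile taken as the genome-wide cutoff, and the
    trait regions at or above it counted. The analytic null is
    Binomial(#trait regions, 0.05): expected count 0.05 x n, with
    binomial_p = P(X >= round(mean observed count)).
    """
    pool = np.asarray(random_pool, dtype=float)
    if pool.shape[0] < n_random:
        raise InputError(
            f"random pool of {pool.shape[0]} medians < n_random={n_random}")
    obs = np.array([v for v in trait_medians.values() if v is not None])
    n_regions = obs.shape[0]
    rng = np.random.default_rng(seed)
    counts = np.empty(n_iter)
    for it in range(n_iter):
        sample = rng.choice(pool, size=n_random, replace=False)
        cutoff = np.percentile(sample, 95)
        counts[it] = (obs >= cutoff).sum()
    mean_count = float(counts.mean())
    expected = 0.05 * n_regions
    p = float(binom.sf(round(mean_count) - 1, n_regions, 0.05))
    return EnrichmentReport(
        measure=measure,
        observed_count=mean_count,
        null_mean=expected,
        null_q05=float(binom.ppf(0.05, n_regions, 0.05)),
        null_q95=float(binom.ppf(0.95, n_regions, 0.05)),
        binomial_expected=expected,
        binomial_p=p,
        significant=p < 0.05,
        count_q05=float(np.percentile(counts, 5)),
        count_q95=float(np.percentile(counts, 95)),
    )


def binomial_expected_count(n_regions: int, rate: float = 0.05) -> float:
    """Analytic expectation of significant regions under the binomial null."""
    return rate * n_regions


def matched_enrichment(trait_pvalues: dict[str, float | None],
                       null_set_sampler,
                       n_iter: int = 1000,
                       alpha: float = 0.05,
                       seed: int = 0,
                       measure: str = "") -> EnrichmentReport:
    """Enrichment of matched-null-significant regions over random region sets.

    ``null_set_sampler(iteration, rng)`` must return the empirical p-values
    of one random region set of the same size, each region evaluated against
    its own matched controls. Enrichment is flagged when the observed count
    exceeds the null 95th percentile.
    """
    observed = sum(1 for p in trait_pvalues.values()
                   if p is not None and p < alpha)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_iter)
    for it in range(n_iter):
        ps = null_set_sampler(it, rng)
        counts[it] = sum(1 for p in ps if p is not None and p < alpha)
    n_regions = len(trait_pvalues)
    q95 = float(np.percentile(counts, 95))
    return EnrichmentReport(
        measure=measure,
        observed_count=float(observed),
        null_mean=float(counts.mean()),
        null_q05=float(np.percentile(counts, 5)),
        null_q95=q95,
        binomial_expected=alpha * n_regions,
        binomial_p=float(binom.sf(observed - 1, n_regions, alpha)),
        significant=observed > q95,
    )


def write_clusters(labels: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\tcluster\n")
        for rid in labels:
            fh.write(f"{rid}\t{labels[rid]}\n")


def write_enrichment(reports: list[EnrichmentReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("measure\tobserved_count\tnull_mean\tnull_q05\tnull_q95\t"
                 "binomial_expected\tbinomial_p\tsignificant\n")
        for r in reports:
            fh.write(f"{r.measure}\t{r.observed_count:.6g}\t{r.null_mean:.6g}\t"
                     f"{r.null_q05:.6g}\t{r.null_q95:.6g}\t"
                     f"{r.binomial_expected:.6g}\t{r.binomial_p:.6g}\t"
                     f"{int(r.significant)}\n")
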