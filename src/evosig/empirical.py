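"""Region-level empirical p-values and z-scores against the matched null.

The observed statistic for a region x measure is the median measure value
over the region's members; the null is the distribution of the same median
over the region's matched control regions. A control region that matched
fewer than 90% of the required variants is marked; when at least 60% of a
region's controls are marked, that region x measure is removed. Empirical
p-values follow the count rule (#controls with median >= observed, divided
by the controls used) with the two-sided variant doubling the smaller tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (InputError, RegionMeasureResult, ScoreTrack, TraitRegion,
                   is_missing)
from .matching import ControlSuite

log = logging.getLogger(__name__)

MATCH_FRACTION_MIN = 0.90   # control marked iff match_fraction < this
MARKED_REMOVAL_FRACTION = 0.60  # region removed iff marked fraction >= this
MIN_CONTROLS = 100          # below this the empirical p is missing


@dataclass
class NullDistribution:
    """Control-region medians for one region x measure."""

    region_id: str
    measure_name: str
    control_medians: np.ndarray
    n_marked: int
    n_used: int
    removed: bool

    def __post_init__(self) -> None:
        self.control_medians = np.asarray(self.control_medians, dtype=float)
        if self.n_used != self.control_medians.shape[0]:
            raise InputError("n_used inconsistent with control medians")


def region_median(values) -> float | None:
    """Median of the non-missing values; all-missing yields missing.

    Even counts take the mean of the two central values (numpy convention).
    """
    vals = [v for v in values if not is_missing(v)]
    if not vals:
        return None
    return float(np.median(vals))


def build_null(suite: ControlSuite, track: ScoreTrack,
               variant_index: dict[str, tuple[str, int]],
               measure_name: str | None = None) -> NullDistribution:
    """Assemble the matched null for one region x measure.

    Controls with match_fraction < 0.90 are marked and excluded from the
    null; unmarked controls whose members carry no track value at all are
    also excluded (logged) since they yield no median. The region x measure
    is flagged removed when the marked fraction reaches 0.60.
    """
    if not suite.control_regions:
        raise InputError(f"empty control suite for region {suite.region_id}")
    medians = []
    n_marked = 0
    n_no_data = 0
    for cr in suite.control_regions:
        if cr.match_fraction < MATCH_FRACTION_MIN:
            n_marked += 1
            continue
        vals = [track.lookup(*variant_index[mid]) for mid in cr.member_ids
                if mid in variant_index]
        med = region_median(vals)
        if med is None:
            n_no_data += 1
            continue
        medians.append(med)
    if n_no_data:
        log.info("region %s, measure %s: %d unmarked controls with no data",
                 suite.region_id, track.measure_name, n_no_data)
    removed = n_marked / len(suite.control_regions) >= MARKED_REMOVAL_FRACTION
    return NullDistribution(
        region_id=suite.region_id,
        measure_name=measure_name or track.measure_name,
        control_medians=np.array(medians, dtype=float),
        n_marked=n_marked,
        n_used=len(medians),
        removed=removed,
    )


def empirical_p(observed: float, null: NullDistribution, tail: str) -> float | None:
    """Count-rule empirical p against the matched null.

    upper: p = #{control medians >= observed} / n_used.
    two_sided: p = min(1, 2 * min(#{>=}, #{<=}) / n_used).
    p = 0 is reported as-is (no pseudocount); n_used is recorded so callers
    can floor at 1/n_used. Missing (logged) when n_used < 100.
    """
    if null.removed:
        raise InputError(
            f"region {null.region_id} x {null.measure_name} was removed")
    if null.n_used < MIN_CONTROLS:
        log.info("region %s x %s: only %d controls, p missing",
                 null.region_id, null.measure_name, null.n_used)
        return None
    ge = int((null.control_medians >= observed).sum())
    if tail == "upper":
        return ge / null.n_used
    le = int((null.control_medians <= observed).sum())
    return min(1.0, 2.0 * min(ge, le) / null.n_used)


def z_score(observed: float, null: NullDistribution) -> float | None:
    """(observed − mean) / sd of the control medians, sd with n−1 denominator."""
    if null.n_used < 2:
        return None
    sd = float(null.control_medians.std(ddof=1))
    if sd == 0.0:
        log.info("region %s x %s: zero control sd, z missing",
                 null.region_id, null.measure_name)
        return None
    return float((observed - null.control_medians.mean()) / sd)


def evaluate_region(region: TraitRegion, suite: ControlSuite,
                    track: ScoreTrack, tail: str,
                    variant_index: dict[str, tuple[str, int]]) -> RegionMeasureResult:
    """One region x measure: observed median, null, p, z, removal flag."""
    from .measures import lookup_track_values

    observed = region_median(lookup_track_values(track, region))
    if not suite.control_regions:
        # no matched controls could be found at all: no null to compare to
        log.info("region %s x %s: empty control suite, removed",
                 region.region_id, track.measure_name)
        return RegionMeasureResult(
            region_id=region.region_id, measure_name=track.measure_name,
            observed_median=observed, n_controls_used=0, n_controls_marked=0,
            empirical_p=None, z=None, removed=True)
    null = build_null(suite, track, variant_index)
    if null.removed or observed is None:
        return RegionMeasureResult(
            region_id=region.region_id, measure_name=track.measure_name,
            observed_median=observed, n_controls_used=null.n_used,
            n_controls_marked=null.n_marked, empirical_p=None, z=None,
            removed=null.removed)
    return RegionMeasureResult(
        region_id=region.region_id, measure_name=track.measure_name,
        observed_median=observed, n_controls_used=null.n_used,
        n_controls_marked=null.n_marked,
        empirical_p=empirical_p(observed, null, tail),
        z=z_score(observed, null),
        removed=False)


def evaluate_all(regions: list[TraitRegion],
                 suites: dict[str, ControlSuite],
                 tracks: dict[str, ScoreTrack],
                 registry: dict[str, dict],
                 variant_index: dict[str, tuple[str, int]]) -> list[RegionMeasureResult]:
    """Evaluate every region against every measure; one result per pair.

    Deterministic given inputs; a region without a control suite is an
    error. Measure tails come from the registry (falling back to the
    track's own declaration).
    """
    results = []
    for region in regions:
        suite = suites.get(region.region_id)
        if suite is None:
            raise InputError(f"region {region.region_id} has no control suite")
        for name in sorted(tracks):
            track = tracks[name]
            tail = registry.get(name, {}).get("tail", track.tail)
            results.append(evaluate_region(region, suite, track, tail,
                                           variant_index))
    return results
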