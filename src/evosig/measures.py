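"""Per-variant evolutionary measures computed from haplotype panels.

Computed here: Weir–Cockerham F_ST (two-population variance-component
estimator), the extended-haplotype-homozygosity family (EHH curves, iHH,
iHS, iES, XP-EHH), the Beta score of balancing selection, and alignment
block age on a dated species tree. Measures that the pipeline only ingests
(PhyloP, PhastCons, GERP, LINSIGHT, TMRCA) enter as ScoreTracks through
``evosig.io.read_score_track`` and are indistinguishable downstream.

EHH distances are physical bp (no genetic map); the EHH definition is the
probability that two randomly drawn carrier haplotypes are identical over
the interval from the core site to the offset, computed marker-by-marker
outward in each direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import yaml

from .core import HaplotypePanel, InputError, ScoreTrack, TraitRegion

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST

def weir_cockerham_fst(n1: float, p1: float, h1: float,
                       n2: float, p2: float, h2: float) -> float | None:
    """Two-population Weir–Cockerham θ̂ for one site.

    Parameters are per population: diploid sample size ``n``, alt-allele
    frequency ``p``, observed heterozygote frequency ``h``. Returns the
    ratio of variance components a/(a+b+c), or ``None`` when the site is
    monomorphic overall (a+b+c = 0). Symmetric in the two populations and
    invariant under simultaneous ref/alt relabelling.
    """
    if min(n1, n2) < 2:
        raise InputError("Weir-Cockerham estimator requires n >= 2 per population")
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1.0)) * (p_bar * (1.0 - p_bar)
                                      - s2 * (r - 1.0) / r
                                      - h_bar / 4.0))
    b = (n_bar / (n_bar - 1.0)) * (p_bar * (1.0 - p_bar)
                                   - s2 * (r - 1.0) / r
                                   - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar))
    c = h_bar / 2.0
    denom = a + b + c
    if denom == 0.0:
        return None
    return a / denom


def _site_stats(panel: HaplotypePanel, i: int) -> tuple[float, float, float]:
    """(n_diploids, alt freq, observed het frequency) for column i."""
    col = panel.haplotypes[:, i]
    a0 = col[0::2]
    a1 = col[1::2]
    n = a0.shape[0]
    p = float(col.mean())
    h = float((a0 != a1).mean())
    return float(n), p, h


def fst_track(panel_a: HaplotypePanel, panel_b: HaplotypePanel,
              measure_name: str | None = None) -> ScoreTrack:
    """Per-variant Weir–Cockerham θ̂ between two panels sharing variants."""
    name = measure_name or f"fst_{panel_a.population}_{panel_b.population}"
    ids_b = {v.id: k for k, v in enumerate(panel_b.variants)}
    values: dict[tuple[str, int], float] = {}
    for i, v in enumerate(panel_a.variants):
        j = ids_b.get(v.id)
        if j is None:
            continue
        n1, p1, h1 = _site_stats(panel_a, i)
        n2, p2, h2 = _site_stats(panel_b, j)
        theta = weir_cockerham_fst(n1, p1, h1, n2, p2, h2)
        if theta is not None:
            values[(v.chrom, v.pos)] = theta
    return ScoreTrack(measure_name=name, values=values,
                      tail="upper", provenance="computed")


# ---------------------------------------------------------------------------
# EHH family

@dataclass
class EhhCurve:
    """EHH values at signed bp offsets from a core site (offset 0 value 1)."""

    core_id: str
    allele_class: str  # "ancestral", "derived", "0", "1", or "all"
    offsets: np.ndarray  # sorted ascending, includes 0
    ehh_values: np.ndarray

    def side(self, sign: int) -> tuple[np.ndarray, np.ndarray]:
        """(|offsets|, values) walking outward on one side, starting at 0."""
        if sign > 0:
            mask = self.offsets >= 0
            off = self.offsets[mask]
            val = self.ehh_values[mask]
        else:
            mask = self.offsets <= 0
            off = -self.offsets[mask][::-1]
            val = self.ehh_values[mask][::-1]
        return off, val


def _side_ehh_values(H: np.ndarray, carriers: np.ndarray,
                     cols: np.ndarray) -> np.ndarray:
    """EHH after extending through cols[0..k] for k = 0..len(cols)-1.

    Equivalent to refining the carrier partition marker by marker, but
    computed in one pass: rows are sorted lexicographically over the
    extension columns, the first-mismatch depth of each adjacent sorted
    pair is found, and run sizes are accumulated by merging in decreasing
    depth order (each adjacent pair joins exactly once).
    """
    n = carriers.size
    L = cols.size
    if L == 0:
        return np.empty(0)
    B = np.ascontiguousarray(H[np.ix_(carriers, cols)])
    view = B.view([("", B.dtype)] * L).ravel()
    order = np.argsort(view, kind="stable")
    S = B[order]
    neq = S[1:] != S[:-1]
    any_neq = neq.any(axis=1)
    depth = np.where(any_neq, neq.argmax(axis=1), L)  # leading agreement length

    parent = np.arange(n)
    size = np.ones(n, dtype=np.int64)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    total_pairs = n * (n - 1) // 2
    by_depth: dict[int, list[int]] = {}
    for j, dj in enumerate(depth):
        by_depth.setdefault(int(dj), []).append(j)

    ehh = np.empty(L)
    pairsum = 0
    for level in range(L, 0, -1):
        for j in by_depth.get(level, []):
            a, b = find(j), find(j + 1)
            if a != b:
                pairsum += size[a] * size[b]
                parent[b] = a
                size[a] += size[b]
        ehh[level - 1] = pairsum / total_pairs
    return ehh


def ehh_curve(panel: HaplotypePanel, core: int, allele,
              truncate_at: float | None = None) -> EhhCurve:
    """EHH decay outward from ``core`` for carriers of ``allele``.

    ``allele`` is 0, 1, or ``"all"`` (the site-specific EHHS over every
    haplotype used for iES). At offset x the value is
    Σ_h C(n_h, 2) / C(n, 2) over distinct haplotypes h extended from the
    core to x, computed marker-by-marker outward in both directions. When
    ``truncate_at`` is given, the stored curve stops at the first marker
    whose value falls below it (the curve is weakly decreasing, so nothing
    past that point contributes to a cutoff integral at or above the same
    level).
    """
    H = panel.haplotypes
    if allele == "all":
        carriers = np.arange(H.shape[0])
    else:
        carriers = np.flatnonzero(H[:, core] == int(allele))
    if carriers.size < 2:
        raise InputError(
            f"core column {core}: fewer than 2 carriers of allele {allele!r}")
    chrom = panel.variants[core].chrom
    positions = panel.positions
    chroms = panel.chroms
    core_pos = positions[core]

    offsets = [0]
    values = [1.0]
    for step in (1, -1):
        if step > 0:
            cols = np.arange(core + 1, panel.n_variants)
        else:
            cols = np.arange(core - 1, -1, -1)
        cols = cols[chroms[cols] == chrom]
        # grow the extension window geometrically: most curves hit the
        # cutoff within a few dozen markers
        L = min(64, cols.size)
        while True:
            vals = _side_ehh_values(H, carriers, cols[:L])
            below = np.flatnonzero(vals < truncate_at) if truncate_at \
                is not None else np.flatnonzero(vals == 0.0)
            if below.size or L == cols.size:
                break
            L = min(cols.size, L * 4)
        stop = vals.shape[0]
        if below.size:
            stop = int(below[0]) + 1
        for k in range(stop):
            offsets.append(int(positions[cols[k]] - core_pos))
            values.append(float(vals[k]))
    order = np.argsort(offsets, kind="stable")
    return EhhCurve(core_id=panel.variants[core].id,
                    allele_class=str(allele),
                    offsets=np.asarray(offsets)[order],
                    ehh_values=np.asarray(values, dtype=float)[order])


def integrate_ehh(curve: EhhCurve, cutoff: float = 0.05) -> float:
    """iHH: trapezoidal area of the EHH curve over bp, per side.

    Each side accumulates consecutive-trapezoid areas while both segment
    endpoints are >= ``cutoff``, stopping at the first endpoint below it;
    the total is the sum of the two sides.
    """
    total = 0.0
    for sign in (+1, -1):
        off, val = curve.side(sign)
        for k in range(1, off.shape[0]):
            if val[k - 1] < cutoff or val[k] < cutoff:
                break
            total += 0.5 * (val[k - 1] + val[k]) * (off[k] - off[k - 1])
    return total


def ihs_scores(panel: HaplotypePanel, ancestral_alleles: dict[str, int],
               bin_width: float = 0.025, cutoff: float = 0.05,
               min_bin: int = 10) -> dict[str, float | None]:
    """Standardised iHS per variant.

    Unstandardised iHS = ln(iHH_ancestral / iHH_derived); standardised
    within derived-allele-frequency bins of width ``bin_width`` (subtract
    bin mean, divide by bin sd). Bins holding fewer than ``min_bin``
    variants yield missing, as do variants with zero iHH on either allele
    or with unknown ancestral allele.
    """
    raw: dict[str, float] = {}
    dfreq: dict[str, float] = {}
    out: dict[str, float | None] = {}
    for i, v in enumerate(panel.variants):
        anc = ancestral_alleles.get(v.id)
        if anc not in (0, 1):
            out[v.id] = None
            continue
        der = 1 - anc
        p_der = float((panel.haplotypes[:, i] == der).mean())
        if not (0.0 < p_der < 1.0):
            out[v.id] = None
            continue
        n_anc = panel.n_haplotypes - round(p_der * panel.n_haplotypes)
        if min(n_anc, panel.n_haplotypes - n_anc) < 2:
            out[v.id] = None
            continue
        ihh_a = integrate_ehh(ehh_curve(panel, i, anc, truncate_at=cutoff), cutoff)
        ihh_d = integrate_ehh(ehh_curve(panel, i, der, truncate_at=cutoff), cutoff)
        if ihh_a == 0.0 or ihh_d == 0.0:
            log.info("iHS missing for %s: zero iHH", v.id)
            out[v.id] = None
            continue
        raw[v.id] = math.log(ihh_a / ihh_d)
        dfreq[v.id] = p_der

    bins: dict[int, list[str]] = {}
    for vid, f in dfreq.items():
        bins.setdefault(int(f / bin_width), []).append(vid)
    for b, vids in bins.items():
        if len(vids) < min_bin:
            for vid in vids:
                out[vid] = None
            continue
        vals = np.array([raw[vid] for vid in vids])
        mu = vals.mean()
        sd = vals.std(ddof=1)
        for vid in vids:
            out[vid] = None if sd == 0.0 else float((raw[vid] - mu) / sd)
    return out


def ies_value(panel: HaplotypePanel, core: int, cutoff: float = 0.05) -> float:
    """Integrated site-specific EHH over all haplotypes (Tang-style iES)."""
    return integrate_ehh(ehh_curve(panel, core, "all", truncate_at=cutoff), cutoff)


def xpehh_scores(panel_a: HaplotypePanel, panel_b: HaplotypePanel,
                 cutoff: float = 0.05) -> dict[str, float | None]:
    """Standardised XP-EHH (A vs B) per shared polymorphic variant.

    raw = ln(iES_A / iES_B); standardised over all scored variants. Positive
    values mean longer haplotype homozygosity in population A.
    """
    ids_b = {v.id: k for k, v in enumerate(panel_b.variants)}
    raw: dict[str, float] = {}
    out: dict[str, float | None] = {}
    for i, v in enumerate(panel_a.variants):
        j = ids_b.get(v.id)
        if j is None:
            continue
        if not (panel_a.is_polymorphic(i) and panel_b.is_polymorphic(j)):
            out[v.id] = None
            continue
        ies_a = ies_value(panel_a, i, cutoff)
        ies_b = ies_value(panel_b, j, cutoff)
        if ies_b == 0.0 or ies_a == 0.0:
            out[v.id] = None
            continue
        raw[v.id] = math.log(ies_a / ies_b)
    if raw:
        vals = np.array(list(raw.values()))
        mu = vals.mean()
        sd = vals.std(ddof=1) if vals.size > 1 else 0.0
        for vid, r in raw.items():
            out[vid] = float((r - mu) / sd) if sd > 0.0 else None
    return out


# ---------------------------------------------------------------------------
# Beta score (balancing selection)

def _beta_weight(f_i: float, f_c: float) -> float:
    """Similarity weight between folded frequencies; 1 at f_i == f_c."""
    return 1.0 - abs(f_i - f_c) / 0.5


def beta_score(core_folded_freq: float,
               window_freqs: list[float],
               n: int) -> float:
    """β(1) for one core variant from folded frequencies in its window.

    θ̂_β = Σ_i w_i / E_w where w_i = 1 − |f_i − f_c|/0.5 and
    E_w = Σ_{k=1}^{n−1} (1/k) · w(fold(k/n), f_c) is the neutral expectation
    of summed weight per unit θ; θ̂_W = S / Σ_{k=1}^{n−1} 1/k with S the
    window SNP count; β = θ̂_β − θ̂_W. An empty window yields 0.
    """
    f_c = core_folded_freq
    if not (0.0 < f_c <= 0.5):
        raise InputError(f"core folded frequency must be in (0,0.5], got {f_c}")
    if not window_freqs:
        return 0.0
    for f in window_freqs:
        if not (0.0 < f <= 0.5):
            raise InputError(f"window folded frequency out of (0,0.5]: {f}")
    e_w = sum((1.0 / k) * _beta_weight(min(k / n, 1.0 - k / n), f_c)
              for k in range(1, n))
    a_n = sum(1.0 / k for k in range(1, n))
    theta_beta = sum(_beta_weight(f, f_c) for f in window_freqs) / e_w
    theta_w = len(window_freqs) / a_n
    return theta_beta - theta_w


def beta_track(panel: HaplotypePanel, window_bp: int = 1000,
               measure_name: str = "beta") -> ScoreTrack:
    """β(1) per polymorphic variant; window is ±window_bp/2 around the core."""
    positions = panel.positions
    chroms = panel.chroms
    folded = np.array([panel.maf(i) for i in range(panel.n_variants)])
    poly = folded > 0.0
    half = window_bp / 2.0
    values: dict[tuple[str, int], float] = {}
    for i, v in enumerate(panel.variants):
        if not poly[i]:
            continue
        in_win = np.flatnonzero(
            (chroms == v.chrom) & (np.abs(positions - v.pos) <= half) & poly)
        in_win = in_win[in_win != i]
        values[(v.chrom, v.pos)] = beta_score(
            float(folded[i]), [float(folded[j]) for j in in_win],
            panel.n_haplotypes)
    return ScoreTrack(measure_name=measure_name, values=values,
                      tail="upper", provenance="computed")


# ---------------------------------------------------------------------------
# Alignment block age

class DatedTree:
    """Time-calibrated species tree (newick, branch lengths in Myr).

    The tree must be ultrametric to within ``tol`` so node ages are
    well-defined, and tip labels must be unique.
    """

    def __init__(self, tree: dendropy.Tree, tol: float = 1e-6):
        self.tree = tree
        tree.is_rooted = True
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise InputError("duplicate tip labels in dated tree")
        self.tip_labels = set(labels)
        tree.calc_node_ages(ultrametricity_precision=tol)
        # leaf-label set per node, for direct MRCA lookup
        self._leafsets: list[tuple[frozenset, float]] = []
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                nd._leafset = frozenset([nd.taxon.label])
            else:
                s = frozenset().union(*(ch._leafset for ch in nd.child_nodes()))
                nd._leafset = s
            self._leafsets.append((nd._leafset, float(nd.age)))

    @classmethod
    def from_newick(cls, newick: str, tol: float = 1e-6) -> "DatedTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree, tol=tol)

    @classmethod
    def from_file(cls, path, tol: float = 1e-6) -> "DatedTree":
        return cls.from_newick(Path(path).read_text())

    def mrca_age(self, species: set[str]) -> float:
        missing = species - self.tip_labels
        if missing:
            raise InputError(f"species not in tree: {sorted(missing)}")
        if len(species) == 1:
            return 0.0
        best = None
        for leafset, age in self._leafsets:
            if species <= leafset and (best is None or age < best):
                best = age
        return float(best)


def alignment_block_age(block_species: set[str], tree: DatedTree,
                        focal: str) -> float:
    """Age (Myr) of the MRCA of the species present in an alignment block.

    The focal species must itself be in the block; a block containing only
    the focal species has age 0.
    """
    if focal not in tree.tip_labels:
        raise InputError(f"species not in tree: ['{focal}']")
    if focal not in block_species:
        raise InputError(f"focal species {focal!r} absent from block")
    return tree.mrca_age(set(block_species))


# ---------------------------------------------------------------------------
# Track plumbing and the measure registry

def lookup_track_values(track: ScoreTrack, region: TraitRegion) -> list[float | None]:
    """Per-member values in region member order, missing preserved."""
    return [track.lookup(v.chrom, v.pos) for v in region.members]


#: tail convention and handling per measure; |iHS| enters as a magnitude
DEFAULT_REGISTRY: dict[str, dict] = {
    "fst": {"tail": "upper", "provenance": "computed"},
    "ihs": {"tail": "upper", "provenance": "computed", "magnitude": True},
    "xpehh": {"tail": "upper", "provenance": "computed"},
    "ies": {"tail": "upper", "provenance": "computed"},
    "beta": {"tail": "upper", "provenance": "computed"},
    "alignment_block_age": {"tail": "two_sided", "provenance": "computed"},
    "phastcons": {"tail": "upper", "provenance": "ingested"},
    "gerp": {"tail": "upper", "provenance": "ingested"},
    "linsight": {"tail": "upper", "provenance": "ingested"},
    "phylop": {"tail": "two_sided", "provenance": "ingested"},
    "tmrca": {"tail": "two_sided", "provenance": "ingested"},
}


def load_registry(path=None) -> dict[str, dict]:
    """Load the YAML measure registry; defaults ship with the package."""
    if path is None:
        path = Path(__file__).with_name("measures.yaml")
    with open(path) as fh:
        reg = yaml.safe_load(fh)
    for name, entry in reg.items():
        if entry.get("tail") not in ("upper", "two_sided"):
            raise InputError(f"registry entry {name}: bad tail {entry.get('tail')!r}")
    return reg


def apply_registry_transform(track: ScoreTrack, entry: dict) -> ScoreTrack:
    """Apply registry handling (currently: magnitude fold for |iHS|)."""
    if not entry.get("magnitude"):
        return track
    return ScoreTrack(
        measure_name=track.measure_name,
        values={k: abs(v) for k, v in track.values.items()},
        tail=entry.get("tail", track.tail),
        provenance=track.provenance,
    )
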