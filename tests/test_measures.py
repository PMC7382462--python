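import math

import numpy as np
import pytest

from evosig.core import InputError, ScoreTrack, TraitRegion, Variant
from evosig.measures import (DatedTree, EhhCurve, alignment_block_age,
                             beta_score, ehh_curve, fst_track, ies_value,
                             ihs_scores, integrate_ehh, lookup_track_values,
                             weir_cockerham_fst, xpehh_scores)

from conftest import make_panel


# --------------------------------------------------------------------------
# Weir-Cockerham FST

def anova_theta(n1, p1, h1, n2, p2, h2):
    """Independent oracle: ANOVA mean-squares derivation of θ̂.

    Decomposes allele-indicator variance over populations / individuals /
    gametes via sums of squares, a different route to the same estimator.
    """
    ns, ps, hs = [n1, n2], [p1, p2], [h1, h2]
    N = sum(ns)
    pbar = sum(n * p for n, p in zip(ns, ps)) / N
    ssg = 0.5 * sum(n * h for n, h in zip(ns, hs))
    ssi = 0.0
    for n, p, h in zip(ns, ps, hs):
        n_aa = n * (p - h / 2)
        n_het = n * h
        n_rr = n * (1 - p - h / 2)
        ssi += 2 * (n_aa * (1 - p) ** 2 + n_het * (0.5 - p) ** 2 + n_rr * p * p)
    ssp = 2 * sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps))
    msg = ssg / N
    msi = ssi / sum(n - 1 for n in ns)
    msp = ssp / 1.0
    nc = (N - sum(n * n for n in ns) / N) / 1.0
    s_g, s_i, s_p = msg, (msi - msg) / 2, (msp - msi) / (2 * nc)
    denom = s_p + s_i + s_g
    return None if denom == 0 else s_p / denom


class TestWeirCockerham:
    def test_fixed_difference(self):
        assert weir_cockerham_fst(50, 1.0, 0.0, 50, 0.0, 0.0) == pytest.approx(1.0)

    def test_monomorphic_missing(self):
        assert weir_cockerham_fst(10, 0.0, 0.0, 10, 0.0, 0.0) is None

    def test_hand_variance_component_value(self):
        got = weir_cockerham_fst(10, 0.8, 0.2, 10, 0.3, 0.4)
        assert got == pytest.approx(0.36379928315412197, abs=1e-14)
        assert got == pytest.approx(anova_theta(10, 0.8, 0.2, 10, 0.3, 0.4),
                                    abs=1e-14)

    def test_matches_anova_oracle_on_random_sites(self):
        """θ̂ equals the independently derived ANOVA estimator to 1e-12
        on 1000 random genotype configurations."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 1000:
            n1, n2 = rng.integers(5, 60, size=2)
            g1 = rng.multinomial(n1, [1 / 3] * 3)
            g2 = rng.multinomial(n2, [1 / 3] * 3)
            p1 = (2 * g1[0] + g1[1]) / (2 * n1)
            p2 = (2 * g2[0] + g2[1]) / (2 * n2)
            h1, h2 = g1[1] / n1, g2[1] / n2
            mine = weir_cockerham_fst(n1, p1, h1, n2, p2, h2)
            oracle = anova_theta(n1, p1, h1, n2, p2, h2)
            if mine is None:
                assert oracle is None or abs(oracle) < 1e-12
                continue
            assert mine == pytest.approx(oracle, abs=1e-12)
            checked += 1

    def test_population_swap_and_relabel_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n1, n2 = rng.integers(5, 40, size=2)
            p1, p2 = rng.uniform(0.05, 0.95, size=2)
            h1 = min(rng.uniform(0, 1), 2 * min(p1, 1 - p1))
            h2 = min(rng.uniform(0, 1), 2 * min(p2, 1 - p2))
            t = weir_cockerham_fst(n1, p1, h1, n2, p2, h2)
            assert t == pytest.approx(
                weir_cockerham_fst(n2, p2, h2, n1, p1, h1), abs=1e-12)
            assert t == pytest.approx(
                weir_cockerham_fst(n1, 1 - p1, h1, n2, 1 - p2, h2), abs=1e-12)

    def test_fst_track_elevated_at_differentiated_site(self):
        cols_a = [[1, 1, 1, 1, 0, 0, 0, 0], [1, 0, 1, 0, 1, 0, 1, 0]]
        cols_b = [[1, 1, 1, 1, 1, 1, 1, 0], [1, 0, 1, 0, 1, 0, 1, 0]]
        pa = make_panel(cols_a, population="A")
        pb = make_panel(cols_b, population="B")
        tr = fst_track(pa, pb)
        assert tr.lookup("chr1", 1000) > tr.lookup("chr1", 2000)


# --------------------------------------------------------------------------
# EHH family

def _ehh_example_panel():
    """Core at column 1 with 4 carriers whose right-extensions are
    {00, 00, 01, 10} over columns 2 and 3."""
    #          h0 h1 h2 h3 h4 h5 h6 h7   (carriers: h0-h3)
    core = [1, 1, 1, 1, 0, 0, 0, 0]
    m1 = [0, 0, 0, 1, 0, 0, 1, 1]   # right marker 1
    m2 = [0, 0, 1, 0, 1, 1, 0, 0]   # right marker 2
    left = [0, 0, 0, 0, 1, 1, 1, 1]
    return make_panel([left, core, m1, m2], spacing=1000)


class TestEhh:
    def test_offset_zero_is_one(self):
        panel = _ehh_example_panel()
        curve = ehh_curve(panel, 1, 1)
        assert curve.ehh_values[curve.offsets == 0][0] == 1.0

    def test_enumerated_extension_classes(self):
        """4 carriers with 2-marker extensions {00,00,01,10}:
        EHH = C(2,2)/C(4,2) = 1/6 at the second marker."""
        panel = _ehh_example_panel()
        curve = ehh_curve(panel, 1, 1)
        right = dict(zip(curve.offsets.tolist(), curve.ehh_values.tolist()))
        assert right[1000] == pytest.approx(3 / 6)   # classes {0:3, 1:1}
        assert right[2000] == pytest.approx(1 / 6)

    def test_identical_carriers_flat_curve(self):
        cols = [[1, 1, 0, 0, 1, 0]] * 4
        panel = make_panel([list(c) for c in cols], spacing=500)
        curve = ehh_curve(panel, 1, 1)
        assert np.all(curve.ehh_values == 1.0)

    def test_fewer_than_two_carriers_errors(self):
        panel = make_panel([[1, 0, 0, 0], [1, 1, 0, 0]])
        with pytest.raises(InputError, match="carriers"):
            ehh_curve(panel, 0, 1)

    def test_weakly_decreasing_outward(self, sim_panels):
        panels, _ = sim_panels
        panel = panels["POP1"]
        for core in (200, 700, 1200):
            if not panel.is_polymorphic(core):
                continue
            allele = 1 if (panel.haplotypes[:, core] == 1).sum() >= 2 else 0
            curve = ehh_curve(panel, core, allele)
            for sign in (+1, -1):
                _, val = curve.side(sign)
                assert np.all(np.diff(val) <= 1e-12)

    def test_curve_values_unchanged_by_noninformative_marker(self):
        """A marker where all carriers agree does not refine the partition:
        EHH at the shared offsets is identical with or without it."""
        core = [1, 1, 1, 1, 0, 0, 0, 0]
        m1 = [0, 0, 0, 1, 0, 1, 0, 1]
        noop = [0, 0, 0, 0, 1, 1, 0, 0]   # all carriers carry 0
        m2 = [0, 1, 0, 1, 1, 0, 0, 1]
        with_noop = make_panel([core, m1, noop, m2], spacing=1000)
        without = make_panel([core, m1, m2], spacing=1000)
        c_with = ehh_curve(with_noop, 0, 1)
        c_without = ehh_curve(without, 0, 1)
        d_with = dict(zip(c_with.offsets.tolist(), c_with.ehh_values))
        d_without = dict(zip(c_without.offsets.tolist(), c_without.ehh_values))
        # positions of m1/m2 differ between panels; compare by marker rank
        assert d_with[1000] == d_without[1000]          # after m1
        assert d_with[2000] == d_with[1000]             # no-op marker
        assert c_with.ehh_values.min() == c_without.ehh_values.min()


class TestIntegrateEhh:
    def test_hand_trapezoid_with_cutoff(self):
        """1.0@0, 0.5@1000, 0.04@2000 at cutoff 0.05: only the first
        trapezoid (area 750) qualifies."""
        curve = EhhCurve("c", "1", np.array([0, 1000, 2000]),
                         np.array([1.0, 0.5, 0.04]))
        assert integrate_ehh(curve, 0.05) == pytest.approx(750.0)

    def test_flat_rectangle_one_side(self):
        curve = EhhCurve("c", "1", np.array([0, 1000]), np.array([1.0, 1.0]))
        assert integrate_ehh(curve) == pytest.approx(1000.0)

    def test_all_below_cutoff_zero(self):
        curve = EhhCurve("c", "1", np.array([0, 500]), np.array([1.0, 0.01]))
        assert integrate_ehh(curve, 0.05) == 0.0

    def test_additive_over_directions(self):
        both = EhhCurve("c", "1", np.array([-800, 0, 1000]),
                        np.array([0.5, 1.0, 0.25]))
        left = EhhCurve("c", "1", np.array([-800, 0]), np.array([0.5, 1.0]))
        right = EhhCurve("c", "1", np.array([0, 1000]), np.array([1.0, 0.25]))
        assert integrate_ehh(both) == pytest.approx(
            integrate_ehh(left) + integrate_ehh(right))


class TestIhs:
    def test_mirror_structure_gives_zero_raw(self):
        """Ancestral and derived carriers with mirror-image haplotype
        structure have equal iHH, hence log-ratio 0 -> equal scores."""
        core = [1, 1, 1, 1, 0, 0, 0, 0]
        m = [1, 1, 0, 0, 1, 1, 0, 0]   # symmetric refinement of both classes
        panel = make_panel([core, m], spacing=1000)
        anc = {"v0": 0, "v1": 0}
        a = ehh_curve(panel, 0, 0)
        d = ehh_curve(panel, 0, 1)
        assert integrate_ehh(a) == pytest.approx(integrate_ehh(d))

    def test_label_swap_flips_sign(self, sim_panels):
        panels, _ = sim_panels
        panel = panels["POP1"]
        raws0, raws1 = [], []
        # unstandardized iHS is a log-ratio of the two alleles' iHH values,
        # so relabelling ancestral/derived flips its sign site by site
        for i in range(0, 200, 10):
            if not panel.is_polymorphic(i):
                continue
            counts = (panel.haplotypes[:, i] == 1).sum()
            if min(counts, panel.n_haplotypes - counts) < 2:
                continue
            ihh0 = integrate_ehh(ehh_curve(panel, i, 0), 0.05)
            ihh1 = integrate_ehh(ehh_curve(panel, i, 1), 0.05)
            if ihh0 > 0 and ihh1 > 0:
                raws0.append(math.log(ihh0 / ihh1))
                raws1.append(math.log(ihh1 / ihh0))
        assert raws0 and np.allclose(raws0, [-r for r in raws1])

    def test_standardization_per_bin(self, sim_panels):
        """Standardized scores have per-bin mean 0 and sd 1 by construction."""
        panels, ancestral = sim_panels
        panel = panels["POP1"]
        scores = ihs_scores(panel, ancestral, bin_width=0.25, min_bin=10)
        by_bin = {}
        for vid, s in scores.items():
            if s is None:
                continue
            i = panel.index_of(vid)
            f = float((panel.haplotypes[:, i] == 1).mean())
            by_bin.setdefault(int(f / 0.25), []).append(s)
        assert by_bin
        for b, vals in by_bin.items():
            assert len(vals) >= 10
            assert np.mean(vals) == pytest.approx(0.0, abs=1e-9)
            assert np.std(vals, ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestXpehh:
    def test_identical_panels_zero_raw(self, small_panel):
        for i in range(small_panel.n_variants):
            a = ies_value(small_panel, i)
            assert a == pytest.approx(ies_value(small_panel, i))

    def test_swap_negates(self, sim_panels):
        panels, _ = sim_panels
        pa, pb = panels["POP1"], panels["POP2"]
        ab = xpehh_scores(pa, pb)
        ba = xpehh_scores(pb, pa)
        pairs = [(ab[v], ba[v]) for v in ab
                 if ab.get(v) is not None and ba.get(v) is not None]
        assert len(pairs) > 100
        # standardized over the same variant set: z(x) = -z(-x) holds site-wise
        xs = np.array([p[0] for p in pairs])
        ys = np.array([p[1] for p in pairs])
        assert np.allclose(xs, -ys, atol=1e-9)

    def test_planted_sweep_attains_top_score(self):
        """One founder haplotype driven to 80% in A makes that locus the
        top-ranked XP-EHH site."""
        from evosig.simulate import PlantedSignal, SimConfig, simulate_panels

        sig = PlantedSignal(locus=400, kind="sweep", effect=0.8, span=60,
                            population="POP1")
        cfg = SimConfig(seed=21, n_variants=800, n_diploids=40,
                        planted_signals=[sig])
        panels, _ = simulate_panels(cfg)
        scores = xpehh_scores(panels["POP1"], panels["POP2"])
        vals = {v: s for v, s in scores.items() if s is not None}
        planted_id = panels["POP1"].variants[430].id
        ranked = sorted(vals, key=vals.get, reverse=True)
        top = set(ranked[:max(1, len(ranked) // 50)])
        swept_ids = {panels["POP1"].variants[j].id for j in range(400, 460)}
        assert swept_ids & top


# --------------------------------------------------------------------------
# Beta score

class TestBeta:
    def test_empty_window_zero(self):
        assert beta_score(0.3, [], 10) == 0.0

    def test_adding_matched_variant_increases(self):
        base = [0.1, 0.5, 0.2]
        b0 = beta_score(0.3, base, 10)
        b1 = beta_score(0.3, base + [0.3], 10)
        assert b1 > b0

    def test_toy_window_brute_force_value(self):
        """Direct-summation oracle for n=10, f_c=0.3,
        freqs {0.3, 0.3, 0.1, 0.5, 0.2}."""
        got = beta_score(0.3, [0.3, 0.3, 0.1, 0.5, 0.2], 10)
        assert got == pytest.approx(0.1407947228618518, abs=1e-12)

    def test_neutral_windows_center_near_zero(self):
        """Windows drawn from the neutral folded SFS have mean β near 0
        (calibration of the two estimators' normalisation constants)."""
        rng = np.random.default_rng(13)
        n = 40
        weights = np.array([1.0 / k for k in range(1, n)])
        probs = weights / weights.sum()
        a_n = weights.sum()
        theta = 3.0
        betas = []
        for _ in range(200):
            s = rng.poisson(theta * a_n)
            ks = rng.choice(np.arange(1, n), size=s, p=probs)
            freqs = [min(k / n, 1 - k / n) for k in ks]
            kc = int(rng.integers(1, n))
            fc = min(kc / n, 1 - kc / n)
            betas.append(beta_score(fc, freqs, n))
        assert abs(np.mean(betas)) < 0.5

    def test_frequency_matched_cluster_raises_beta(self):
        rng = np.random.default_rng(14)
        n = 40
        neutral = [min(k / n, 1 - k / n)
                   for k in rng.integers(1, n, size=6)]
        planted = neutral + [0.45, 0.47, 0.5, 0.48]
        assert beta_score(0.5, planted, n) > beta_score(0.5, neutral, n)

    def test_invalid_frequencies_error(self):
        with pytest.raises(InputError):
            beta_score(0.7, [0.2], 10)
        with pytest.raises(InputError):
            beta_score(0.3, [0.6], 10)


# --------------------------------------------------------------------------
# Alignment block age

@pytest.fixture
def hcg_tree():
    return DatedTree.from_newick("((H:5,C:5):5,G:10);")


class TestAlignmentBlockAge:
    def test_lca_hand_examples(self, hcg_tree):
        assert alignment_block_age({"H", "C"}, hcg_tree, "H") == pytest.approx(5.0)
        assert alignment_block_age({"H", "G"}, hcg_tree, "H") == pytest.approx(10.0)

    def test_all_tips_root_age(self, hcg_tree):
        assert alignment_block_age({"H", "C", "G"}, hcg_tree, "H") == \
            pytest.approx(10.0)

    def test_focal_only_zero(self, hcg_tree):
        assert alignment_block_age({"H"}, hcg_tree, "H") == 0.0

    def test_unknown_species_named_in_error(self, hcg_tree):
        with pytest.raises(InputError, match="X"):
            alignment_block_age({"H", "X"}, hcg_tree, "H")

    def test_monotone_in_block_size(self):
        from evosig.simulate import DEFAULT_TREE_NEWICK

        tree = DatedTree.from_newick(DEFAULT_TREE_NEWICK)
        species = ["human", "chimp", "gorilla", "orangutan", "macaque"]
        prev = 0.0
        for k in range(1, len(species) + 1):
            age = alignment_block_age(set(species[:k]), tree, "human")
            assert age >= prev - 1e-12
            prev = age

    def test_non_ultrametric_rejected(self):
        with pytest.raises(Exception):
            DatedTree.from_newick("((H:5,C:3):5,G:10);")


# --------------------------------------------------------------------------
# Measure registry

def test_registry_declares_tails_and_magnitude():
    from evosig.measures import DEFAULT_REGISTRY, apply_registry_transform, load_registry

    reg = load_registry()
    assert set(reg) == set(DEFAULT_REGISTRY)
    for name in ("phylop", "tmrca", "alignment_block_age"):
        assert reg[name]["tail"] == "two_sided"
    for name in ("fst", "beta", "xpehh", "phastcons", "gerp", "linsight"):
        assert reg[name]["tail"] == "upper"
    track = ScoreTrack("ihs", {("chr1", 1): -2.0, ("chr1", 2): 0.5})
    folded = apply_registry_transform(track, reg["ihs"])
    assert folded.values[("chr1", 1)] == 2.0


# --------------------------------------------------------------------------
# Track lookup

def test_lookup_track_values_preserves_order_and_missing():
    vs = [Variant("a", "chr1", 100, "A", "G"),
          Variant("b", "chr1", 200, "A", "G"),
          Variant("c", "chr1", 300, "A", "G")]
    region = TraitRegion(lead=vs[0], members=vs,
                         r2_to_lead={v.id: 1.0 for v in vs})
    track = ScoreTrack("m", {("chr1", 100): 1.0, ("chr1", 300): 3.0})
    vals = lookup_track_values(track, region)
    assert vals == [1.0, None, 3.0]
    assert sum(v is None for v in vals) == 1
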