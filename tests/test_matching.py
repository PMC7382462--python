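import numpy as np
import pytest

from evosig.core import InputError
from evosig.matching import (VariantAnnotation, annotate_pool,
                             assemble_control_regions, build_control_suite,
                             matches_windows, select_control_leads)

from conftest import make_panel


def ann(vid="x", maf=0.2, buddies=20, density=3, distance=1000):
    return VariantAnnotation(vid, maf, buddies, density, distance)


class TestAnnotatePool:
    def test_maf_fold(self):
        """Allele count 30 of 200 haplotypes folds to MAF 0.15."""
        col = [1] * 30 + [0] * 170
        other = [1, 0] * 100
        panel = make_panel([col, other])
        pool = annotate_pool(panel, [("chr1", 1, 10)])
        by_id = pool.by_id()
        assert by_id["v0"].maf == pytest.approx(0.15)

    def test_genic_variant_distance_zero(self):
        panel = make_panel([[1, 0, 1, 0], [0, 1, 1, 0]])
        # v0 at pos 1000 inside gene; v1 at pos 2000 is 500 bp from its end
        pool = annotate_pool(panel, [("chr1", 900, 1500)])
        by_id = pool.by_id()
        assert by_id["v0"].gene_distance == 0
        assert by_id["v1"].gene_distance == 500

    def test_gene_density_counts_window_overlaps(self):
        """3 genes overlapping a 100 kb window centred on the variant."""
        panel = make_panel([[1, 0, 1, 0]])
        pos = 1000  # window [pos-50k, pos+50k] clipped below 0 is fine
        genes = [("chr1", 100, 200),            # inside
                 ("chr1", 40_000, 45_000),      # inside
                 ("chr1", 50_900, 51_100),      # straddles upper edge
                 ("chr1", 60_000, 61_000),      # outside
                 ("chr2", 100, 200)]            # wrong chrom
        pool = annotate_pool(panel, genes, density_window_bp=100_000)
        assert pool.by_id()["v0"].gene_density == 3

    def test_buddies_exclude_self_and_count_strict(self):
        c = [1, 1, 0, 0, 1, 0, 1, 0]
        panel = make_panel([c, list(c), list(c), [1, 0, 0, 1, 0, 1, 0, 1]])
        pool = annotate_pool(panel, [("chr1", 1, 10)])
        assert pool.by_id()["v0"].n_ld_buddies == 2

    def test_empty_gene_set_errors(self, small_panel):
        with pytest.raises(InputError, match="gene"):
            annotate_pool(small_panel, [])


class TestMatchingWindows:
    def test_accept_within_all_windows(self):
        lead = ann(maf=0.20, buddies=20, density=3, distance=1000)
        cand = ann("c", maf=0.24, buddies=22, density=5, distance=4000)
        assert matches_windows(lead, cand)

    def test_reject_maf_outside_absolute_window(self):
        lead = ann(maf=0.20)
        cand = ann("c", maf=0.26)
        assert not matches_windows(lead, cand)

    def test_exact_duplicate_always_matches(self):
        lead = ann()
        dup = ann("c", lead.maf, lead.n_ld_buddies, lead.gene_density,
                  lead.gene_distance)
        assert matches_windows(lead, dup)
        assert select_control_leads(lead, [dup], 5, seed=0) == ["c"]

    def test_buddy_window_is_relative(self):
        lead = ann(buddies=20)
        assert matches_windows(lead, ann("c", 0.2, 22, 3, 1000))
        assert not matches_windows(lead, ann("c", 0.2, 23, 3, 1000))

    def test_empty_pool_errors(self):
        with pytest.raises(InputError, match="empty"):
            select_control_leads(ann(), [], 5, seed=0)

    def test_joint_acceptance_factorises_under_iid_covariates(self):
        """With iid covariates, the joint acceptance fraction approximates
        the product of per-covariate window probabilities (window logic
        sanity check)."""
        rng = np.random.default_rng(42)
        n = 4000
        lead = ann(maf=0.25, buddies=20, density=4, distance=2000)
        pool = [ann(f"c{i}",
                    maf=float(rng.uniform(0.05, 0.5)),
                    buddies=int(rng.integers(0, 60)),
                    density=int(rng.integers(0, 40)),
                    distance=int(rng.integers(0, 30_000)))
                for i in range(n)]
        joint = len(select_control_leads(lead, pool, n, seed=0)) / n
        p_maf = np.mean([abs(a.maf - lead.maf) <= 0.05 for a in pool])
        p_bud = np.mean([abs(a.n_ld_buddies - 20) <= 2 for a in pool])
        p_den = np.mean([0 <= a.gene_density <= 24 for a in pool])
        p_dis = np.mean([0 <= a.gene_distance <= 12_000 for a in pool])
        assert joint == pytest.approx(p_maf * p_bud * p_den * p_dis, abs=0.05)


def _ld_block_panel():
    """Control lead (v0) with 2 strict and 5 relaxed LD partners."""
    base = [1] * 10 + [0] * 10
    cols = [list(base)]         # v0, the lead
    cols += [list(base), list(base)]  # strict partners, r2 = 1
    for k in range(5):          # relaxed: one flipped carrier -> r2 ~ 0.82
        c = list(base)
        c[k] = 0
        cols.append(c)
    cols.append([1, 0] * 10)    # unrelated
    return make_panel(cols, spacing=100)


class TestAssembleControlRegions:
    def test_full_strict_match(self):
        panel = _ld_block_panel()
        suite = assemble_control_regions(["v0"], k=2, panel=panel, seed=1)
        cr = suite.control_regions[0]
        assert cr.match_fraction == 1.0
        assert all(a == 0.9 for a in cr.matched_at)

    def test_no_partners_partial_fraction(self):
        panel = make_panel([[1, 0] * 5, [1, 1, 0, 0, 1, 0, 0, 1, 1, 0]])
        suite = assemble_control_regions(["v0"], k=4, panel=panel, seed=1)
        cr = suite.control_regions[0]
        assert len(cr.member_ids) == 1
        assert cr.match_fraction == pytest.approx(0.2)

    def test_two_pass_fill_strict_then_relaxed(self):
        """2 strict + 5 relaxed candidates, k=4 -> 2 strict + 2 relaxed."""
        panel = _ld_block_panel()
        suite = assemble_control_regions(["v0"], k=4, panel=panel, seed=1)
        cr = suite.control_regions[0]
        assert cr.match_fraction == 1.0
        assert sorted(cr.matched_at) == [0.6, 0.6, 0.9, 0.9, 0.9]

    def test_seed_reproducibility_and_window_satisfaction(self, sim_panels):
        panels, _ = sim_panels
        panel = panels["POP1"]
        genes = [("chr1", 1000, 5000), ("chr1", 60_000, 70_000)]
        pool = annotate_pool(panel, genes, ld_window_bp=5000)
        by_id = pool.by_id()
        lead_id = pool.annotations[50].variant_id
        lead_ann = by_id[lead_id]
        cands = [a for a in pool.annotations if a.variant_id != lead_id]
        a = select_control_leads(lead_ann, cands, 20, seed=9)
        b = select_control_leads(lead_ann, cands, 20, seed=9)
        c = select_control_leads(lead_ann, cands, 20, seed=10)
        assert a == b
        for chosen in (a, c):
            for vid in chosen:
                assert matches_windows(lead_ann, by_id[vid])
        if len(a) == 20 and len(c) == 20:
            assert a != c or len(set(a) | set(c)) == 20


def test_suite_excludes_trait_members(sim_panels):
    """No control shares the trait lead or overlaps the trait members."""
    from evosig.clump import ClumpConfig, clump_regions
    from evosig.core import GwasRecord

    panels, _ = sim_panels
    panel = panels["POP1"]
    genes = [("chr1", 1000, 5000)]
    pool = annotate_pool(panel, genes, ld_window_bp=5000)
    lead = panel.variants[300]
    gwas = [GwasRecord(lead.id, lead.chrom, lead.pos, 1e-6)]
    for j in range(295, 306):
        v = panel.variants[j]
        if v.id != lead.id:
            gwas.append(GwasRecord(v.id, v.chrom, v.pos, 5e-5))
    region = clump_regions(gwas, panel, ClumpConfig(window_bp=5000))[0]
    suite = build_control_suite(region, panel, pool, n_controls=30, seed=3,
                                window_bp=5000)
    member_ids = {v.id for v in region.members}
    for cr in suite.control_regions:
        assert cr.lead_id not in member_ids
        assert not member_ids & set(cr.member_ids)


def test_annotation_validation():
    with pytest.raises(InputError):
        VariantAnnotation("v", 0.0, 1, 1, 1)
    with pytest.raises(InputError):
        VariantAnnotation("v", 0.2, -1, 1, 1)
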