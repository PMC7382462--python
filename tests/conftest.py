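import numpy as np
import pytest

from evosig.core import HaplotypePanel, Variant
from evosig.simulate import SimConfig, simulate_panels


def make_panel(columns, population="POP1", spacing=1000, chrom="chr1"):
    """Panel from a list of per-variant haplotype columns (lists of 0/1)."""
    H = np.array(columns, dtype=np.int8).T
    variants = [Variant(f"v{i}", chrom, 1000 + i * spacing, "A", "G")
                for i in range(len(columns))]
    return HaplotypePanel(population=population, variants=variants,
                          haplotypes=H)


@pytest.fixture
def small_panel():
    """8 haplotypes, 5 variants; columns 0 and 1 identical, 2 complementary."""
    c0 = [1, 1, 1, 0, 0, 0, 1, 0]
    c1 = list(c0)
    c2 = [1 - x for x in c0]
    c3 = [1, 0, 1, 0, 1, 0, 1, 0]
    c4 = [1, 1, 0, 0, 1, 1, 0, 0]
    return make_panel([c0, c1, c2, c3, c4])


@pytest.fixture(scope="session")
def sim_panels():
    cfg = SimConfig(seed=11, n_variants=1500, n_diploids=40)
    panels, ancestral = simulate_panels(cfg)
    return panels, ancestral


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    from evosig.simulate import write_fixture_bundle

    out = tmp_path_factory.mktemp("bundle")
    cfg = SimConfig(seed=5, n_variants=2000, n_diploids=30)
    truth = write_fixture_bundle(cfg, out, n_regions=8, window_bp=4000)
    return out, truth
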