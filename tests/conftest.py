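import numpy as np
import pytest

import xpscan as xs


def build_panel(haps, positions=None, chroms=None, breeds=None, roles=None,
                alleles=None):
    """Assemble a BreedPanel from a raw haplotype matrix (rows=haplotypes)."""
    haps = np.asarray(haps, dtype=np.int8)
    n_hap, m = haps.shape
    assert n_hap % 2 == 0
    n_ind = n_hap // 2
    if positions is None:
        positions = (np.arange(m) + 1) * 1_000_000
    if chroms is None:
        chroms = ["1"] * m
    if alleles is None:
        alleles = np.array([["A", "B"]] * m, dtype=object)
    mm = xs.MarkerMap(np.array([f"m{j}" for j in range(m)], dtype=object),
                      np.array(chroms, dtype=object),
                      np.asarray(positions, dtype=np.int64), alleles)
    ids = [f"ind{k}" for k in range(n_ind)]
    if breeds is None:
        breeds = ["X"] * n_ind
    breed_of = dict(zip(ids, breeds))
    return xs.BreedPanel(mm, haps, ids, breed_of, roles or {})


@pytest.fixture(scope="session")
def small_panel():
    """A reusable 3-breed neutral panel (two calibration breeds + one)."""
    cfg = xs.SimConfig(breeds=[
        xs.BreedConfig("A", 120, 120, 20, 15),
        xs.BreedConfig("B", 400, 150, 20, 15, role="calibration"),
        xs.BreedConfig("C", 400, 150, 20, 15, role="calibration"),
    ], n_markers=120, n_chromosomes=2, seed=11)
    panel, truth = xs.simulate_panel(cfg)
    return panel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
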