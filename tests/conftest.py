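import numpy as np
import pandas as pd
import pytest

from hapsignal.hapio import HaplotypeSet, Panel, Region, VariantSite
from hapsignal.synthetic_data import (
    DEFAULT_CORE,
    SimConfig,
    simulate,
    simulate_surviving_sweep,
    sweep_config,
)

#: region used for Hamming clustering on the synthetic locus (10 kb around
#: the focal site, i.e. gene scale relative to the 200 bp site spacing)
CLUSTER_REGION = Region("3R", 6924703, 6934703)


def make_hapset(matrix, positions=None, chrom="3R", populations=None):
    """Hand-build a HaplotypeSet from an (n_sites, n_hap) 0/1 array."""
    matrix = np.asarray(matrix, dtype=np.uint8)
    n_sites, n_hap = matrix.shape
    assert n_hap % 2 == 0
    if positions is None:
        positions = 1000 + 10 * np.arange(n_sites)
    sites = tuple(
        VariantSite(chrom, int(p), "A", "G") for p in positions
    )
    n_samples = n_hap // 2
    if populations is None:
        populations = ["pop1"] * n_samples
    samples = [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "sample_id": np.repeat(samples, 2),
            "hap": np.tile([1, 2], n_samples),
            "population": np.repeat(populations, 2),
            "species": "gambiae",
        }
    )
    return HaplotypeSet(sites=sites, matrix=matrix, meta=meta)


def make_panel(hapset):
    samples = hapset.sample_ids
    pops = {
        s: hapset.meta.loc[hapset.meta["sample_id"] == s, "population"].iloc[0]
        for s in samples
    }
    return Panel(
        samples=tuple(samples),
        populations=pops,
        species={s: "gambiae" for s in samples},
    )


@pytest.fixture(scope="session")
def neutral_sim():
    return simulate(SimConfig(seed=2024))


@pytest.fixture(scope="session")
def sweep_sim():
    return simulate_surviving_sweep(sweep_config(seed=2024))


@pytest.fixture(scope="session")
def core_region():
    return DEFAULT_CORE
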