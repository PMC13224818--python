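import numpy as np
import pytest

from nodufam import GeneTree, SimConfig, default_species_config, simulate_family


@pytest.fixture(scope="session")
def config():
    return default_species_config()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tree(flags: str, config, superfamily_id: str = "toy") -> GeneTree:
    """Build a GeneTree whose leaf order realises a binary legume (L) /
    non-legume (N) pattern, e.g. "LLNLL".  Legume leaves use medtr, glyma,
    phavu, ... cyclically; non-legume leaves use vitvi, arath, prupe."""
    legumes = [c for c in config.codes if config.is_legume(c)]
    others = [c for c in config.codes if not config.is_legume(c)]
    leaves = []
    for i, ch in enumerate(flags):
        pool = legumes if ch == "L" else others
        code = pool[i % len(pool)]
        leaves.append(f"{code}.g{i:03d}")
    return GeneTree(superfamily_id=superfamily_id, leaf_order=leaves)


@pytest.fixture
def wgd_family():
    """A family with a WGD above the NFNC ancestor, fully retained."""
    return simulate_family(SimConfig(wgd_events={"nfnc": 1.0}, seed=7), "wgdfam")
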