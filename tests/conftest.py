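import numpy as np
import pandas as pd
import pytest

from asymdex.manifest import DISEASE, NORMAL
from asymdex.resources import compendium_manifest
from asymdex.synthetic import SimConfig, StudyDesign, simulate_gene_level


@pytest.fixture(scope="session")
def affy_manifest():
    """The 31 Affymetrix studies of the five-cancer compendium."""
    return compendium_manifest(blocks=("core", "asym"))


@pytest.fixture(scope="session")
def core_manifest():
    """The 19 symmetric Affymetrix studies."""
    return compendium_manifest(blocks=("core",))


@pytest.fixture
def tiny_table():
    """3v3 toy expression table with one strongly shifted gene."""
    rng = np.random.default_rng(7)
    values = rng.normal(8.0, 0.3, size=(20, 6))
    values[0, 3:] += 5.0  # planted effect
    samples = [f"n{i}" for i in range(3)] + [f"d{i}" for i in range(3)]
    table = pd.DataFrame(values, index=[f"g{i:02d}" for i in range(20)], columns=samples)
    labels = {s: (NORMAL if s.startswith("n") else DISEASE) for s in samples}
    return table, labels


@pytest.fixture(scope="session")
def small_collection():
    """Three symmetric simulated studies with planted effects."""
    cfg = SimConfig(
        n_genes=300,
        studies=[StudyDesign("t", 6, 6) for _ in range(3)],
        de_fraction=0.1,
        effect_mean=1.5,
        seed=11,
    )
    tables, labels, truth = simulate_gene_level(cfg)
    return cfg, tables, labels, truth
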