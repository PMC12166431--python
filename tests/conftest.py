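import numpy as np
import pytest

from deathmark.synthetic import ScenarioManifest, generate_scenario


@pytest.fixture(scope="session")
def small_manifest():
    """Reduced study: quick enough for per-module tests, same structure."""
    return ScenarioManifest(
        seed=7,
        n_genes=300,
        n_cell_lines=12,
        n_knockdowns=60,
        n_planted=4,
        n_corr_decoys=3,
        n_signature_decoys=3,
        n_cited_decoys=5,
    )


@pytest.fixture(scope="session")
def small_scenario(small_manifest):
    return generate_scenario(small_manifest)


@pytest.fixture(scope="session")
def default_scenario():
    """The default study conditions: 2000 genes, 20 cell lines,
    500 knockdowns, 10 planted suppressors."""
    return generate_scenario(ScenarioManifest(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(20250922)
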