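import numpy as np
import pytest

from mdnmf.simulate import PlantedConfig, planted_blocks


@pytest.fixture
def edge_file(tmp_path):
    """Write an edge list to a temp file and return its path."""

    def _write(rows, delim="\t", name="edges.tsv"):
        path = tmp_path / name
        path.write_text("\n".join(delim.join(r) for r in rows) + "\n", encoding="utf-8")
        return path

    return _write


@pytest.fixture(scope="session")
def planted_data():
    """Noisy two-block fixture: 20 x 10, within 0.6, background 0.02."""
    return planted_blocks(
        PlantedConfig(m=20, d=10, n_blocks=2, within_block_prob=0.6,
                      background_prob=0.02, seed=0)
    )


@pytest.fixture(scope="session")
def dense_block_data():
    """Dense two-block fixture (10% within-block dropout): 20 x 10."""
    return planted_blocks(
        PlantedConfig(m=20, d=10, n_blocks=2, within_block_prob=0.9,
                      background_prob=0.02, seed=0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
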