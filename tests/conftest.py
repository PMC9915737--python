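import numpy as np
import pytest

import pocketrank as pr


@pytest.fixture(scope="session")
def small_dataset() -> pr.RankingDataset:
    """30 proteins with the default effect structure; enough signal to learn."""
    return pr.generate_feature_table(pr.SyntheticSpec(n_proteins=30, seed=42))


@pytest.fixture(scope="session")
def small_model(small_dataset) -> pr.BoostedRanker:
    return pr.train(small_dataset, pr.LambdaRankParams(n_trees=60, seed=42))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_group(rng: np.random.Generator, max_size: int = 6) -> np.ndarray:
    """Random binary-relevance group with at least one item."""
    n = int(rng.integers(1, max_size + 1))
    return rng.integers(0, 2, size=n)


@pytest.fixture(scope="session")
def labeled_fixture_entry() -> pr.ProteinEntry:
    """A structure fixture parsed back through the I/O layer (in-memory)."""
    import tempfile
    from pathlib import Path

    fx = pr.generate_structure_fixture(pr.SyntheticSpec(seed=5))
    with tempfile.TemporaryDirectory() as d:
        pdb, out = fx.write(d)
        return pr.load_entry(pdb, out, [fx.manifest_row[1]], fx.protein_id)
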