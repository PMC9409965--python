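import numpy as np
import pytest

from robustcheck.dataset_core import OmicsTable
from robustcheck.synthetic_data import SynthConfig, generate_dataset, reference_fixture


@pytest.fixture(scope="session")
def reference_table():
    """Canonical 159x24 fixture (83/76 classes, 5 planted informative features)."""
    table, truth = reference_fixture(seed=42)
    return table, truth


@pytest.fixture(scope="session")
def reference_screen(reference_table):
    """Factor-analysis screen of the reference fixture (shared: it is the
    slowest stage in the suite)."""
    from robustcheck.factor_analysis import ScreenConfig, run_factor_analysis

    table, _ = reference_table
    return run_factor_analysis(table, ScreenConfig(max_pairs=300, n_draws=20_000, seed=0))


@pytest.fixture(scope="session")
def small_planted_table():
    """40-sample, 12-feature table with 5 strongly informative features."""
    config = SynthConfig(
        n_case=20, n_control=20, n_features=12, n_informative=5,
        effect_size=2.5, correlation=0.3, seed=7,
    )
    return generate_dataset(config)


@pytest.fixture
def tiny_table():
    """Hand-written 6x2 table, perfectly separated in the first feature."""
    return OmicsTable(
        values=np.array(
            [[1.0, 5.0], [2.0, 4.0], [3.0, 6.0], [11.0, 5.5], [12.0, 4.5], [13.0, 6.5]]
        ),
        sample_ids=("a", "b", "c", "d", "e", "f"),
        feature_names=("sep", "flat"),
        labels=np.array([0, 0, 0, 1, 1, 1]),
    )


@pytest.fixture
def separable_toy():
    """Linearly separable 2-D blobs at (-3,-3) and (3,3), n=40."""
    rng = np.random.default_rng(0)
    x0 = rng.normal(-3, 0.5, size=(20, 2))
    x1 = rng.normal(3, 0.5, size=(20, 2))
    values = np.vstack([x0, x1])
    return OmicsTable(
        values=values,
        sample_ids=tuple(f"s{i}" for i in range(40)),
        feature_names=("f1", "f2"),
        labels=np.array([0] * 20 + [1] * 20),
    )
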