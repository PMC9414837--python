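import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ndoa.benchmark import evaluate_benchmark
from ndoa.regression import TrainingSet, fit


@pytest.fixture(scope="session")
def benchmark_result():
    """Full pipeline run on the 10-record seed-7 synthetic benchmark with
    record-wise held-out traces; shared because it is the expensive part of
    the suite."""
    return evaluate_benchmark(n_records=10, seed=7)


@pytest.fixture(scope="session")
def quick_model():
    """A cheap robust-linear index model over random features, for tests
    that exercise the streaming machinery rather than model quality."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(60, 5))
    y = np.clip(50 + 20 * X[:, 0] + rng.normal(0, 2, 60), 0, 100)
    ts = TrainingSet(X, y, np.array(["s0"] * 60, dtype=object))
    return fit(ts, kind="linear_robust", seed=1)
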