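import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dynconn.graphmetrics import METRIC_ORDER
from dynconn.synthetic import CohortSpec, Coupling, generate_cohort

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_metric_table(
    n_subjects: int,
    classes=("Ug", "Tg", "Sc"),
    bands=("delta", "theta", "alpha", "beta", "full"),
    n_windows: int = 63,
    methods=("pli", "wpli"),
    seed: int = 0,
) -> pd.DataFrame:
    """Complete long-format metric table with reproducible random values."""
    rng = np.random.default_rng(seed)
    rows = list(
        itertools.product(classes, range(n_subjects), methods, bands,
                          range(1, n_windows + 1), METRIC_ORDER)
    )
    df = pd.DataFrame(rows, columns=["condition", "subject", "method", "band", "window", "metric"])
    df["value"] = rng.normal(size=len(df))
    return df


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects/class, 10 trials, 6 channels; one alpha coupling (0,1) in
    windows 14-25 at strength 0.9 for class 'coupled'."""
    spec = CohortSpec(
        n_subjects_per_class=3,
        n_trials=10,
        n_channels=6,
        classes=("coupled", "uncoupled"),
        class_coupling=[Coupling("coupled", (0, 1), "alpha", (14, 25), np.pi / 4, 0.9)],
        seed=42,
    )
    epochs, truth = generate_cohort(spec)
    return spec, epochs, truth


def random_graph(n: int, rng: np.random.Generator, zero_frac: float = 0.0) -> np.ndarray:
    """Random symmetric weighted graph with weights in (0, 1] and an optional
    fraction of absent edges."""
    w = rng.uniform(0.05, 1.0, (n, n))
    if zero_frac:
        w[rng.random((n, n)) < zero_frac] = 0.0
    w = np.triu(w, 1)
    w = w + w.T
    return w
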