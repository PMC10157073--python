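import matplotlib
import numpy as np
import pytest
from hypothesis import settings

from wmpattern import FeatureTable, SyntheticSpec, generate_cohort

matplotlib.use("Agg")
settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


def make_table(X, y=None, prefix="f"):
    """Small helper: wrap a matrix (and optional ±1 labels) in a FeatureTable."""
    X = np.asarray(X, float)
    n, d = X.shape
    return FeatureTable(
        [f"s{i:03d}" for i in range(n)],
        [f"{prefix}{j}" for j in range(d)],
        X,
        None if y is None else np.asarray(y),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default 14 vs 15 synthetic cohort with planted sparse effects."""
    return generate_cohort(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def fitted_default(default_cohort):
    """A desk-scale nested-CV fit of the default cohort (shared across tests)."""
    from wmpattern import NestedCVClassifier

    clf = NestedCVClassifier(default_cohort.features, k_outer=5, r_outer=2,
                             k_inner=3, r_inner=2,
                             c_grid=[0.0625, 0.25, 1.0, 4.0], seed=11)
    return clf.fit()
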