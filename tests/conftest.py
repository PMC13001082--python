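import numpy as np
import pandas as pd
import pytest

from dompaint.formula import ElementVector
from dompaint.morpho import WellProfileMatrix, WellSchema


def random_valid_formula(rng: np.random.Generator) -> ElementVector:
    """A random composition satisfying the element-count invariants."""
    c = int(rng.integers(1, 40))
    h = int(rng.integers(1, 2 * c + 3))
    return ElementVector(
        c, h, int(rng.integers(0, 4)), int(rng.integers(0, 20)), int(rng.integers(0, 3))
    )


@pytest.fixture
def small_schema() -> WellSchema:
    return WellSchema(
        base_features=["nuclear_area", "nuclear_diameter", "cell_area"],
        correlation_pairs=[("nuclear_area", "nuclear_diameter"),
                           ("nuclear_area", "cell_area")],
    )


def make_wells(
    n_treatments: int = 6,
    replicates: int = 4,
    n_controls: int = 8,
    n_features: int = 5,
    seed: int = 0,
    plates: int = 1,
) -> WellProfileMatrix:
    """Small raw well matrix with Gaussian features, controls at baseline."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for p in range(plates):
        for t in range(n_treatments):
            for r in range(replicates):
                rows.append(rng.normal(t * 0.1, 1.0, n_features))
                labels.append({"plate": f"P{p}", "well": f"W{t}_{r}",
                               "treatment": f"T{t}", "is_control": False})
        for r in range(n_controls):
            rows.append(rng.normal(0, 1.0, n_features))
            labels.append({"plate": f"P{p}", "well": f"C{r}",
                           "treatment": "DMSO", "is_control": True})
    return WellProfileMatrix(
        values=pd.DataFrame(rows, columns=[f"f{i}" for i in range(n_features)]),
        labels=pd.DataFrame(labels),
    )
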