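"""Shared fixtures: small synthetic cohorts and fGn helpers."""

import numpy as np
import pandas as pd
import pytest

from neurocascade.roi import FeatureTable
from neurocascade.synthetic import FgnSpec, generate_fgn, oracle_cohort


@pytest.fixture(scope="session")
def separable_cohort() -> FeatureTable:
    """Three well-separated classes (strong planted effects, 20 per class)."""
    return oracle_cohort(n_per_class={"AD": 20, "MCI": 20, "HC": 20}, seed=11)


@pytest.fixture(scope="session")
def small_noise_table() -> FeatureTable:
    """A tiny pure-noise table (18 subjects × 20 features) for harness tests."""
    rng = np.random.default_rng(5)
    ids = [f"S{i:02d}" for i in range(18)]
    groups = pd.Series(["AD", "MCI", "HC"] * 6, index=ids, name="group")
    cols = pd.MultiIndex.from_tuples(
        [("HE", l) for l in range(1, 21)], names=["metric", "label"]
    )
    values = pd.DataFrame(rng.standard_normal((18, 20)), index=ids, columns=cols)
    values.index.name = "subject_id"
    return FeatureTable(values=values, groups=groups)


def fgn_batch(H: float, length: int, n: int, seed: int) -> np.ndarray:
    """n independent fGn series stacked as rows."""
    return np.stack(
        [generate_fgn(FgnSpec(H=H, length=length, seed=seed * 100000 + i)) for i in range(n)]
    )
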