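"""Shared fixtures: one session-scoped default synthetic cohort feeds the
planted-recovery tests, so the expensive point-process simulation runs once."""

import warnings

import numpy as np
import pandas as pd
import pytest

from timephen import clustering, features, synthetic

COHORT_SEED = 11


@pytest.fixture(scope="session")
def default_cohort():
    cohort, truth = synthetic.generate_cohort(synthetic.SyntheticConfig(rng_seed=COHORT_SEED))
    return cohort, truth


@pytest.fixture(scope="session")
def feature_matrix(default_cohort):
    cohort, _ = default_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mat, manifest = features.build_feature_matrix(cohort)
    return mat, manifest


@pytest.fixture(scope="session")
def phenotype_assignments(feature_matrix):
    mat, _ = feature_matrix
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assignments, report = clustering.assign_phenotypes(mat, k=5, B=100, rng=7)
    return assignments, report


@pytest.fixture()
def small_cohort():
    """A fast low-density cohort for I/O and validation tests."""
    sparse = {
        name: synthetic.ClusterArchetype(
            name=name,
            density_targets={"ck": 150.0, "cd8": 40.0, "cd68": 30.0, "foxp3": 10.0},
            marker_rates=arch.marker_rates,
            tumor_fraction=arch.tumor_fraction,
        )
        for name, arch in synthetic.default_archetypes().items()
    }
    cfg = synthetic.SyntheticConfig(n_patients=8, rng_seed=3, archetypes=sparse)
    cohort, truth = synthetic.generate_cohort(cfg)
    return cohort, truth


def random_cell_table(rng: np.random.Generator, n: int, box: float = 400.0) -> pd.DataFrame:
    """Random marker table used by oracle-equivalence tests."""
    lineage = rng.choice(["ck", "cd8", "cd68", "foxp3", "none"], size=n)
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "core_id": "core",
            "x_um": rng.uniform(0, box, n),
            "y_um": rng.uniform(0, box, n),
            "compartment": rng.choice(["tumor", "stroma"], size=n),
        }
    )
    for m in ("ck", "cd8", "cd68", "foxp3"):
        df[m] = lineage == m
    df["pd1"] = (rng.random(n) < 0.3) & df["cd8"]
    df["pdl1"] = (rng.random(n) < 0.4) & (df["ck"] | df["cd68"])
    return df
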