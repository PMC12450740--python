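import numpy as np
import pandas as pd
import pytest

from wqsmix import MixtureDataset, SimulationSpec, generate


@pytest.fixture(scope="session")
def case_study_shaped():
    """14 subjects x 3 occasions x 30 components, two equal strata."""
    spec = SimulationSpec(seed=20230801)
    ds, truth = generate(spec)
    return ds, truth


@pytest.fixture(scope="session")
def recovery_shaped():
    """Moderate-size dataset with strong signal for recovery checks."""
    spec = SimulationSpec(
        n_subjects=120,
        n_occasions=3,
        n_components=10,
        n_active=3,
        true_b1=0.5,
        true_b12=0.3,
        sigma_b2=0.6,
        sigma_e2=0.4,
        seed=7,
    )
    ds, truth = generate(spec)
    return ds, truth


def make_dataset(
    n_subjects=10,
    n_occasions=2,
    n_components=3,
    stratified=False,
    seed=0,
):
    """Small hand-rolled long-format dataset (no mixture signal)."""
    rng = np.random.default_rng(seed)
    n = n_subjects * n_occasions
    df = pd.DataFrame(
        rng.lognormal(size=(n, n_components)),
        columns=[f"x{j}" for j in range(n_components)],
    )
    df.insert(0, "subject", np.repeat([f"S{i}" for i in range(n_subjects)], n_occasions))
    df.insert(1, "occasion", np.tile([f"T{t}" for t in range(n_occasions)], n_subjects))
    df["y"] = rng.normal(size=n)
    df["age"] = np.repeat(rng.normal(size=n_subjects), n_occasions)
    kwargs = {}
    if stratified:
        half = n_subjects // 2
        strat = np.repeat(
            np.array(["A"] * half + ["B"] * (n_subjects - half)), n_occasions
        )
        df["sex"] = strat
        kwargs["stratum_col"] = "sex"
    return MixtureDataset(
        data=df,
        subject_col="subject",
        occasion_col="occasion",
        outcome_col="y",
        component_cols=[f"x{j}" for j in range(n_components)],
        covariate_cols=["age"],
        **kwargs,
    )
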