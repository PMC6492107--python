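import numpy as np
import pandas as pd
import pytest

from normdae import (
    Feature,
    FeatureSchema,
    ModelConfig,
    MorphometryTable,
    build_model,
    default_cohort_spec,
    generate_cohort,
    train,
)


@pytest.fixture(scope="session")
def schema():
    from normdae import default_schema
    return default_schema()


def make_mini_schema(n: int = 3) -> FeatureSchema:
    """A small ad-hoc schema for arithmetic-level tests."""
    return FeatureSchema(tuple(
        Feature(f"feat{i}", "thickness", "left", "desikan_killiany")
        for i in range(n)
    ))


def make_mini_table(values, ages=None, sexes=None, schema=None,
                    group="HC", dataset="D1") -> MorphometryTable:
    """Build a MorphometryTable from a (subjects x features) array."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = values.shape
    schema = schema or make_mini_schema(p)
    df = pd.DataFrame(values, columns=list(schema.names))
    df.insert(0, "subject_id", [f"S{i:03d}" for i in range(n)])
    df.insert(1, "age", ages if ages is not None else [25] * n)
    df.insert(2, "sex", sexes if sexes is not None else ["M"] * n)
    df.insert(3, "group", group)
    df.insert(4, "dataset", dataset)
    return MorphometryTable(df, schema)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but full-width synthetic study shared across tests."""
    spec = default_cohort_spec(seed=42, n_reference=200, n_controls=40,
                               n_patients=40)
    reference, clinical = generate_cohort(spec)
    return spec, reference, clinical


@pytest.fixture(scope="session")
def trained_small(small_cohort):
    """A briefly trained full-width model for inference-level tests."""
    _, reference, _ = small_cohort
    cfg = ModelConfig(epochs=60, seed=0)
    return train(build_model(cfg), reference)
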