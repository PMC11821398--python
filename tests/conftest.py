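import numpy as np
import pytest

from oilauth import (
    ClassDistribution,
    CompositionSample,
    CompositionTable,
    FeatureSchema,
    GroundTruthSpec,
    make_fixture_bundle,
)


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study bundle (27 CO / 10 SO / 33 mixtures)."""
    return make_fixture_bundle()


@pytest.fixture(scope="session")
def schema(bundle):
    return bundle.schema


@pytest.fixture()
def tiny_schema():
    """Four features across the three compositional blocks."""
    return FeatureSchema(
        ["fa1", "fa2", "tag1", "toco1"],
        {"fa1": "FA", "fa2": "FA", "tag1": "TAG", "toco1": "TOCO"},
    )


def make_table(schema, rows, label="CO", replicate_ids=None, sample_ids=None):
    """Build a table from a list of value rows (floats or flag tokens)."""
    samples = []
    for i, row in enumerate(rows):
        values, flags = [], []
        for v in row:
            if isinstance(v, str):
                values.append(np.nan)
                flags.append(v)
            else:
                values.append(float(v))
                flags.append(None)
        samples.append(
            CompositionSample(
                sample_ids[i] if sample_ids else f"S{i + 1}",
                label,
                np.array(values),
                tuple(flags),
                replicate_ids[i] if replicate_ids else None,
            )
        )
    return CompositionTable(schema, samples)


def separated_distributions(k=37, gap=1000.0):
    """CO/SO pair whose 7 mixture classes are tens of pooled SDs apart."""
    co = ClassDistribution("CO", np.zeros(k), np.eye(k))
    so = ClassDistribution("SO", np.full(k, gap), np.eye(k))
    return co, so


def identical_distributions(k=37):
    """CO/SO pair with exactly the same law: every class is identical."""
    rng = np.random.default_rng(0)
    mu = rng.uniform(1, 5, size=k)
    A = rng.standard_normal((k, k)) / np.sqrt(k)
    sigma = A @ A.T + 0.5 * np.eye(k)
    return (
        ClassDistribution("CO", mu, sigma),
        ClassDistribution("SO", mu.copy(), sigma.copy()),
    )
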