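from __future__ import annotations

import numpy as np
import pytest

from enzmech.datasets import Attribute, Instance, MultiLabelDataset
from enzmech.synth import SynthConfig, generate


@pytest.fixture(scope="session")
def clean_synth():
    """Clean fixture: 5 families x 3 orthologs + 10 negatives, no confounders."""
    return generate(SynthConfig(seed=20140519))


@pytest.fixture(scope="session")
def confounded_synth():
    """Same conditions plus one fully-overlapping confounder family pair."""
    return generate(SynthConfig(seed=20140519, confounder_pairs=1))


@pytest.fixture(scope="session")
def complex_synth():
    """Fixture with one 2-subunit complex family, for label splitting."""
    return generate(SynthConfig(seed=20140519, n_complex_families=1))


def random_dataset(
    rng: np.random.Generator,
    n_max: int = 30,
    d_max: int = 10,
    l_max: int = 4,
) -> MultiLabelDataset:
    """A small random binary multi-label dataset for oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    d = int(rng.integers(1, d_max + 1))
    n_labels = int(rng.integers(1, l_max + 1))
    labels = [f"M{9100 + i:04d}" for i in range(n_labels)]
    instances = []
    for i in range(n):
        attrs = {j: 1.0 for j in range(d) if rng.random() < 0.4}
        labs = frozenset(l for l in labels if rng.random() < 0.3)
        instances.append(Instance(id=f"R{i:03d}", attributes=attrs, labels=labs))
    return MultiLabelDataset(
        instances=instances,
        attribute_space=[Attribute(f"s{j}", "binary") for j in range(d)],
        label_space=labels,
    )


@pytest.fixture
def toy_dataset() -> MultiLabelDataset:
    """Three proteins over three signatures: P1(m1)={s1}, P2(m1)={s1,s2},
    P3(m2)={s3}."""
    return MultiLabelDataset(
        instances=[
            Instance(id="P1", attributes={0: 1}, labels={"M9201"}),
            Instance(id="P2", attributes={0: 1, 1: 1}, labels={"M9201"}),
            Instance(id="P3", attributes={2: 1}, labels={"M9202"}),
        ],
        attribute_space=[Attribute(s, "binary") for s in ("s1", "s2", "s3")],
        label_space=["M9201", "M9202"],
    )
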