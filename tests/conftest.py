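import numpy as np
import pytest

from goensembles.datasets import AnnotationRecord
from goensembles.features import FeaturizerConfig, ProteinRecord, featurize
from goensembles.ontology import OntologyDag


@pytest.fixture
def diamond_dag() -> OntologyDag:
    """root <- A, root <- B, A <- C, B <- C."""
    return OntologyDag.from_edges(
        [("A", "root"), ("B", "root"), ("C", "A"), ("C", "B")]
    )


@pytest.fixture
def chain_dag() -> OntologyDag:
    """root <- A <- B."""
    return OntologyDag.from_edges([("A", "root"), ("B", "A")])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_records(rng: np.random.Generator, n: int, lo: int = 20, hi: int = 60):
    from goensembles.features import STANDARD_AMINO_ACIDS

    alphabet = np.array(list(STANDARD_AMINO_ACIDS))
    out = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        out.append(ProteinRecord(f"P{i:04d}", "".join(rng.choice(alphabet, size=length))))
    return out


@pytest.fixture
def small_feature_problem(rng):
    """A small separable 2-mer classification problem for learner tests.

    40 proteins; positives carry the motif 'ACA' so the 2-mers AC/CA are
    enriched.  Features use k=2 (400 columns) to keep fits fast.
    """
    records = random_records(rng, 40)
    labels = np.array([1] * 20 + [0] * 20)
    boosted = []
    for rec, y in zip(records, labels):
        seq = rec.sequence
        if y == 1:
            seq = "ACAACAACA" + seq
        boosted.append(ProteinRecord(rec.id, seq))
    X = featurize(boosted, FeaturizerConfig(k=2))
    return X, labels
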