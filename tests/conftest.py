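import numpy as np
import pytest

from mirsea.io import ExpressionDataset
from mirsea.scoring import rank_mirnas
from mirsea.weighting import ConvertedPathway


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    """3 miRNAs x 4 samples, 2 per class, deterministic values."""
    rng = np.random.default_rng(11)
    return ExpressionDataset(
        mirna_ids=["miR-1", "miR-2", "miR-3"],
        values=rng.normal(size=(3, 4)),
        sample_ids=["s1", "s2", "s3", "s4"],
        phenotype=["A", "A", "B", "B"],
        classes=("A", "B"),
    )


def random_instance(rng, max_len: int = 50, min_len: int = 4):
    """A random ranked list plus a member set with >=1 member and >=1 miss."""
    n = int(rng.integers(min_len, max_len + 1))
    ids = [f"m{i:03d}" for i in range(n)]
    scores = rng.normal(size=n)
    k = int(rng.integers(1, n))
    members = set(rng.choice(ids, size=k, replace=False).tolist())
    ranked = rank_mirnas(dict(zip(ids, scores)))
    pathway = ConvertedPathway(pathway_id="P", members={m: 0.5 for m in members})
    return ranked, pathway, members
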