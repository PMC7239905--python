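import numpy as np
import pandas as pd
import pytest

from panomix.blocks import OmicBlock


def make_block(values, kind="GE", name=None, gene_ids=None, prefix="f"):
    """Wrap a plain array into an OmicBlock with generated annotation."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if gene_ids is None:
        gene_ids = [f"g{j:05d}" for j in range(p)]
    feats = pd.DataFrame({
        "feature_id": [f"{prefix}_{j:05d}" for j in range(p)],
        "gene_id": gene_ids,
        "chromosome": ["chr1"] * p,
        "kind": [kind] * p,
    })
    return OmicBlock(values, [f"s{i:04d}" for i in range(n)], feats,
                     name or kind)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_block(rng):
    return make_block(rng.standard_normal((20, 10)))
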