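import numpy as np
import pandas as pd
import pytest

from immunedecomp import GeneSignature, SignatureCollection


def brute_force_es(ranks: dict, set_genes, alpha: float) -> float:
    """Independent running-sum ssGSEA oracle (direct per-position walk).

    Walks genes in decreasing-rank order (ties by gene id), accumulating
    the weighted in-set ECDF minus the unweighted out-of-set ECDF at every
    position.  Deliberately naive: O(p) per evaluation, no closed form.
    """
    genes = sorted(ranks, key=lambda g: (-ranks[g], g))
    inset = {g for g in set_genes if g in ranks}
    p, m = len(genes), len(inset)
    assert 1 <= m < p
    total_w = sum(ranks[g] ** alpha for g in inset)
    es = 0.0
    cum_in = 0.0
    cum_out = 0
    for g in genes:
        if g in inset:
            cum_in += ranks[g] ** alpha
        else:
            cum_out += 1
        es += cum_in / total_w - cum_out / (p - m)
    return es


@pytest.fixture
def rng():
    return np.random.default_rng(20160913)


@pytest.fixture
def small_expr():
    """5 genes x 3 samples, includes a tie in the last column."""
    return pd.DataFrame(
        {
            "A": [5.0, 4.0, 3.0, 2.0, 1.0],
            "B": [1.0, 3.0, 5.0, 2.0, 4.0],
            "C": [2.0, 2.0, 1.0, 4.0, 3.0],
        },
        index=["g1", "g2", "g3", "g4", "g5"],
    )


@pytest.fixture
def tiny_collection():
    return SignatureCollection(
        (
            GeneSignature("top", ("g1", "g2")),
            GeneSignature("bottom", ("g4", "g5")),
        ),
        source="test",
    )
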