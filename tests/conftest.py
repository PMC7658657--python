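import numpy as np
import pandas as pd
import pytest

from slscreen import synthetic_data as synth
from slscreen._types import GenePair


@pytest.fixture(scope="session")
def small_truth():
    """A small study with every kind of planted signal."""
    cfg = synth.GeneratorConfig(
        n_genes=120,
        n_cancers=12,
        n_pairs=20,
        n_mut_signal_pairs=2,
        n_expr_signal_pairs=2,
        n_combined_pairs=2,
        n_prognostic_pairs=2,
        n_de_cancers=11,
        n_loci=24,
        n_down_mirnas=3,
        n_drug_effect_pairs=1,
    )
    return synth.generate_truth(cfg, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_catalog(rng, n_genes=30, n_pairs=40):
    """Random canonical pair list over a small gene universe."""
    genes = [f"X{i:03d}" for i in range(n_genes)]
    taken = set()
    pairs = []
    while len(pairs) < n_pairs:
        i, j = rng.integers(0, n_genes, size=2)
        if i == j:
            continue
        a, b = sorted((genes[i], genes[j]))
        if (a, b) in taken:
            continue
        taken.add((a, b))
        pairs.append(GenePair.make(a, b, {"human_validated"}))
    return pairs
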