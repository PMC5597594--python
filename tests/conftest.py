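import numpy as np
import pandas as pd
import pytest

from polytrans import synthetic_data as sd
from polytrans.matrix import FractionCountMatrix
from polytrans.polysome import FractionDesign


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def design():
    return FractionDesign()


@pytest.fixture(scope="session")
def small_sim():
    cfg = sd.SimConfig(n_genes=120, seed=42)
    return sd.simulate_polysome_counts(cfg)


@pytest.fixture(scope="session")
def gene_models():
    return sd.make_gene_models(40, np.random.default_rng(7), minus_fraction=0.25)


def build_fcm(genes, values, fractions=tuple(range(4, 17)), conditions=("L", "LE"), n_replicates=4):
    """FractionCountMatrix from ``values(gene_index, condition, fraction, replicate)``."""
    meta = [
        (f"{cond}_f{f:02d}_r{r}", cond, r, f)
        for cond in conditions
        for f in fractions
        for r in range(1, n_replicates + 1)
    ]
    data = {
        sid: [values(i, cond, f, r) for i in range(len(genes))]
        for sid, cond, r, f in meta
    }
    counts = pd.DataFrame(data, index=list(genes))
    samples = pd.DataFrame(
        meta, columns=["sample", "condition", "replicate", "fraction"]
    ).set_index("sample")
    return FractionCountMatrix(counts, samples)
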