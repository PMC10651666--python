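import numpy as np
import pandas as pd
import pytest

from myoaging.diffexpr import DEResult
from myoaging.simulate import SimConfig, simulate_counts


def small_config(**overrides) -> SimConfig:
    """A fast mixed-block scenario for unit tests."""
    defaults = dict(
        n_genes_shared=200,
        n_genes_male_block=60,
        n_genes_female_block=180,
        n_genes_null=600,
        seed=11,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    """One shared simulation (counts + truth) reused across read-only tests."""
    return simulate_counts(small_config())


def make_de_result(genes, pvals, lfcs, sex="male") -> DEResult:
    """Hand-build a DEResult from parallel lists."""
    p = np.asarray(pvals, dtype=float)
    tab = pd.DataFrame(
        {
            "log2fc": np.asarray(lfcs, dtype=float),
            "p_value": p,
            "neg_log10_p": -np.log10(p),
            "base_mean": 100.0,
        },
        index=pd.Index(genes, name="gene"),
    )
    return DEResult(table=tab, sex=sex)
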