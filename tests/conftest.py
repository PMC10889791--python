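import numpy as np
import pandas as pd
import pytest

from refstab.ct_data import CtTable


def make_table(ct_rows, genes=None, groups=None, amp=None):
    """Build an aggregated CtTable from a plain matrix (genes x samples)."""
    ct = np.asarray(ct_rows, dtype=float)
    k, n = ct.shape
    genes = genes or [f"g{i+1}" for i in range(k)]
    groups = groups or [""] * n
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{j+1}" for j in range(n)],
            "group": groups,
            "bio_rep": list(range(1, n + 1)),
            "tech_rep": [1] * n,
        }
    )
    af = pd.Series(amp, index=genes) if amp is not None else None
    return CtTable(ct=pd.DataFrame(ct, index=genes), samples=samples, amp_factor=af)


@pytest.fixture
def tiny_table():
    """3 genes x 3 samples from the hand-computed Delta-Ct example."""
    return make_table([[20, 20, 20], [21, 22, 23], [25, 25, 26]])


@pytest.fixture
def rng():
    return np.random.default_rng(20240219)
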