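import numpy as np
import pandas as pd
import pytest

from newsecm import IntensityMatrix, LfqSimConfig, simulate_lfq


def make_matrix(values, organisms=None, genes=None, samples_meta=None):
    """Small IntensityMatrix from a dict {sample_id: values}."""
    vdf = pd.DataFrame(values, dtype=float)
    n = len(vdf)
    vdf.index = [f"P{i}" for i in range(n)]
    proteins = pd.DataFrame({
        "gene": genes if genes is not None else [f"G{i}" for i in range(n)],
        "organism": organisms if organisms is not None else ["human"] * n,
    }, index=vdf.index)
    if samples_meta is None:
        samples_meta = {s: ("dECM-tumor", "GalNAz", "eluate")
                        for s in vdf.columns}
    samples = pd.DataFrame(
        [{"sample_id": s, "model": m, "treatment": t, "fraction": f}
         for s, (m, t, f) in samples_meta.items()]).set_index("sample_id")
    return IntensityMatrix(vdf, proteins, samples)


@pytest.fixture
def toy_matrix():
    """Two samples A=(2,3,5), B=(6,9,15) in one scope."""
    return make_matrix({"A": [2, 3, 5], "B": [6, 9, 15]})


@pytest.fixture
def small_lfq():
    cfg = LfqSimConfig(n_proteins_human=120, n_proteins_rat=40,
                       n_samples_per_group=3, censor_quantile=0.15, seed=42)
    return simulate_lfq(cfg)
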