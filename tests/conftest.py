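import numpy as np
import pytest

from otskit import load_pser_trna, read_element_catalog
from otskit import synthetic_data as sd


@pytest.fixture(scope="session")
def pser_trna():
    return load_pser_trna()


@pytest.fixture(scope="session")
def element_catalog():
    return read_element_catalog()


@pytest.fixture()
def noiseless_curve():
    """Flat at OD 0.01 until 2 h, then logistic mu=0.6/h toward capacity 1.0."""
    curve, truth = sd.simulate_growth_curve(
        od0=0.01, lag_h=2.0, mu=0.6, capacity=1.0, noise_sd=0.0, seed=0
    )
    return curve, truth


@pytest.fixture()
def toy_quant_table():
    """4 proteins x 3v3, complete, lognormal-free fixed values."""
    import pandas as pd
    from otskit import QuantTable

    rng = np.random.default_rng(42)
    base = rng.normal(25, 1.5, size=4)
    data = {"protein_id": [f"P{i}" for i in range(4)]}
    design = {}
    for cond, shift in (("A", 0.0), ("B", [0.0, 2.0, -1.0, 0.3])):
        for r in range(3):
            s = f"{cond}_{r + 1}"
            vals = base + np.asarray(shift) + rng.normal(0, 0.3, size=4)
            data[f"LFQ.{s}"] = np.exp2(vals)
            data[f"iBAQ.{s}"] = np.exp2(vals) / 10.0
            design[s] = cond
    return QuantTable(frame=pd.DataFrame(data), design=design)
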