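import numpy as np
import pandas as pd
import pytest

from gscdsrt import synthetic as syn


@pytest.fixture(scope="session")
def small_noiseless_screen():
    """3+4 cultures × 8 drugs, no well noise: fits must round-trip."""
    design = syn.ScreenDesign(n_multiregional=3, n_reference=4, n_drugs=8)
    plates, truth = syn.make_screen(
        design, syn.ScreenTruthConfig(noise_cv=0.0), seed=11)
    return design, plates, truth


@pytest.fixture()
def toy_plate():
    """One culture, one drug, 5 doses, exact half-max signal at 10 µM."""
    neg, pos = 1000.0, 0.0
    doses = np.geomspace(0.4, 250.0, 5)
    from gscdsrt.dose_response import logistic4
    inh = logistic4(np.log10(doses), 90.0, 0.0, 1.0, 1.0)
    rows = [("d1", float(d), "drug", neg - (y / 100.0) * (neg - pos))
            for d, y in zip(doses, inh)]
    rows += [("DMSO", 0.0, "neg_ctrl", neg)] * 4
    rows += [("benz", 100.0, "pos_ctrl", pos)] * 4
    plate = pd.DataFrame(rows, columns=["drug", "dose_uM", "well_type", "signal"])
    plate.insert(0, "culture", "C1")
    return plate


@pytest.fixture(scope="session")
def grouped_dss_matrix():
    """Deterministic 6-culture × 4-drug matrix with obvious group structure."""
    rng = np.random.default_rng(99)
    idx = ["MRa", "MRb", "MRc", "REFa", "REFb", "REFc"]
    mat = pd.DataFrame(rng.uniform(0, 30, (6, 4)), index=idx,
                       columns=[f"d{i}" for i in range(4)])
    return mat
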