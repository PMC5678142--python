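import numpy as np
import pytest

from kaspcall import CloneTruth, SimParams
from kaspcall.synthetic_data import simulate_panel_from_truths


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def default_params():
    return SimParams()


@pytest.fixture
def noise_free():
    return SimParams().noise_free()


@pytest.fixture
def diploid_truths():
    """One clone per compound diploid genotype, plus a 10-cell mixed well."""
    singles = {
        "wt_wt": ("WT", "WT"),
        "het": ("WT", "HDR"),
        "hom": ("HDR", "HDR"),
        "nhej_nhej": ("NHEJ", "NHEJ"),
        "hdr_nhej": ("HDR", "NHEJ"),
        "wt_nhej": ("WT", "NHEJ"),
    }
    truths = [CloneTruth(name, alleles) for name, alleles in singles.items()]
    truths.append(CloneTruth("multi10", tuple(["HDR"] + ["WT"] * 19)))
    return truths


@pytest.fixture
def noise_free_panel(diploid_truths, noise_free, rng):
    return simulate_panel_from_truths(diploid_truths, noise_free, rng)
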