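import numpy as np
import pytest

from eparscan import refdata, simdata
from eparscan.trees import Clade, HaplogroupTree


@pytest.fixture(scope="session")
def ltr6b_model():
    return refdata.default_ltr6b_model()


@pytest.fixture(scope="session")
def topology():
    return refdata.reference_topology()


@pytest.fixture(scope="session")
def str_panel():
    return refdata.default_str_panel()


@pytest.fixture(scope="session")
def noisy_cohort():
    """Moderate-noise cohort with inflated carrier frequencies for power."""
    spec = simdata.CohortSpec(
        n_males=800, n_females=800, freq_epar=0.05, freq_xdel_allele=0.02,
        noise_sd=0.05, seed=11,
    )
    return simdata.simulate_cohort(spec)


def random_tree(rng: np.random.Generator, n_tips: int) -> HaplogroupTree:
    """Random binary tree topology by sequential tip splitting."""
    root = Clade("t0")
    tips = [root]
    for i in range(1, n_tips):
        target = tips[rng.integers(len(tips))]
        left = Clade(target.label, parent=target)
        right = Clade(f"t{i}", parent=target)
        target.children = [left, right]
        target.label = f"n{i}"
        tips.remove(target)
        tips.extend([left, right])
    return HaplogroupTree(root)
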