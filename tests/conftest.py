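import numpy as np
import pytest

from sabrefit import (PAIR_REFERENCE_ESTIMATES, SHARED_REFERENCE_ESTIMATES,
                      StudyDesign, generate_study)


@pytest.fixture(scope="session")
def conc10():
    """10 log-spaced concentrations, 1 nM to 100 uM."""
    return np.logspace(-9, -4, 10)


@pytest.fixture(scope="session")
def neca_pair_noisefree(conc10):
    """Noise-free NECA N/X pair from the pairwise reference estimates."""
    truth = PAIR_REFERENCE_ESTIMATES["NECA"]
    design = StudyDesign(logKd={"NECA": truth["logKd"]}, gamma=truth["gamma"],
                         q=truth["q"], concentrations=conc10,
                         noise_sd=0.0, seed=0)
    return generate_study(design)


@pytest.fixture(scope="session")
def shared_study_noisefree(conc10):
    """Noise-free six-dataset study: shared gamma/q, per-agonist logKd."""
    design = StudyDesign(
        logKd={a: v["logKd"] for a, v in PAIR_REFERENCE_ESTIMATES.items()},
        gamma=SHARED_REFERENCE_ESTIMATES["gamma"],
        q=SHARED_REFERENCE_ESTIMATES["q"],
        concentrations=conc10, noise_sd=0.0, seed=0)
    return generate_study(design)
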