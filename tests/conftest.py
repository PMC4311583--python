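import pytest

from mediaopt import datasets
from mediaopt.rsm import anova, fit_quadratic


@pytest.fixture(scope="session")
def pb_study():
    """Bundled 12-run cellulase screening experiment (design, response)."""
    return datasets.load_pb_study()


@pytest.fixture(scope="session")
def ccd_study():
    """Bundled 20-run cellulase CCD experiment (design, response)."""
    return datasets.load_ccd_study()


@pytest.fixture(scope="session")
def ccd_fit(ccd_study):
    """Quadratic model + ANOVA fitted to the bundled CCD experiment."""
    design, response = ccd_study
    model = fit_quadratic(design, response)
    return model, anova(model, design, response)
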