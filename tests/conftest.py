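import numpy as np
import pytest

from combci import EstimateCI, clopper_pearson


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def hdv_cis():
    """The two reported prevalence intervals of the hepatitis-D worked
    example: HBsAg prevalence and anti-HDV prevalence among HBsAg+."""
    return (
        EstimateCI(lower=0.027, upper=0.050, level=0.95, point=0.035),
        EstimateCI(lower=0.036, upper=0.057, level=0.95, point=0.045),
    )


@pytest.fixture
def sars_cis():
    """Exact binomial CIs for the seroprevalence worked example:
    84/500 positives, 238/270 sensitivity panel, 82/88 specificity panel."""
    return (
        clopper_pearson(84, 500),
        clopper_pearson(238, 270),
        clopper_pearson(82, 88),
    )
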