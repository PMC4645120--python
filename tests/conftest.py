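import pytest

from birddose.community import build_site_year_table
from birddose.effects import ModelSpec, fit_effect_model
from birddose.simulate import make_study, simulate_glmm_dataset


@pytest.fixture(scope="session")
def glmm_data():
    """Site-year table drawn directly from the mixed-model generative truth."""
    return simulate_glmm_dataset(seed=11)


@pytest.fixture(scope="session")
def tnb_model(glmm_data):
    """Abundance GLMM fitted to the direct generative dataset."""
    return fit_effect_model(glmm_data, ModelSpec(response="TNB"))


@pytest.fixture(scope="session")
def study():
    """A full synthetic ecological study at the default design size."""
    return make_study(seed=1)


@pytest.fixture(scope="session")
def study_site_year(study):
    sy = build_site_year_table(study.census, doses=study.doses)
    return sy.merge(study.covariates, on=["site", "year"])
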