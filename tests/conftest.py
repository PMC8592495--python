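import dataclasses

import pytest

from frailmap import GeneratorConfig, generate_areas, generate_survey


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A reduced-size study: quick to generate, same structure as default."""
    return GeneratorConfig(n_respondents=2000, n_areas=20, seed=11)


@pytest.fixture(scope="session")
def small_survey(small_config):
    return generate_survey(small_config)


@pytest.fixture(scope="session")
def small_areas(small_config):
    return generate_areas(small_config)


@pytest.fixture(scope="session")
def complete_survey_config() -> GeneratorConfig:
    """Full response, no missingness: the clean-data benchmark."""
    return dataclasses.replace(
        GeneratorConfig(n_respondents=2000, n_areas=20, seed=11),
        nonresponse_target=0.0,
        item_missing_rate=0.0,
    )


@pytest.fixture(scope="session")
def complete_survey(complete_survey_config):
    survey, truth = generate_survey(complete_survey_config)
    return survey, truth
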