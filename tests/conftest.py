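import pytest

import cllburden as cb
from cllburden.config import ModelConfig


@pytest.fixture(scope="session")
def config() -> ModelConfig:
    return cb.default_config()


def with_strat(config: ModelConfig, **kw) -> ModelConfig:
    return config.model_copy(update={"strat": config.strat.model_copy(update=kw)})


def with_epi(config: ModelConfig, **kw) -> ModelConfig:
    return config.model_copy(
        update={"epidemiology": config.epidemiology.model_copy(update=kw)}
    )


@pytest.fixture(scope="session")
def short_config(config) -> ModelConfig:
    """Default parameters but a short 2000-2013 window for cheap engine runs."""
    return with_strat(config, report_start_year=2011, report_end_year=2013)
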