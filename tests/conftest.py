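"""Shared fixtures: small, fast synthetic configurations.

The full-scale study layout (142 weeks anchored 2018-01-05 with the
nine-week pulse) is exercised in the acceptance tests; unit tests mostly
use a shorter 60-week span with a mid-series pulse to keep model fits
cheap.
"""

from datetime import date

import pytest

from edseries import InterventionSpec, NoiseSpec, SyntheticConfig, TransferModelSpec


SHORT_WEEKS = 60
SHORT_ANCHOR = date(2018, 1, 5)
# week 40 of the short span starts 2018-10-05, a Friday
SHORT_PULSE_START = date(2018, 10, 5)


@pytest.fixture
def short_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_weeks=SHORT_WEEKS,
        intervention=InterventionSpec(
            kind="pulse",
            start_date=SHORT_PULSE_START,
            series_length=SHORT_WEEKS,
            n_weeks=6,
        ),
    )


@pytest.fixture
def default_config() -> SyntheticConfig:
    return SyntheticConfig()


def spec_for(truth, noise=NoiseSpec((1, 5)), burn_in=6) -> TransferModelSpec:
    return TransferModelSpec(
        noise=noise,
        include_control=True,
        intervention=tuple(truth.indicator),
        burn_in_weeks=burn_in,
    )
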