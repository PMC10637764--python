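from datetime import date

import pandas as pd
import pytest

from stripshade import StripLayout, day_context
from stripshade.synth import GrowthSpec, growth_height_series

#: Experimental site latitude (43 deg 16 min N) used throughout the tests.
SITE_LATITUDE = 43.267


@pytest.fixture(scope="session")
def layout_2m3s() -> StripLayout:
    return StripLayout()


@pytest.fixture(scope="session")
def layout_3m6s() -> StripLayout:
    return StripLayout(configuration="3M6S", n_maize_rows=3, n_soybean_rows=6)


@pytest.fixture(scope="session")
def midsummer_ctx():
    """Solar context for a mid-season day (July 20) at the site."""
    return day_context(date(2021, 7, 20).timetuple().tm_yday, SITE_LATITUDE)


@pytest.fixture(scope="session")
def growth_hms() -> pd.DataFrame:
    """Daily H_ms frame from the default synthetic growth curves (24 days)."""
    series, _ = growth_height_series(GrowthSpec())
    return series.frame()
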