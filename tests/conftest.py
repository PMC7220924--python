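import numpy as np
import pandas as pd
import pytest

from rwlr.synthetic import PrecipSeries, gen_precip, gen_scene_stack


def make_precip(depths, start="2001-01-01", station_id="T01") -> PrecipSeries:
    """PrecipSeries from a short pattern, padded with wet days to 365+."""
    depths = list(depths)
    if len(depths) < 365:
        depths = depths + [1.0] * (365 - len(depths))
    dates = pd.date_range(start, periods=len(depths), freq="D")
    return PrecipSeries(station_id=station_id, dates=dates,
                        precip_mm=np.asarray(depths, dtype=float))


@pytest.fixture(scope="session")
def precip_2yr():
    return gen_precip(730, seed=5)


@pytest.fixture(scope="session")
def noise_free_stack(precip_2yr):
    return gen_scene_stack(precip_2yr, noise_sd=0.0, seed=7)
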