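import numpy as np
import pandas as pd
import pytest

import forestcloud as fc
from forestcloud.timeutils import JJA


@pytest.fixture(scope="session")
def small_landcover():
    return fc.demo_landcover(40, 40)


@pytest.fixture(scope="session")
def jja_scene(small_landcover):
    """Two JJA seasons, 40x40, default enhancement, calm wind."""
    cfg = fc.SimConfig(years=2, months=JJA, seed=42)
    days = cfg.calendar().days()
    calm = pd.DataFrame({"u10": 0.0, "v10": 0.0}, index=days.normalize())
    truth = fc.simulate_truth(small_landcover, cfg, wind=calm)
    return truth


@pytest.fixture(scope="session")
def null_scene(small_landcover):
    """One JJA season with no forest enhancement (exchangeable landscape)."""
    cfg = fc.SimConfig(years=1, months=JJA, delta_forest_jja=0.0, seed=7)
    return fc.simulate_truth(small_landcover, cfg)


def make_mask_stack(flags, start="2004-06-01 06:00"):
    """Mask stack from a raw (time, y, x) flag array at 15-min cadence
    inside the daylight window (wraps to the next day after 17:45)."""
    flags = np.asarray(flags, dtype=np.uint8)
    nt = flags.shape[0]
    spd = 48
    t0 = pd.Timestamp(start)
    times = []
    for i in range(nt):
        day, slot = divmod(i, spd)
        times.append(t0 + pd.Timedelta(days=day) + pd.Timedelta(minutes=15 * slot))
    return fc.CloudMaskStack(pd.DatetimeIndex(times), flags)
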