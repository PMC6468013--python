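import numpy as np
import pandas as pd
import pytest

from herdtrack import synthetic as syn


@pytest.fixture(scope="session")
def small_landscape():
    return syn.simulate_landscape(1, extent=(0.0, 10.0, 0.0, 10.0))


@pytest.fixture(scope="session")
def migrant_truth():
    return syn.TrackTruth(
        animal_id="m1",
        sex="F",
        tactic="migrant",
        winter_center=(10.0, 10.0),
        summer_center=(25.0, 20.0),
        spring_theta=124.0,
        autumn_theta=260.0,
        spring_phi=3.0,
        autumn_phi=2.0,
        ou_sd=0.5,
    )


@pytest.fixture(scope="session")
def resident_truth():
    return syn.TrackTruth(
        animal_id="r1",
        sex="F",
        tactic="resident",
        winter_center=(10.0, 10.0),
        summer_center=(10.0, 10.0),
        spring_theta=124.0,
        autumn_theta=260.0,
        spring_phi=2.0,
        autumn_phi=2.0,
        ou_sd=0.5,
    )


def year_track(truth, seed, **kwargs):
    start = pd.Timestamp(year=truth.year, month=1, day=1, tz="UTC")
    end = pd.Timestamp(year=truth.year, month=12, day=31, hour=22, tz="UTC")
    return syn.simulate_track(truth, None, start, end, seed=seed, **kwargs)


@pytest.fixture(scope="session")
def migrant_track(migrant_truth):
    return year_track(migrant_truth, seed=3)


@pytest.fixture(scope="session")
def resident_track(resident_truth):
    return year_track(resident_truth, seed=7)


def straight_track(n=50, speed_kmh=2.0, interval_h=2.0, start="2010-05-01"):
    """Constant-velocity eastward track."""
    ts = pd.date_range(start, periods=n, freq=pd.Timedelta(hours=interval_h), tz="UTC")
    x = np.arange(n) * speed_kmh * interval_h
    return syn.Track(
        animal_id="s1",
        sex="F",
        brand="b",
        fixes=pd.DataFrame({"timestamp": ts, "x_km": x, "y_km": np.zeros(n)}),
        fix_interval_h=interval_h,
    )
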