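import numpy as np
import pandas as pd
import pytest

from woundkinetics import EllipseRelation


@pytest.fixture
def baboon_relation():
    """Day-1 width-length relation of wild-baboon natural wounds."""
    return EllipseRelation(a=0.121, b=3.963)


def make_trajectory(widths, times, individual="w1", species="baboon",
                    setting="experimental", replicate=1, kind="width"):
    """Tidy observation table for one wound trajectory."""
    return pd.DataFrame(
        {
            "individual_id": individual,
            "species": species,
            "setting": setting,
            "time_days": np.asarray(times, dtype=float),
            "kind": kind,
            "value": np.asarray(widths, dtype=float),
            "replicate": replicate,
        }
    )


@pytest.fixture
def make_traj():
    return make_trajectory


def make_linear_records(groups, seed=0, n_individuals=4, times=None,
                        noise_sd=0.0, re_slope_sd=0.0, re_int_sd=0.0):
    """Healing-record table with per-individual linear trajectories.

    ``groups`` maps group label -> population rate (mm/day).
    """
    rng = np.random.default_rng(seed)
    times = np.asarray([0, 2, 4, 6, 8, 10, 12, 14] if times is None else times,
                       dtype=float)
    rows = []
    for grp, rate in groups.items():
        for i in range(n_individuals):
            u1 = rng.normal(0, re_slope_sd) if re_slope_sd else 0.0
            u0 = rng.normal(0, re_int_sd) if re_int_sd else 0.0
            d = u0 + (rate + u1) * times
            if noise_sd:
                d = d + rng.normal(0, noise_sd, size=len(times))
            for t, v in zip(times, d):
                rows.append(
                    {
                        "individual_id": f"{grp}_{i}",
                        "species": grp,
                        "setting": "experimental",
                        "time_days": t,
                        "healing_distance_mm": v,
                        "replicate": 1,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def make_records():
    return make_linear_records
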