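import numpy as np
import pandas as pd
import pytest

from illusionephys import stimgen as sg
from illusionephys import synthetic as syn


@pytest.fixture(scope="session")
def geometry():
    return sg.DisplayGeometry(pixels_per_degree=4.0)


@pytest.fixture(scope="session")
def grid_layout():
    return sg.InducerLayout.grid3x3()


@pytest.fixture(scope="session")
def grating():
    return sg.GratingSpec(direction=90.0)


@pytest.fixture(scope="session")
def small_session():
    """A 30-unit, 30-trials/condition session shared across analysis tests."""
    trials = sg.condition_table(trials_per_condition=30, order_seed=11)
    units = syn.make_cohort(30, seed=12)
    bundle = syn.simulate_session(units, trials, seed=13, run_fraction=0.3)
    return bundle


def simulate_rect_spikes(
    presentations: pd.DataFrame,
    rf_center_cell: tuple[int, int],
    rf_sigma_cells: float = 1.0,
    amplitude: float = 60.0,
    baseline: float = 2.0,
    latency_ms: float = 40.0,
    seed: int = 0,
    unit_id: int = 0,
) -> pd.DataFrame:
    """Poisson spikes for a rectangle-mapping session with a Gaussian RF.

    The evoked rate for a presentation at grid cell (r, c) is
    ``amplitude * exp(-d^2 / (2 sigma^2))`` for 60 ms starting
    ``latency_ms`` after onset, on top of a homogeneous baseline.  The
    short evoked window keeps the next presentation's pre-onset baseline
    free of response bleed-through.
    """
    rng = np.random.default_rng(seed)
    onsets = presentations["onset_s"].to_numpy()
    ids = presentations["presentation"].to_numpy()
    r0, c0 = rf_center_cell

    # homogeneous baseline over the whole session; each spike is assigned
    # to the presentation with the nearest onset
    t0, t1 = onsets.min() - 0.1, onsets.max() + 0.1
    n_base = rng.poisson(baseline * (t1 - t0))
    t_base = np.sort(rng.uniform(t0, t1, size=n_base))
    nearest = np.clip(np.searchsorted(onsets + 0.1, t_base), 0, len(onsets) - 1)

    times = [t_base]
    trial = [ids[nearest]]
    for k, p in presentations.iterrows():
        d2 = (p["row"] - r0) ** 2 + (p["col"] - c0) ** 2
        evoked = amplitude * np.exp(-d2 / (2 * rf_sigma_cells**2))
        n_ev = rng.poisson(evoked * 0.06)
        t_ev = p["onset_s"] + latency_ms / 1000.0 + rng.uniform(0.0, 0.06, size=n_ev)
        times.append(t_ev)
        trial.append(np.full(n_ev, int(p["presentation"])))
    out = pd.DataFrame(
        {
            "unit_id": unit_id,
            "trial_id": np.concatenate(trial).astype(int),
            "t_s": np.concatenate(times),
        }
    )
    return out.sort_values("t_s", ignore_index=True)
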