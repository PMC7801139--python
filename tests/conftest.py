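import datetime as dt

import pytest

import worklife as wl


@pytest.fixture(scope="session")
def structure():
    return wl.build_transition_structure(wl.canonical_state_space())


@pytest.fixture(scope="session")
def default_sim():
    """Moderate simulated dataset under the default scenario."""
    return wl.simulate_population(wl.default_config(n_persons=500, seed=11))


@pytest.fixture(scope="session")
def default_trajectories(default_sim):
    cfg = default_sim.config
    return wl.assign_population(
        default_sim.persons, default_sim.episodes, (cfg.baseline_date, cfg.study_end_date)
    )


def make_episode(pid, kind, start, end=None):
    """Shorthand for an EpisodeRecord with ISO date strings."""
    s = dt.date.fromisoformat(start)
    e = dt.date.fromisoformat(end) if end else s
    return wl.EpisodeRecord(person_id=pid, episode_type=kind, start_date=s, end_date=e)
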