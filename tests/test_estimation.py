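"""Cox fits and Aalen-Johansen against independent oracles.

Oracles: a hand-coded loop-based Breslow partial likelihood maximized
numerically (scipy), lifelines on tie-free data (Efron equals Breslow
without ties), a subgroup Nelson-Aalen estimator, and a naive
matrix-product Aalen-Johansen implementation.
"""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import worklife as wl
from worklife.estimation import (
    StepCumHaz,
    TransitionCoxFit,
    aalen_johansen,
    fit_all_transitions,
    fit_transition_cox,
    to_transition_records,
)
from worklife.states import DEATH, WORK

from conftest import make_episode


# ---------------------------------------------------------------------------
# transition records


def _records_for(trajs, persons, structure, cols=()):
    return to_transition_records(trajs, persons, structure, cols)


def _persons_frame(rows):
    return pd.DataFrame(rows)


def test_work_only_followup_yields_six_censored_records(structure):
    person = {"person_id": 1, "birth_date": dt.date(1950, 6, 15)}
    window = (dt.date(2005, 1, 1), dt.date(2005, 12, 31))
    traj = wl.assign_daily_states(
        [make_episode(1, "earnings", "2005-01-01", "2005-12-31")], person, window
    )
    persons = _persons_frame([{"person_id": 1, "birth_date": person["birth_date"]}])
    rec = _records_for([traj], persons, structure)
    assert len(rec) == 6
    assert (rec["status"] == 0).all()
    assert (rec["from_state"] == WORK).all()
    assert sorted(rec["to_state"]) == sorted(
        t for _, t in structure.outgoing(WORK)
    )


def test_disability_retirement_sojourn_yields_two_records(structure):
    person = {"person_id": 3, "birth_date": dt.date(1947, 1, 20)}
    window = (dt.date(2005, 1, 1), dt.date(2005, 12, 31))
    traj = wl.assign_daily_states(
        [make_episode(3, "full_disability_pension", "2005-01-01", "2005-12-31")],
        person,
        window,
    )
    persons = _persons_frame([{"person_id": 3, "birth_date": person["birth_date"]}])
    rec = _records_for([traj], persons, structure)
    sub = rec[rec["from_state"] == "disability_retirement"]
    assert len(sub) == 2
    assert sorted(sub["to_state"]) == ["death", "retirement"]


def test_hand_fixture_records_match_sojourn_enumeration(structure):
    """Record list equals the by-hand enumeration sojourns x allowed exits."""
    window = (dt.date(2005, 1, 1), dt.date(2005, 12, 31))
    p3 = {"person_id": 3, "birth_date": dt.date(1947, 1, 20)}
    traj = wl.assign_daily_states(
        [
            make_episode(3, "earnings", "2005-01-01", "2005-02-28"),
            make_episode(3, "sickness_allowance_full", "2005-02-01", "2005-03-31"),
            make_episode(3, "full_disability_pension", "2005-05-01", "2005-08-31"),
            make_episode(3, "oldage_or_early_pension", "2005-09-01", "2005-12-31"),
            make_episode(3, "death", "2005-11-15"),
        ],
        p3,
        window,
    )
    persons = _persons_frame([{"person_id": 3, "birth_date": p3["birth_date"]}])
    rec = _records_for([traj], persons, structure)
    # sojourns: work(6) trwd(6) inactivity(6) disability_retirement(2) retirement(1)
    assert len(rec) == 21
    assert rec.groupby("from_state").size().to_dict() == {
        "work": 6,
        "time_restricted_work_disability": 6,
        "economic_inactivity": 6,
        "disability_retirement": 2,
        "retirement": 1,
    }
    # exactly one realized transition per non-terminal sojourn
    events = rec[rec["status"] == 1]
    assert list(zip(events["from_state"], events["to_state"])) == [
        ("work", "time_restricted_work_disability"),
        ("time_restricted_work_disability", "economic_inactivity"),
        ("economic_inactivity", "disability_retirement"),
        ("disability_retirement", "retirement"),
        ("retirement", "death"),
    ]
    # person-time conservation in age units
    for _, g in rec.groupby("from_state"):
        assert (g["exit_age"] > g["entry_age"]).all()
    sojourn_years = rec.drop_duplicates("from_state")  # one sojourn per state here
    total = (sojourn_years["exit_age"] - sojourn_years["entry_age"]).sum()
    # at-risk time stops when death (the absorbing single-day interval) begins
    assert total == pytest.approx((traj.n_days - 1) / 365.25, abs=1e-9)


# ---------------------------------------------------------------------------
# Cox partial likelihood


def naive_breslow_loglik(entry, exit_, status, z, beta):
    """Loop-based left-truncated Breslow partial log-likelihood."""
    beta = np.atleast_1d(beta)
    ll = 0.0
    for t in np.unique(exit_[status == 1]):
        ev = (exit_ == t) & (status == 1)
        risk = (entry < t) & (t <= exit_)
        ll += (z[ev] @ beta).sum() - ev.sum() * np.log(np.exp(z[risk] @ beta).sum())
    return ll


def small_fixture():
    entry = np.array([0, 0, 0, 0, 0.5, 0.5, 1, 1.0]) + 50
    exit_ = np.array([1, 2, 2, 3, 2, 3, 2.5, 3.5]) + 50
    status = np.array([1, 1, 0, 1, 1, 0, 1, 0])
    z = np.array([0, 1, 0, 1, 1, 0, 0, 1.0])
    return entry, exit_, status, z


def _frame(entry, exit_, status, z):
    return pd.DataFrame(
        {
            "person_id": np.arange(len(entry)),
            "transition_id": 1,
            "from_state": "work",
            "to_state": "death",
            "entry_age": entry,
            "exit_age": exit_,
            "status": status,
            "z": z,
        }
    )


def test_beta_matches_brute_force_partial_likelihood():
    entry, exit_, status, z = small_fixture()
    fit = fit_transition_cox(_frame(entry, exit_, status, z), ["z"])
    res = minimize(
        lambda b: -naive_breslow_loglik(entry, exit_, status, z[:, None], b),
        x0=[0.0],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14},
    )
    assert fit.beta[0] == pytest.approx(res.x[0], abs=1e-6)
    assert fit.loglik == pytest.approx(-res.fun, abs=1e-9)


def test_breslow_baseline_matches_hand_computation():
    """dA0(t) = d_t / sum over the risk set of exp(beta z)."""
    entry, exit_, status, z = small_fixture()
    fit = fit_transition_cox(_frame(entry, exit_, status, z), ["z"])
    r = np.exp(z * fit.beta[0])
    for age, inc in zip(fit.event_ages, fit.base_increments):
        ev = (exit_ == age) & (status == 1)
        risk = (entry < age) & (age <= exit_)
        assert inc == pytest.approx(ev.sum() / r[risk].sum(), rel=1e-12)


def test_identical_covariates_give_zero_beta():
    entry, exit_, status, z = small_fixture()
    fit = fit_transition_cox(_frame(entry, exit_, status, np.ones_like(z)), ["z"])
    assert fit.beta[0] == 0.0


def test_zero_events_degenerates_cleanly(caplog):
    entry, exit_, status, z = small_fixture()
    fit = fit_transition_cox(_frame(entry, exit_, 0 * status, z), ["z"])
    assert fit.n_events == 0
    assert fit.beta[0] == 0.0
    assert fit.event_ages.size == 0
    assert fit.cumhaz([0.0]).at(60.0) == 0.0


def test_case_weights_equal_record_replication():
    """Weight k must reproduce the fit on k copied records (bootstrap contract)."""
    entry, exit_, status, z = small_fixture()
    df = _frame(entry, exit_, status, z)
    w = np.array([2, 1, 0, 1, 3, 1, 2, 1.0])
    expanded = df.loc[df.index.repeat(w.astype(int))].reset_index(drop=True)
    fit_w = fit_transition_cox(df, ["z"], weights=w)
    fit_e = fit_transition_cox(expanded, ["z"])
    assert fit_w.beta[0] == pytest.approx(fit_e.beta[0], abs=1e-9)
    assert np.allclose(fit_w.base_increments, fit_e.base_increments)


def test_matches_lifelines_on_tie_free_data():
    """Without ties, Breslow and Efron coincide: cross-check vs lifelines."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(21)
    n = 400
    z = rng.integers(0, 2, n).astype(float)
    entry = 50 + rng.uniform(0, 1, n)
    t = entry + rng.exponential(1.0 / (0.3 * np.exp(0.7 * z)))
    cens = entry + 4.0
    exit_ = np.minimum(t, cens)
    status = (t <= cens).astype(int)
    df = _frame(entry, exit_, status, z)
    fit = fit_transition_cox(df, ["z"])
    cph = lifelines.CoxPHFitter()
    cph.fit(
        df.rename(columns={"exit_age": "T", "status": "E"})[["T", "E", "z", "entry_age"]],
        duration_col="T",
        event_col="E",
        entry_col="entry_age",
    )
    assert fit.beta[0] == pytest.approx(cph.params_["z"], abs=1e-5)
    assert fit.se[0] == pytest.approx(cph.standard_errors_["z"], abs=1e-5)


def test_recovers_true_hazard_ratio_two_groups():
    """Simulated two-group exponential data with HR 2: exp(beta) within 3 SE."""
    config = wl.default_config(
        n_persons=40_000,
        seed=17,
        intensities={(WORK, DEATH): 0.05},
        effects={(WORK, DEATH): {"class_manual": np.log(2.0)}},
        class_distribution={"manual": 0.5, "upper_non_manual": 0.5},
        class_occupations={"manual": ("9330",), "upper_non_manual": ("2310",)},
        overlap_rate=0.0,
    )
    data = wl.simulate_population(config)
    persons = wl.add_design_columns(data.persons)
    structure = wl.build_transition_structure(wl.canonical_state_space())
    rec = to_transition_records(data.latent, persons, structure, ["class_manual"])
    sub = rec[rec["to_state"] == DEATH].reset_index(drop=True)
    fit = fit_transition_cox(sub, ["class_manual"])
    hr = np.exp(fit.beta[0])
    se_hr = hr * fit.se[0]
    assert abs(hr - 2.0) < 3 * se_hr


def test_adjusted_cumhaz_reference_and_doubling():
    fit = TransitionCoxFit(
        transition_id=1,
        from_state="work",
        to_state="death",
        cov_names=("z",),
        beta=np.array([np.log(2.0)]),
        se=np.array([0.1]),
        event_ages=np.array([51.0, 52.0, 55.0]),
        base_increments=np.array([0.1, 0.05, 0.2]),
        n_events=3,
        loglik=0.0,
    )
    ref = wl.adjusted_cumhaz(fit, [0.0])
    assert np.allclose(ref.increments, fit.base_increments)
    doubled = wl.adjusted_cumhaz(fit, [1.0])
    assert np.allclose(doubled.increments, 2 * fit.base_increments)
    assert doubled.at(53.0) == pytest.approx(2 * (0.1 + 0.05))
    with pytest.raises(ValueError):
        wl.adjusted_cumhaz(fit, [1.0, 0.0])


def test_adjusted_cumhaz_matches_subgroup_nelson_aalen():
    """A(t|z=1) from the Cox fit tracks the Nelson-Aalen estimate computed
    on the exposed subgroup alone, within that estimate's sampling error."""
    config = wl.default_config(
        n_persons=20_000,
        seed=19,
        intensities={(WORK, DEATH): 0.06},
        effects={(WORK, DEATH): {"class_manual": 0.5}},
        class_distribution={"manual": 0.5, "upper_non_manual": 0.5},
        class_occupations={"manual": ("9330",), "upper_non_manual": ("2310",)},
        overlap_rate=0.0,
    )
    data = wl.simulate_population(config)
    persons = wl.add_design_columns(data.persons)
    structure = wl.build_transition_structure(wl.canonical_state_space())
    rec = to_transition_records(data.latent, persons, structure, ["class_manual"])
    sub = rec[rec["to_state"] == DEATH].reset_index(drop=True)
    fit = fit_transition_cox(sub, ["class_manual"])
    adj = wl.adjusted_cumhaz(fit, [1.0])

    grp = sub[sub["class_manual"] == 1.0]
    entry = grp["entry_age"].to_numpy()
    exit_ = grp["exit_age"].to_numpy()
    status = grp["status"].to_numpy()
    for t in (55.0, 60.0):
        na = var = 0.0
        for u in np.unique(exit_[(status == 1) & (exit_ <= t)]):
            d = ((exit_ == u) & (status == 1)).sum()
            y = ((entry < u) & (u <= exit_)).sum()
            na += d / y
            var += d / y**2
        assert abs(adj.at(t) - na) < 3 * np.sqrt(var)


# ---------------------------------------------------------------------------
# Aalen-Johansen


def naive_aalen_johansen(trajs, structure, s, horizon):
    """Independent matrix-product estimator from sojourn counts."""
    states = structure.space.states
    n = len(states)
    idx = {st: i for i, st in enumerate(states)}
    sojourns = []  # (from, entry, exit, to or None)
    for traj in trajs:
        entry_days = (traj.baseline_date - traj.birth_date).days
        iv = traj.intervals
        for i, (state, a, b) in enumerate(iv):
            if state in structure.space.absorbing:
                continue
            t0 = max((entry_days + a) / 365.25, 50.0)
            if i + 1 < len(iv):
                t1 = (entry_days + iv[i + 1][1]) / 365.25
                to = iv[i + 1][0]
            else:
                t1 = min((entry_days + b + 1) / 365.25, 63.0)
                to = None
            if t1 > t0:
                sojourns.append((state, t0, t1, to))
    times = sorted(
        {t1 for _, _, t1, to in sojourns if to is not None and s < t1 <= horizon}
    )
    P = np.eye(n)
    for t in times:
        dA = np.zeros((n, n))
        for j, state in enumerate(states):
            at_risk = sum(1 for f, t0, t1, _ in sojourns if f == state and t0 < t <= t1)
            if at_risk == 0:
                continue
            for f, t0, t1, to in sojourns:
                if f == state and t1 == t and to is not None:
                    dA[j, idx[to]] += 1.0 / at_risk
        np.fill_diagonal(dA, -dA.sum(axis=1))
        P = P @ (np.eye(n) + dA)
    return P


def test_identity_when_no_events(structure):
    person = {"person_id": 1, "birth_date": dt.date(1950, 6, 15)}
    window = (dt.date(2005, 1, 1), dt.date(2005, 12, 31))
    traj = wl.assign_daily_states(
        [make_episode(1, "earnings", "2005-01-01", "2005-12-31")], person, window
    )
    persons = _persons_frame([{"person_id": 1, "birth_date": person["birth_date"]}])
    rec = _records_for([traj], persons, structure)
    fits = fit_all_transitions(rec, structure)
    P = aalen_johansen(fits, structure)
    assert P.grid.tolist() == [50.0]
    assert np.array_equal(P.matrices[0], np.eye(7))


def test_pooled_estimator_equals_naive_implementation(default_sim, default_trajectories, structure):
    """With beta = 0 (no covariates) the product-integral estimator must
    coincide exactly with the naive nonparametric implementation."""
    trajs = default_trajectories[:20]
    persons = default_sim.persons[default_sim.persons["person_id"].isin(
        [t.person_id for t in trajs]
    )]
    rec = _records_for(trajs, persons, structure)
    fits = fit_all_transitions(rec, structure)
    P = aalen_johansen(fits, structure)
    expected = naive_aalen_johansen(trajs, structure, 50.0, 63.0)
    assert np.allclose(P.matrices[-1], expected, atol=1e-12)


def test_row_stochastic_and_bounded(default_sim, default_trajectories, structure):
    rec = _records_for(default_trajectories, default_sim.persons, structure)
    fits = fit_all_transitions(rec, structure)
    P = aalen_johansen(fits, structure)
    assert np.abs(P.matrices.sum(axis=2) - 1).max() < 1e-10
    assert P.matrices.min() >= 0.0
    assert P.matrices.max() <= 1.0 + 1e-12
    # absorbing rows stay unit vectors
    death = list(P.states).index("death")
    assert np.allclose(P.matrices[:, death, :], np.eye(7)[death])


def test_chapman_kolmogorov_on_grid(default_sim, default_trajectories, structure):
    """P(s,u) P(u,t) = P(s,t) exactly for the product-integral estimator."""
    rec = _records_for(default_trajectories, default_sim.persons, structure)
    fits = fit_all_transitions(rec, structure)
    P = aalen_johansen(fits, structure)
    u = P.grid[len(P.grid) // 2]
    Pu = aalen_johansen(fits, structure, s=float(u))
    left = P.at(u) @ Pu.at(63.0)
    assert np.allclose(left, P.at(63.0), atol=1e-10)


def test_step_cumhaz_evaluation():
    f = StepCumHaz(np.array([51.0, 52.0]), np.array([0.1, 0.2]))
    assert f.at(50.5) == 0.0
    assert f.at(51.0) == pytest.approx(0.1)
    assert f.at(60.0) == pytest.approx(0.3)
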