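"""Multistate estimation: transition records, Cox fits, Aalen-Johansen.

The statistical engine behind the working-life-expectancy analysis.
Daily-state trajectories are expanded into counting-process records
(one record per sojourn per allowed exit, the competing-risks "long
format"), a separate Cox proportional-hazards model is fitted for each
allowed transition with age as the underlying time axis and delayed
entry at the baseline age (left truncation), and the covariate-adjusted
cumulative transition hazards are composed into transition-probability
matrices by the Aalen-Johansen product integral

    P(s, t) = prod_{s < u <= t} (I + dA(u)),

where dA(u) has the adjusted hazard increments off-diagonal and minus
their row sums on the diagonal.  The Markov assumption applies: the
hazard of leaving a state depends only on the current state, current
age, and baseline covariates.

Ties are handled with the Breslow approximation and the baseline
cumulative hazard is the Breslow estimator, so the two compose exactly.
Case weights are supported throughout (the person-level bootstrap
reweights records instead of copying them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assign import DataError, StateTrajectory
from .states import ConfigurationError, TransitionStructure

log = logging.getLogger(__name__)

START_AGE = 50.0
HORIZON_AGE = 63.0


class EstimationError(RuntimeError):
    """Cox fit failed to converge."""


# ---------------------------------------------------------------------------
# counting-process data preparation


def to_transition_records(
    trajectories: Sequence[StateTrajectory],
    persons: pd.DataFrame,
    structure: TransitionStructure,
    covariate_columns: Sequence[str] = (),
) -> pd.DataFrame:
    """Expand trajectories into competing-risks transition records.

    Each sojourn in a non-absorbing state contributes one record per
    allowed outgoing transition: status 1 for the transition that
    occurred at the sojourn's exit age, 0 for the others (all 0 when the
    sojourn ends by censoring).  Ages are fractional years (days alive /
    365.25); entry is delayed at the age on the first sojourn day and
    censoring is clipped at age 63.

    Returns a DataFrame with columns person_id, transition_id,
    from_state, to_state, entry_age, exit_age, status, plus the
    requested covariate columns copied from ``persons``.
    """
    cov = persons.set_index("person_id")
    missing = [c for c in covariate_columns if c not in cov.columns]
    if missing:
        raise ConfigurationError(f"persons table lacks covariate columns {missing}")

    pid_col, tid_col, frm_col, to_col = [], [], [], []
    entry_col, exit_col, status_col = [], [], []

    for traj in trajectories:
        iv = traj.intervals
        entry_days = (traj.baseline_date - traj.birth_date).days
        for i, (state, a, b) in enumerate(iv):
            if state in structure.space.absorbing:
                continue
            outgoing = structure.outgoing(state)
            if not outgoing:
                continue
            t0 = (entry_days + a) / 365.25
            if i + 1 < len(iv):
                nxt = iv[i + 1][0]
                t1 = (entry_days + iv[i + 1][1]) / 365.25
                if not structure.is_allowed(state, nxt):
                    raise DataError(
                        f"person {traj.person_id}: disallowed transition "
                        f"{state} -> {nxt}"
                    )
                event_to = nxt
            else:
                t1 = min((entry_days + b + 1) / 365.25, HORIZON_AGE)
                event_to = None
            t0 = max(t0, START_AGE)
            if t1 <= t0:
                continue
            for tid, to in outgoing:
                pid_col.append(traj.person_id)
                tid_col.append(tid)
                frm_col.append(state)
                to_col.append(to)
                entry_col.append(t0)
                exit_col.append(t1)
                status_col.append(1 if to == event_to else 0)

    records = pd.DataFrame(
        {
            "person_id": pid_col,
            "transition_id": np.asarray(tid_col, dtype=int),
            "from_state": frm_col,
            "to_state": to_col,
            "entry_age": np.asarray(entry_col, dtype=float),
            "exit_age": np.asarray(exit_col, dtype=float),
            "status": np.asarray(status_col, dtype=int),
        }
    )
    for c in covariate_columns:
        records[c] = cov[c].reindex(records["person_id"]).to_numpy(dtype=float)
    return records


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties, left truncation, case weights)


class _RiskSums:
    """Suffix-sum machinery for risk-set aggregates at event times.

    For quantity q_i, returns sum over the risk set {i: entry_i < t <= exit_i}
    as (suffix over exit >= t) - (suffix over entry >= t).
    """

    def __init__(self, entry: np.ndarray, exit_: np.ndarray):
        self.exit_order = np.argsort(exit_, kind="stable")
        self.entry_order = np.argsort(entry, kind="stable")
        self.sorted_exit = exit_[self.exit_order]
        self.sorted_entry = entry[self.entry_order]

    def at(self, q: np.ndarray, times: np.ndarray) -> np.ndarray:
        # q shape (n, ...) -> result (len(times), ...)
        suf_exit = np.cumsum(q[self.exit_order][::-1], axis=0)[::-1]
        suf_entry = np.cumsum(q[self.entry_order][::-1], axis=0)[::-1]
        zero = np.zeros_like(q[:1])
        suf_exit = np.concatenate([suf_exit, zero])
        suf_entry = np.concatenate([suf_entry, zero])
        ie = np.searchsorted(self.sorted_exit, times, side="left")
        ia = np.searchsorted(self.sorted_entry, times, side="left")
        return suf_exit[ie] - suf_entry[ia]


@dataclass
class TransitionCoxFit:
    """One transition's Cox fit: coefficients and Breslow baseline.

    ``event_ages`` are the distinct ages with (positively weighted)
    events; ``base_increments[l]`` is the baseline cumulative-hazard jump
    dA0 at ``event_ages[l]``.
    """

    transition_id: int
    from_state: str
    to_state: str
    cov_names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    event_ages: np.ndarray
    base_increments: np.ndarray
    n_events: float
    loglik: float

    def linear_predictor(self, profile: Sequence[float]) -> float:
        z = np.asarray(profile, dtype=float)
        if z.shape != self.beta.shape:
            raise ValueError(
                f"profile has {z.size} entries, model has {self.beta.size} covariates"
            )
        return float(self.beta @ z)

    def adjusted_increments(self, profile: Sequence[float]) -> np.ndarray:
        """Hazard increments under proportional adjustment exp(beta.z)."""
        return self.base_increments * np.exp(self.linear_predictor(profile))

    def cumhaz(self, profile: Sequence[float]) -> "StepCumHaz":
        return StepCumHaz(self.event_ages, self.adjusted_increments(profile))


@dataclass
class StepCumHaz:
    """Nondecreasing step function A(t) = sum of increments at ages <= t."""

    ages: np.ndarray
    increments: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.increments = np.asarray(self.increments, dtype=float)
        self._cum = np.cumsum(self.increments)

    def at(self, t) -> np.ndarray | float:
        idx = np.searchsorted(self.ages, np.asarray(t, dtype=float), side="right")
        cum = np.concatenate([[0.0], self._cum])
        out = cum[idx]
        return float(out) if np.ndim(t) == 0 else out


def adjusted_cumhaz(fit: TransitionCoxFit, profile: Sequence[float]) -> StepCumHaz:
    """A_k(t | z) = A0_k(t) * exp(beta . z)."""
    return fit.cumhaz(profile)


def fit_transition_cox(
    records: pd.DataFrame,
    covariate_columns: Sequence[str] = (),
    weights: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> TransitionCoxFit:
    """Fit one transition's Cox model by Newton-Raphson.

    ``records`` holds that transition's competing-risks records
    (entry_age, exit_age, status, covariates).  The partial likelihood
    uses Breslow tie handling; the risk set at age t is
    {i: entry_age_i < t <= exit_age_i} (delayed entry).  ``weights`` are
    nonnegative case weights (default 1), used both in the likelihood
    and in the Breslow baseline.

    With zero (weighted) events the fit degenerates to beta = 0 with an
    identically-zero baseline and a logged warning.
    """
    tid = int(records["transition_id"].iloc[0]) if len(records) else 0
    frm = records["from_state"].iloc[0] if len(records) else ""
    to = records["to_state"].iloc[0] if len(records) else ""
    cov_names = tuple(covariate_columns)
    p = len(cov_names)

    entry = records["entry_age"].to_numpy(dtype=float)
    exit_ = records["exit_age"].to_numpy(dtype=float)
    status = records["status"].to_numpy(dtype=int)
    z = (
        records[list(cov_names)].to_numpy(dtype=float)
        if p
        else np.empty((len(records), 0))
    )
    w = (
        np.ones(len(records), dtype=float)
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    if (w < 0).any():
        raise ValueError("negative case weights")
    live = w > 0
    entry, exit_, status, z, w = entry[live], exit_[live], status[live], z[live], w[live]
    if np.any(entry >= exit_):
        raise DataError("records with entry_age >= exit_age")

    ev = status == 1
    if not np.any(ev):
        log.warning("transition %s (%s -> %s): zero events, beta fixed at 0", tid, frm, to)
        return TransitionCoxFit(
            transition_id=tid,
            from_state=frm,
            to_state=to,
            cov_names=cov_names,
            beta=np.zeros(p),
            se=np.full(p, np.nan),
            event_ages=np.empty(0),
            base_increments=np.empty(0),
            n_events=0.0,
            loglik=0.0,
        )

    # center covariates: the partial likelihood is invariant to location
    # shifts, and centering keeps exp(eta) well scaled under separation
    zbar0 = (w[:, None] * z).sum(axis=0) / w.sum() if p else np.zeros(0)
    z = z - zbar0

    times, inv = np.unique(exit_[ev], return_inverse=True)
    d = np.bincount(inv, weights=w[ev], minlength=len(times))  # weighted tied events
    s_ev = np.zeros((len(times), p))
    for j in range(p):
        s_ev[:, j] = np.bincount(inv, weights=(w[ev] * z[ev, j]), minlength=len(times))
    risk = _RiskSums(entry, exit_)

    BETA_BOUND = 20.0  # |log HR| beyond this is numerically infinite

    beta = np.zeros(p)

    def loglik_grad_info(b):
        # clip the linear predictor: under monotone likelihood (separation)
        # beta diverges and exp would overflow long before ll stops improving
        r = w * np.exp(np.clip(z @ b, -500, 500))
        s0 = risk.at(r, times)
        rz = r[:, None] * z
        s1 = risk.at(rz, times) if p else np.zeros((len(times), 0))
        rzz = rz[:, :, None] * z[:, None, :] if p else np.zeros((len(z), 0, 0))
        s2 = risk.at(rzz, times) if p else np.zeros((len(times), 0, 0))
        if np.any(~np.isfinite(s0)) or np.any(s0 <= 0):
            # S0 > 0 holds mathematically (the event itself is at risk); a
            # nonpositive value is suffix-sum cancellation at an extreme
            # beta -- signal the caller to shorten the step
            return -np.inf, None, None, None
        ll = float(np.sum(s_ev @ b) - d @ np.log(s0))
        zbar = s1 / s0[:, None] if p else s1
        grad = s_ev.sum(axis=0) - (d[:, None] * zbar).sum(axis=0)
        info = np.zeros((p, p))
        if p:
            info = np.einsum("l,ljk->jk", d, s2 / s0[:, None, None]) - np.einsum(
                "l,lj,lk->jk", d, zbar, zbar
            )
        return ll, grad, info, s0

    ll, grad, info, s0 = loglik_grad_info(beta)
    if not np.isfinite(ll):
        raise EstimationError("empty risk set at an event age")
    if p:
        for it in range(max_iter):
            if np.max(np.abs(grad)) < 1e-9:
                break
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, grad, rcond=None)[0]
            if grad @ step <= 1e-12:
                # singular information (separation): Newton direction carries
                # no ascent; fall back to the gradient
                step = grad
            scale = 1.0
            improved = False
            for _ in range(30):
                new_beta = np.clip(beta + scale * step, -BETA_BOUND, BETA_BOUND)
                new_ll, new_grad, new_info, new_s0 = loglik_grad_info(new_beta)
                if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                    improved = True
                    break
                scale /= 2
            if not improved:
                # the likelihood is numerically flat in every ascent
                # direction: treat as a (possibly monotone) optimum
                log.warning(
                    "transition %s: partial likelihood flat at loglik %.6g, "
                    "accepting current estimate",
                    tid,
                    ll,
                )
                break
            converged = np.max(np.abs(scale * step)) < tol
            plateaued = abs(new_ll - ll) < 1e-9 * (abs(ll) + 1.0)
            beta, ll, grad, info, s0 = new_beta, new_ll, new_grad, new_info, new_s0
            if converged:
                break
            if np.max(np.abs(beta)) >= BETA_BOUND:
                log.warning(
                    "transition %s: coefficient(s) at the +/-%.0f bound "
                    "(monotone likelihood), estimate truncated",
                    tid,
                    BETA_BOUND,
                )
                break
            if plateaued:
                # ll has saturated; if beta is still drifting outward this is
                # a monotone likelihood (effectively infinite estimate)
                if np.max(np.abs(grad)) > 1e-6 and np.max(np.abs(beta)) > 10.0:
                    log.warning(
                        "transition %s: partial likelihood is monotone, "
                        "coefficient(s) effectively infinite (max |beta| = %.1f)",
                        tid,
                        float(np.max(np.abs(beta))),
                    )
                break
        else:
            raise EstimationError(
                f"transition {tid}: no convergence in {max_iter} iterations "
                f"(max |grad| = {np.max(np.abs(grad)):.3g})"
            )

    if p:
        try:
            var = np.diag(np.linalg.inv(info))
            se = np.where(var > 0, np.sqrt(np.where(var > 0, var, 1.0)), np.nan)
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    else:
        se = np.empty(0)

    # Breslow baseline at the reference profile z = 0 (original scale):
    # S0 was computed on centered covariates, so rescale by exp(-zbar.beta)
    base_inc = (d / s0) * np.exp(-float(zbar0 @ beta)) if p else d / s0
    return TransitionCoxFit(
        transition_id=tid,
        from_state=frm,
        to_state=to,
        cov_names=cov_names,
        beta=beta,
        se=se,
        event_ages=times,
        base_increments=base_inc,
        n_events=float(d.sum()),
        loglik=ll,
    )


def fit_all_transitions(
    records: pd.DataFrame,
    structure: TransitionStructure,
    covariate_columns: Sequence[str] = (),
    person_weights: Mapping | pd.Series | None = None,
) -> dict[int, TransitionCoxFit]:
    """Fit every allowed transition's Cox model from pooled records.

    Transitions with no records or no events get the degenerate
    zero-event fit (identity contribution to the product integral).
    ``person_weights`` maps person_id to a bootstrap multiplicity.
    """
    fits: dict[int, TransitionCoxFit] = {}
    w_all = None
    if person_weights is not None:
        pw = pd.Series(person_weights)
        w_all = pw.reindex(records["person_id"]).fillna(0.0).to_numpy(dtype=float)
    grouped = dict(tuple(records.groupby("transition_id", sort=True)))
    for i, (frm, to) in enumerate(structure.transitions):
        tid = i + 1
        sub = grouped.get(tid)
        if sub is None or not len(sub):
            fits[tid] = TransitionCoxFit(
                transition_id=tid,
                from_state=frm,
                to_state=to,
                cov_names=tuple(covariate_columns),
                beta=np.zeros(len(covariate_columns)),
                se=np.full(len(covariate_columns), np.nan),
                event_ages=np.empty(0),
                base_increments=np.empty(0),
                n_events=0.0,
                loglik=0.0,
            )
            continue
        w = w_all[sub.index.to_numpy()] if w_all is not None else None
        fits[tid] = fit_transition_cox(sub, covariate_columns, weights=w)
    return fits


def fits_to_frame(fits: Mapping[int, TransitionCoxFit]) -> pd.DataFrame:
    """Tidy coefficient table (one row per transition x covariate)."""
    rows = []
    for tid in sorted(fits):
        f = fits[tid]
        if not f.cov_names:
            rows.append(
                {
                    "transition_id": tid,
                    "from_state": f.from_state,
                    "to_state": f.to_state,
                    "covariate": None,
                    "coef": np.nan,
                    "se": np.nan,
                    "hr": np.nan,
                    "n_events": f.n_events,
                }
            )
        for name, b, s in zip(f.cov_names, f.beta, f.se):
            rows.append(
                {
                    "transition_id": tid,
                    "from_state": f.from_state,
                    "to_state": f.to_state,
                    "covariate": name,
                    "coef": b,
                    "se": s,
                    "hr": np.exp(b),
                    "n_events": f.n_events,
                }
            )
    return pd.DataFrame(rows)


def baselines_to_frame(fits: Mapping[int, TransitionCoxFit]) -> pd.DataFrame:
    """Long table of Breslow baseline cumulative hazards (reference profile)."""
    rows = []
    for tid in sorted(fits):
        f = fits[tid]
        cum = np.cumsum(f.base_increments)
        for age, inc, c in zip(f.event_ages, f.base_increments, cum):
            rows.append(
                {
                    "transition_id": tid,
                    "from_state": f.from_state,
                    "to_state": f.to_state,
                    "age": age,
                    "increment": inc,
                    "cumhaz": c,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["transition_id", "from_state", "to_state", "age", "increment", "cumhaz"],
    )


# ---------------------------------------------------------------------------
# Aalen-Johansen product integral


@dataclass
class TransitionProbabilityMatrix:
    """P(s, t) on the pooled event-age grid for one covariate profile.

    ``grid[0] == s`` with ``matrices[0]`` the identity; ``matrices[i]``
    is P(s, grid[i]).
    """

    states: tuple[str, ...]
    start_age: float
    horizon: float
    grid: np.ndarray
    matrices: np.ndarray
    profile: tuple[float, ...] = ()

    def at(self, t: float) -> np.ndarray:
        """P(s, t) — right-continuous step interpolation on the grid."""
        if t < self.start_age:
            raise ValueError(f"t={t} precedes start age {self.start_age}")
        idx = int(np.searchsorted(self.grid, t, side="right")) - 1
        return self.matrices[idx]


def aalen_johansen(
    fits: Mapping[int, TransitionCoxFit],
    structure: TransitionStructure,
    profile: Sequence[float] = (),
    s: float = START_AGE,
    horizon: float = HORIZON_AGE,
    cap_increments: bool = True,
) -> TransitionProbabilityMatrix:
    """Product-integral transition probabilities from adjusted hazards.

    At each pooled event age u in (s, horizon], the increment matrix
    dA(u) carries each transition's adjusted hazard jump off-diagonal
    and minus the row sum on the diagonal; P accumulates as
    P <- P (I + dA(u)).  Rows of I + dA sum to one by construction, so
    every P is row-stochastic without renormalization.

    If a row's off-diagonal increments at some age sum above 1 (possible
    under extreme covariate profiles), they are scaled down so the
    diagonal stays at 0, with a warning — or an error is raised when
    ``cap_increments`` is False.
    """
    states = structure.space.states
    n = len(states)
    sidx = {st: i for i, st in enumerate(states)}

    pooled: list[np.ndarray] = []
    per_tid: list[tuple[int, int, np.ndarray, np.ndarray]] = []
    for tid, fit in fits.items():
        if fit.event_ages.size == 0:
            continue
        inc = fit.adjusted_increments(profile)
        mask = (fit.event_ages > s) & (fit.event_ages <= horizon)
        if not mask.any():
            continue
        ages = fit.event_ages[mask]
        pooled.append(ages)
        per_tid.append((sidx[fit.from_state], sidx[fit.to_state], ages, inc[mask]))

    grid_events = (
        np.unique(np.concatenate(pooled)) if pooled else np.empty(0, dtype=float)
    )
    m = len(grid_events)
    dA = np.zeros((m, n, n))
    for j, k, ages, inc in per_tid:
        pos = np.searchsorted(grid_events, ages)
        np.add.at(dA, (pos, j, k), inc)

    rowsum = dA.sum(axis=2)
    over = rowsum > 1.0
    if over.any():
        if not cap_increments:
            raise EstimationError(
                "hazard increments push a diagonal of I + dA below 0; "
                "re-run with cap_increments=True to truncate them"
            )
        log.warning(
            "capping hazard increments at %d (age, state) points so the "
            "one-step transition matrix stays stochastic",
            int(over.sum()),
        )
        factor = np.where(over, 1.0 / np.where(over, rowsum, 1.0), 1.0)
        dA *= factor[:, :, None]
        rowsum = dA.sum(axis=2)
    ii = np.arange(n)
    dA[:, ii, ii] -= rowsum

    mats = np.empty((m + 1, n, n))
    mats[0] = np.eye(n)
    eye = np.eye(n)
    P = eye.copy()
    for u in range(m):
        P = P @ (eye + dA[u])
        mats[u + 1] = P
    return TransitionProbabilityMatrix(
        states=tuple(states),
        start_age=s,
        horizon=horizon,
        grid=np.concatenate([[s], grid_events]),
        matrices=mats,
        profile=tuple(np.asarray(profile, dtype=float).tolist()),
    )
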