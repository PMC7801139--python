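"""Labor-market state space and allowed-transition structure.

Seven daily states describe later working life: being at work,
time-restricted work disability (full sickness absence, vocational
rehabilitation, temporary disability pension, or partial disability
pension without concurrent earnings), unemployment, economic inactivity,
permanent disability retirement, (old-age) retirement, and death.

The transition structure is data, not code: each state space carries an
explicit rule set (absorbing states and per-state target restrictions)
from which the allowed-transition matrix is derived.  The canonical
space allows 27 transitions: the four "active" states communicate freely
with all six other states, disability retirement can only move on to
retirement or death, retirement only to death, and death absorbs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

WORK = "work"
TRWD = "time_restricted_work_disability"
UNEMPLOYMENT = "unemployment"
INACTIVITY = "economic_inactivity"
DISABILITY_RETIREMENT = "disability_retirement"
RETIREMENT = "retirement"
DEATH = "death"

#: Canonical state order; transition ids are numbered row-major in this order.
CANONICAL_STATES = (
    WORK,
    TRWD,
    UNEMPLOYMENT,
    INACTIVITY,
    DISABILITY_RETIREMENT,
    RETIREMENT,
    DEATH,
)


class ConfigurationError(ValueError):
    """Invalid state-space or run configuration."""


@dataclass(frozen=True)
class StateSpace:
    """A set of states plus the structural rules governing exits.

    Parameters
    ----------
    states
        Ordered state labels.
    absorbing
        States with no outgoing transitions.
    restricted
        Mapping from a state to the only targets it may move to.  States
        that are neither absorbing nor restricted may move to every other
        state (no self-transitions).
    """

    states: tuple[str, ...]
    absorbing: frozenset[str] = frozenset()
    restricted: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for s in self.states:
            if s in seen:
                raise ConfigurationError(f"duplicate state label {s!r}")
            seen.add(s)
        for s in self.absorbing:
            if s not in seen:
                raise ConfigurationError(f"unknown absorbing state {s!r}")
        for s, targets in self.restricted.items():
            if s not in seen:
                raise ConfigurationError(f"unknown restricted state {s!r}")
            if s in self.absorbing:
                raise ConfigurationError(
                    f"state {s!r} cannot be both absorbing and restricted"
                )
            for t in targets:
                if t not in seen:
                    raise ConfigurationError(f"unknown target state {t!r}")
                if t == s:
                    raise ConfigurationError(f"self-transition listed for {s!r}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ConfigurationError(f"unknown state label {state!r}") from None

    def allowed_targets(self, state: str) -> tuple[str, ...]:
        """States reachable from ``state`` in one transition."""
        self.index(state)
        if state in self.absorbing:
            return ()
        if state in self.restricted:
            return tuple(self.restricted[state])
        return tuple(s for s in self.states if s != state)

    def allowed_matrix(self) -> np.ndarray:
        """0/1 matrix, entry (j, k) = 1 iff transition j -> k is allowed."""
        n = self.n_states
        mat = np.zeros((n, n), dtype=int)
        for j, s in enumerate(self.states):
            for t in self.allowed_targets(s):
                mat[j, self.index(t)] = 1
        return mat


def canonical_state_space() -> StateSpace:
    """The seven-state labor-market space with its structural rules."""
    return StateSpace(
        states=CANONICAL_STATES,
        absorbing=frozenset({DEATH}),
        restricted={
            DISABILITY_RETIREMENT: (RETIREMENT, DEATH),
            RETIREMENT: (DEATH,),
        },
    )


@dataclass(frozen=True)
class TransitionStructure:
    """Enumerated allowed transitions with stable 1-based ids.

    Ids are assigned row-major: transitions are sorted by the from-state's
    position in ``space.states``, then by the to-state's position.
    """

    space: StateSpace
    transitions: tuple[tuple[str, str], ...]

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def id_of(self, from_state: str, to_state: str) -> int:
        """1-based id of an allowed transition; raises for disallowed pairs."""
        key = (from_state, to_state)
        try:
            return self._lookup[key]
        except KeyError:
            raise ConfigurationError(
                f"transition {from_state!r} -> {to_state!r} is not allowed"
            ) from None

    def __post_init__(self):
        lookup = {pair: i + 1 for i, pair in enumerate(self.transitions)}
        object.__setattr__(self, "_lookup", lookup)

    def is_allowed(self, from_state: str, to_state: str) -> bool:
        return (from_state, to_state) in self._lookup

    def pair_of(self, transition_id: int) -> tuple[str, str]:
        return self.transitions[transition_id - 1]

    def outgoing(self, from_state: str) -> tuple[tuple[int, str], ...]:
        """(id, to_state) pairs for all transitions out of ``from_state``."""
        return tuple(
            (i + 1, to)
            for i, (frm, to) in enumerate(self.transitions)
            if frm == from_state
        )

    def matrix(self) -> np.ndarray:
        return self.space.allowed_matrix()

    def to_json(self) -> str:
        """Serialize the allowed-transition matrix (with state order)."""
        return json.dumps(
            {
                "states": list(self.space.states),
                "absorbing": sorted(self.space.absorbing),
                "matrix": self.matrix().tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TransitionStructure":
        obj = json.loads(text)
        states = tuple(obj["states"])
        mat = np.asarray(obj["matrix"], dtype=int)
        if mat.shape != (len(states), len(states)):
            raise ConfigurationError("matrix shape does not match state list")
        absorbing = frozenset(obj["absorbing"])
        restricted = {}
        for j, s in enumerate(states):
            if s in absorbing:
                if mat[j].any():
                    raise ConfigurationError(f"absorbing state {s!r} has exits")
                continue
            targets = tuple(states[k] for k in np.flatnonzero(mat[j]))
            full = tuple(t for t in states if t != s)
            if targets != full:
                restricted[s] = targets
        space = StateSpace(states=states, absorbing=absorbing, restricted=restricted)
        return build_transition_structure(space)


def build_transition_structure(space: StateSpace) -> TransitionStructure:
    """Enumerate all allowed ordered state pairs, numbered row-major.

    For the canonical seven-state space this yields exactly 27 transitions.
    """
    transitions = []
    for s in space.states:
        targets = set(space.allowed_targets(s))
        # row-major: to-states in the space's canonical order
        for t in space.states:
            if t in targets:
                transitions.append((s, t))
    return TransitionStructure(space=space, transitions=tuple(transitions))
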