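"""Health-state space of the type 1 diabetes progression model.

Thirteen states: diabetes with no complications, four single-complication
states reachable from it (retinopathy, nephropathy, neuropathy, CHD), seven
"second-stage" states reachable from those (blindness, ESRD, LEA and the four
two-complication composites), and death. Second-stage states and death permit
no outgoing transition except self and death.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum


class Complication:
    RETINOPATHY = "retinopathy"
    NEPHROPATHY = "nephropathy"
    NEUROPATHY = "neuropathy"
    CHD = "CHD"
    BLINDNESS = "blindness"
    ESRD = "ESRD"
    LEA = "LEA"


class State(IntEnum):
    """Model states, in the canonical matrix/trace ordering."""

    NO_COMPLICATIONS = 0
    RETINOPATHY = 1
    NEPHROPATHY = 2
    NEUROPATHY = 3
    CHD = 4
    BLINDNESS = 5
    ESRD = 6
    LEA = 7
    NEPHROPATHY_CHD = 8
    NEUROPATHY_CHD = 9
    RETINOPATHY_CHD = 10
    NEUROPATHY_NEPHROPATHY = 11
    DEATH = 12


@dataclass(frozen=True)
class HealthState:
    """A model state together with its complication composition."""

    state: State
    complications: frozenset[str] = field(default_factory=frozenset)
    is_death: bool = False

    @property
    def name(self) -> str:
        return self.state.name


_COMPOSITION: dict[State, frozenset[str]] = {
    State.NO_COMPLICATIONS: frozenset(),
    State.RETINOPATHY: frozenset({Complication.RETINOPATHY}),
    State.NEPHROPATHY: frozenset({Complication.NEPHROPATHY}),
    State.NEUROPATHY: frozenset({Complication.NEUROPATHY}),
    State.CHD: frozenset({Complication.CHD}),
    State.BLINDNESS: frozenset({Complication.RETINOPATHY, Complication.BLINDNESS}),
    State.ESRD: frozenset({Complication.NEPHROPATHY, Complication.ESRD}),
    State.LEA: frozenset({Complication.NEUROPATHY, Complication.LEA}),
    State.NEPHROPATHY_CHD: frozenset({Complication.NEPHROPATHY, Complication.CHD}),
    State.NEUROPATHY_CHD: frozenset({Complication.NEUROPATHY, Complication.CHD}),
    State.RETINOPATHY_CHD: frozenset({Complication.RETINOPATHY, Complication.CHD}),
    State.NEUROPATHY_NEPHROPATHY: frozenset(
        {Complication.NEUROPATHY, Complication.NEPHROPATHY}
    ),
    State.DEATH: frozenset(),
}

HEALTH_STATES: tuple[HealthState, ...] = tuple(
    HealthState(s, _COMPOSITION[s], is_death=(s is State.DEATH)) for s in State
)

N_STATES = len(State)

LIVING_STATES: tuple[State, ...] = tuple(s for s in State if s is not State.DEATH)

#: States that permit no outgoing transition except self and death
#: (the two-complication composites, blindness, ESRD and LEA).
TERMINAL_LIVING_STATES: frozenset[State] = frozenset(
    {
        State.BLINDNESS,
        State.ESRD,
        State.LEA,
        State.NEPHROPATHY_CHD,
        State.NEUROPATHY_CHD,
        State.RETINOPATHY_CHD,
        State.NEUROPATHY_NEPHROPATHY,
    }
)

#: Every non-self, non-death transition in the model:
#: (source, destination, transition-parameter id, complication added).
#: The CHD -> composite rows reuse the microvascular -> CHD parameter values
#: (the back-transition estimates are taken as equal), so a single drawn
#: parameter feeds both directions in sensitivity analyses.
TRANSITIONS: tuple[tuple[State, State, str, str], ...] = (
    (State.NO_COMPLICATIONS, State.RETINOPATHY, "p_nocomp_retinopathy", Complication.RETINOPATHY),
    (State.NO_COMPLICATIONS, State.NEPHROPATHY, "p_nocomp_nephropathy", Complication.NEPHROPATHY),
    (State.NO_COMPLICATIONS, State.NEUROPATHY, "p_nocomp_neuropathy", Complication.NEUROPATHY),
    (State.NO_COMPLICATIONS, State.CHD, "p_nocomp_chd", Complication.CHD),
    (State.RETINOPATHY, State.BLINDNESS, "p_retinopathy_blindness", Complication.BLINDNESS),
    (State.RETINOPATHY, State.RETINOPATHY_CHD, "p_retinopathy_chd", Complication.CHD),
    (State.NEPHROPATHY, State.ESRD, "p_nephropathy_esrd", Complication.ESRD),
    (State.NEPHROPATHY, State.NEPHROPATHY_CHD, "p_nephropathy_chd", Complication.CHD),
    (State.NEUROPATHY, State.LEA, "p_neuropathy_lea", Complication.LEA),
    (State.NEUROPATHY, State.NEUROPATHY_NEPHROPATHY, "p_neuropathy_nephropathy", Complication.NEPHROPATHY),
    (State.NEUROPATHY, State.NEUROPATHY_CHD, "p_neuropathy_chd", Complication.CHD),
    (State.CHD, State.RETINOPATHY_CHD, "p_retinopathy_chd", Complication.RETINOPATHY),
    (State.CHD, State.NEPHROPATHY_CHD, "p_nephropathy_chd", Complication.NEPHROPATHY),
    (State.CHD, State.NEUROPATHY_CHD, "p_neuropathy_chd", Complication.NEUROPATHY),
)


def composition(state: State) -> frozenset[str]:
    """Complication set carried by ``state``."""
    return _COMPOSITION[state]
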