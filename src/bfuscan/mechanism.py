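"""Discrete-state simulator of the proposed ten-state bifurcation cycle.

The core is modelled as a flavin (OX/SQ/HQ) plus six one-electron FeS sites
(B1-B5 in the NAD(H)-binding subunit, C1 in the small subunit).  The enzyme
cycles through ten canonical states: two H₂ oxidations load four
mid-potential electrons onto B1/FMN/C1/B5; NAD⁺ binding drives the
conformational change that brings C1 within electron-transfer distance
(13 Å, against 19 Å in the open form) of B2 and enables formation of the
low-potential pair on C1+B2; ferredoxin is then reduced by that pair, and
hydride transfer to NAD⁺ closes the books.  Every event has an exact
inverse, so the confurcating direction is the same machine run backwards.

This is a state machine with stoichiometric semantics only — the proposal
names states, not rate constants, so no kinetics are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

OPEN_C1_B2_ANGSTROM = 19.0
CLOSED_C1_B2_ANGSTROM = 13.0
TRANSFER_LIMIT_ANGSTROM = 13.0

_FMN_ELECTRONS = {"OX": 0, "SQ": 1, "HQ": 2}
CLUSTERS = ("B1", "B2", "B3", "B4", "B5", "C1")


def transfer_allowed(distance_angstrom: float) -> bool:
    """Electron tunnelling between FeS centres: allowed at <= 13 Å."""
    if distance_angstrom <= 0:
        raise ValueError("distance must be positive")
    return distance_angstrom <= TRANSFER_LIMIT_ANGSTROM


@dataclass(frozen=True)
class MechanismState:
    state_index: int
    fmn: str  # OX | SQ | HQ
    occupancy: frozenset[str]  # occupied one-electron FeS sites
    conformation: str  # open | closed
    bound: frozenset[str]  # subset of {NAD+, NADH, Fd_ox, Fd_red}
    h2_consumed: int = 0
    h2_produced: int = 0
    h_plus_net: int = 0
    nadh_net: int = 0
    fd_red_net: int = 0

    @property
    def core_electrons(self) -> int:
        return _FMN_ELECTRONS[self.fmn] + len(self.occupancy)

    @property
    def configuration(self) -> tuple:
        """The mechanistic state without bookkeeping tallies.

        Applying an event and then its inverse restores the configuration
        and every *net* tally exactly; the gross H₂ counters are monotone
        turnover counts (one H₂ oxidised then re-made is one consumed and
        one produced, not zero of each).
        """
        return (
            self.state_index, self.fmn, self.occupancy,
            self.conformation, self.bound,
        )

    @property
    def h2_net(self) -> int:
        return self.h2_consumed - self.h2_produced

    @property
    def c1_b2_distance(self) -> float:
        return (
            CLOSED_C1_B2_ANGSTROM
            if self.conformation == "closed"
            else OPEN_C1_B2_ANGSTROM
        )

    def __post_init__(self) -> None:
        if (self.state_index == 1) != (
            self.core_electrons == 0 and not self.bound
            and self.conformation == "open"
        ):
            raise ValueError(
                "state 1 is exactly the fully oxidised, unbound, open form"
            )
        if (self.conformation == "closed") != bool(
            self.bound & {"NAD+", "NADH"}
        ):
            raise ValueError("closed conformation <=> NAD(H) bound")


# canonical configuration per state: (fmn, occupancy, conformation, bound)
_S = {
    1: ("OX", (), "open", ()),
    2: ("SQ", ("B1",), "open", ()),
    3: ("SQ", ("B1", "B5", "C1"), "open", ()),
    4: ("SQ", ("B1", "B5", "C1"), "closed", ("NAD+",)),
    5: ("SQ", ("B1", "B2", "C1"), "closed", ("NAD+",)),
    6: ("SQ", ("B1", "B2", "C1"), "closed", ("Fd_ox", "NAD+")),
    7: ("SQ", ("B1",), "closed", ("Fd_red", "NAD+")),
    8: ("SQ", ("B1",), "closed", ("NAD+",)),
    9: ("HQ", (), "closed", ("NAD+",)),
    10: ("OX", (), "closed", ("NADH",)),
}

# forward (bifurcating) transitions and tally deltas
_FORWARD: dict[tuple[int, str], int] = {
    (1, "oxidize_H2"): 2,
    (2, "oxidize_H2"): 3,
    (3, "bind_NAD"): 4,  # NAD+ binding fused with the conformational change
    (4, "form_low_potential_pair"): 5,  # B5 electron relocates to B2
    (5, "bind_Fd_ox"): 6,
    (6, "reduce_Fd"): 7,  # via B3/B4; requires the closed 13 Å geometry
    (7, "release_Fd_red"): 8,
    (8, "b1_to_fmn"): 9,
    (9, "reduce_NAD"): 10,  # hydride transfer to bound NAD+
    (10, "release_NADH"): 1,  # release triggers relaxation to open
}

INVERSE_EVENTS: dict[str, str] = {
    "oxidize_H2": "produce_H2",
    "bind_NAD": "release_NAD",
    "form_low_potential_pair": "recombine_low_potential_pair",
    "bind_Fd_ox": "release_Fd_ox",
    "reduce_Fd": "oxidize_Fd_red",
    "release_Fd_red": "bind_Fd_red",
    "b1_to_fmn": "fmn_to_b1",
    "reduce_NAD": "oxidize_NADH",
    "release_NADH": "bind_NADH",
}
INVERSE_EVENTS.update({v: k for k, v in INVERSE_EVENTS.items()})

#: full legality table: (state, event) -> next state, closed under inversion
TRANSITIONS: dict[tuple[int, str], int] = dict(_FORWARD)
TRANSITIONS.update(
    {(dst, INVERSE_EVENTS[ev]): src for (src, ev), dst in _FORWARD.items()}
)

_TALLY_DELTAS: dict[str, dict[str, int]] = {
    "oxidize_H2": {"h2_consumed": 1, "h_plus_net": 2},
    "produce_H2": {"h2_produced": 1, "h_plus_net": -2},
    "reduce_NAD": {"h_plus_net": -1},
    "oxidize_NADH": {"h_plus_net": 1},
    "release_NADH": {"nadh_net": 1},
    "bind_NADH": {"nadh_net": -1},
    "release_Fd_red": {"fd_red_net": 1},
    "bind_Fd_red": {"fd_red_net": -1},
}

#: electrons entering (+) or leaving (-) the core, per event
ELECTRON_FLOW: dict[str, int] = {
    "oxidize_H2": 2,
    "produce_H2": -2,
    "reduce_Fd": -2,
    "oxidize_Fd_red": 2,
    "reduce_NAD": -2,
    "oxidize_NADH": 2,
}


def _canonical(index: int, **tallies: int) -> MechanismState:
    fmn, occ, conf, bound = _S[index]
    return MechanismState(
        index, fmn, frozenset(occ), conf, frozenset(bound), **tallies
    )


def initial_state() -> MechanismState:
    """The resting, fully oxidised '0 e⁻' enzyme (state 1)."""
    return _canonical(1)


def legal_events(state: MechanismState) -> list[str]:
    return sorted(ev for (s, ev) in TRANSITIONS if s == state.state_index)


def apply(state: MechanismState, event: str) -> MechanismState:
    """Apply one event; illegal events are rejected naming state and event."""
    key = (state.state_index, event)
    if key not in TRANSITIONS:
        hint = ""
        if event in ("reduce_Fd", "oxidize_Fd_red") and state.conformation == "open":
            hint = (
                f" (open conformation: C1-B2 at {OPEN_C1_B2_ANGSTROM:g} Å "
                "precludes electron transfer)"
            )
        raise ValueError(
            f"event {event!r} is not legal in state {state.state_index}{hint}"
        )
    tallies = {
        "h2_consumed": state.h2_consumed,
        "h2_produced": state.h2_produced,
        "h_plus_net": state.h_plus_net,
        "nadh_net": state.nadh_net,
        "fd_red_net": state.fd_red_net,
    }
    for k, dv in _TALLY_DELTAS.get(event, {}).items():
        tallies[k] += dv
    return _canonical(TRANSITIONS[key], **tallies)


@dataclass(frozen=True)
class Trajectory:
    states: tuple[MechanismState, ...]
    events: tuple[str, ...]

    def __post_init__(self) -> None:
        for i, ev in enumerate(self.events):
            if TRANSITIONS.get((self.states[i].state_index, ev)) != (
                self.states[i + 1].state_index
            ):
                raise ValueError("states and events are inconsistent")

    @property
    def net_stoichiometry(self) -> dict[str, int]:
        final = self.states[-1]
        return {
            "H2_consumed": final.h2_consumed,
            "H2_produced": final.h2_produced,
            "H_plus_net": final.h_plus_net,
            "NADH_net": final.nadh_net,
            "Fd_red_net": final.fd_red_net,
        }

    @property
    def electrons_into_core(self) -> int:
        """Electrons delivered to the core by substrate-oxidation events."""
        return sum(
            ELECTRON_FLOW[ev] for ev in self.events if ELECTRON_FLOW.get(ev, 0) > 0
        )

    def to_records(self) -> list[dict]:
        out = []
        for i, state in enumerate(self.states):
            out.append(
                {
                    "step": i,
                    "state": state.state_index,
                    "fmn": state.fmn,
                    "occupancy": sorted(state.occupancy),
                    "conformation": state.conformation,
                    "bound": sorted(state.bound),
                    "core_electrons": state.core_electrons,
                    "event_to_next": self.events[i] if i < len(self.events) else "",
                }
            )
        return out


_FORWARD_ORDER = [ev for (_s, ev) in sorted(_FORWARD, key=lambda k: k[0])]


def run_cycle(direction: str = "bifurcation") -> Trajectory:
    """One canonical catalytic cycle, returning to the resting state.

    ``bifurcation``: 2 H₂ in, 1 NADH + 1 Fd_red (+3 H⁺) out, states
    1→2→…→10→1.  ``confurcation`` is the exact reverse path with the
    inverse stoichiometry.
    """
    if direction == "bifurcation":
        events = list(_FORWARD_ORDER)
    elif direction == "confurcation":
        events = [INVERSE_EVENTS[ev] for ev in reversed(_FORWARD_ORDER)]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    state = initial_state()
    states = [state]
    for ev in events:
        state = apply(state, ev)
        states.append(state)
    return Trajectory(tuple(states), tuple(events))
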