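"""Discrete state space of the emotion/information opinion model.

An agent is described by three discrete attributes:

* ``emotion`` -- arousal level: 0 (calm, receptive and deliberative) or
  1 (agitated, unreceptive and emotionally charged);
* ``information`` -- the evidence held about the issue: -1, 0 or +1;
* ``opinion`` -- the resulting attitude: -1, 0 or +1.

Opinion is a dependent variable.  Decisive information dictates the
opinion outright.  An uninformed calm agent is neutral.  An uninformed
*agitated* agent, however, keeps a nonzero opinion of either sign: this
is the discrete analogue of the bistable fold of the cusp catastrophe,
with information acting as the normal factor and arousal as the
splitting factor.  Exactly seven triples are admissible.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = [
    "AgentState",
    "Message",
    "all_states",
    "validate_triple",
    "mirror",
    "parse_label",
    "label",
    "STATE_INDEX",
    "N_STATES",
]


class AgentState(NamedTuple):
    """A valid (emotion, information, opinion) triple."""

    emotion: int
    information: int
    opinion: int

    @property
    def label(self) -> str:
        return label(self)

    def __repr__(self) -> str:  # compact, uses the canonical notation
        return f"AgentState({label(self)})"


#: A message mirrors its author's full state; the alias keeps signatures
#: self-documenting.
Message = AgentState

_SIGN_CHAR = {-1: "M", 0: "0", 1: "P"}
_CHAR_SIGN = {v: k for k, v in _SIGN_CHAR.items()}

# Canonical ordering: calm block then agitated block (ascending opinion
# inside each block where applicable).  Every vector, table row/column
# and output file in the package uses this ordering.
_ALL_STATES: tuple[AgentState, ...] = (
    AgentState(0, -1, -1),  # CMM
    AgentState(0, 0, 0),    # C00
    AgentState(0, 1, 1),    # CPP
    AgentState(1, -1, -1),  # AMM
    AgentState(1, 0, -1),   # A0M
    AgentState(1, 0, 1),    # A0P
    AgentState(1, 1, 1),    # APP
)

N_STATES = len(_ALL_STATES)

#: Index of each state in the canonical ordering.
STATE_INDEX: dict[AgentState, int] = {s: i for i, s in enumerate(_ALL_STATES)}


def all_states() -> tuple[AgentState, ...]:
    """Return the seven valid states in canonical order (CMM, C00, CPP,
    AMM, A0M, A0P, APP)."""
    return _ALL_STATES


def validate_triple(emotion: int, information: int, opinion: int) -> bool:
    """True iff the triple is one of the seven admissible states.

    Raises ``ValueError`` for arguments outside their domains.
    """
    if emotion not in (0, 1):
        raise ValueError(f"emotion must be 0 or 1, got {emotion!r}")
    if information not in (-1, 0, 1):
        raise ValueError(f"information must be -1, 0 or +1, got {information!r}")
    if opinion not in (-1, 0, 1):
        raise ValueError(f"opinion must be -1, 0 or +1, got {opinion!r}")
    if information != 0:
        return opinion == information
    # uninformed: calm agents are neutral, agitated agents are committed
    if emotion == 0:
        return opinion == 0
    return opinion != 0


def mirror(state: AgentState) -> AgentState:
    """The plus/minus symmetry operator: negate information and opinion,
    preserve emotion.  An involution mapping the state set onto itself."""
    return AgentState(state.emotion, -state.information, -state.opinion)


#: mirror() expressed as a permutation of canonical indices.
MIRROR_PERM = tuple(STATE_INDEX[mirror(s)] for s in _ALL_STATES)


def label(state: AgentState) -> str:
    """Canonical three-letter label, e.g. ``AgentState(1, 0, -1)`` -> ``"A0M"``."""
    e = "C" if state.emotion == 0 else "A"
    return e + _SIGN_CHAR[state.information] + _SIGN_CHAR[state.opinion]


_LABELS = tuple(label(s) for s in _ALL_STATES)
_LABEL_INDEX = {lab: i for i, lab in enumerate(_LABELS)}

#: Canonical labels in canonical order.
LABELS = _LABELS


def parse_label(text: str) -> AgentState:
    """Parse a state label (case-insensitive); inverse of :func:`label`."""
    key = str(text).strip().upper()
    try:
        return _ALL_STATES[_LABEL_INDEX[key]]
    except KeyError:
        raise ValueError(
            f"unknown state label {text!r}; valid labels are {', '.join(_LABELS)}"
        ) from None
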