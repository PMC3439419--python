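"""Message-level interaction rules and the derived pair-transition tables.

A message carries its author's (emotion, information, opinion).  On
reception, the recipient updates

* its *emotion* from the emotional tone of the message relative to its
  own opinion,
* its *information* by weighing its own evidence against the message's
  (equal weights when both parties are calm; the recipient's evidence
  counts double as soon as either party is agitated),
* its *opinion* from the new control variables, with hysteresis: an
  agitated, uninformed agent keeps its previous opinion.

Both the emotion and the information updates read the *pre-interaction*
states; in particular the "anyone agitated?" flag ignores the emotional
outcome of the same event.

Two interaction units are supported: a single directed message (only the
recipient may change) and a full conversation, in which the two agents
alternate messages until a full two-message round changes neither of
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .states import (
    AgentState,
    Message,
    N_STATES,
    STATE_INDEX,
    all_states,
    label,
    validate_triple,
)

__all__ = [
    "update_emotion",
    "update_information",
    "resolve_opinion",
    "receive_message",
    "PairOutcome",
    "single_message_table",
    "ConversationResult",
    "run_conversation",
    "conversation_table",
    "RECV",
    "CONV_STARTER",
    "CONV_SECOND",
    "table_to_dataframe",
]

DEFAULT_MAX_ROUNDS = 8


class NonTerminationError(RuntimeError):
    """A conversation failed to stabilize within the round cap."""


class UnreachableStateError(ValueError):
    """An opinion resolution that cannot arise from valid update inputs."""


def _check(state: AgentState, name: str) -> None:
    if not validate_triple(state.emotion, state.information, state.opinion):
        raise ValueError(f"{name} {tuple(state)} is not a valid agent state")


def update_emotion(recipient: AgentState, message: Message) -> int:
    """New emotion level of the recipient (0 calm / 1 agitated).

    Agitated messages agitate calm recipients holding the opposite
    (nonzero) opinion and leave everyone else's arousal unchanged.  Calm
    messages never agitate; they calm an agitated recipient only when
    they voice the same nonzero opinion (reassurance).
    """
    if message.emotion == 1:
        if recipient.emotion == 1:
            return 1
        if recipient.opinion == 0 or recipient.opinion == message.opinion:
            return 0
        return 1
    # calm message
    if recipient.emotion == 0:
        return 0
    if message.opinion != 0 and message.opinion == recipient.opinion:
        return 0
    return 1


def update_information(
    recipient_info: int, sender_info: int, any_agitated: bool
) -> int:
    """New information value of the recipient.

    With both parties calm the two evidence values carry equal weight:
    opposite decisive values cancel to 0 and a decisive message convinces
    an uninformed recipient.  With either party agitated the recipient's
    own evidence counts double: the uninformed are never convinced, while
    opposed decisive values still cancel.
    """
    if recipient_info not in (-1, 0, 1) or sender_info not in (-1, 0, 1):
        raise ValueError("information values must be in {-1, 0, +1}")
    if sender_info == 0 or sender_info == recipient_info:
        return recipient_info
    if recipient_info == 0:
        # decisive message to an uninformed recipient
        return 0 if any_agitated else sender_info
    # opposed decisive values balance out
    return 0


def resolve_opinion(new_emotion: int, new_information: int, previous_opinion: int) -> int:
    """Opinion implied by the updated control variables.

    Decisive information dictates the opinion; a calm uninformed agent is
    neutral; an agitated uninformed agent keeps its previous (nonzero)
    opinion -- the hysteresis branch of the model.
    """
    if new_information != 0:
        return new_information
    if new_emotion == 0:
        return 0
    if previous_opinion == 0:
        # cannot be produced by the update rules from valid inputs;
        # guards the AgentState invariant
        raise UnreachableStateError(
            "agitated uninformed agent with no previous opinion"
        )
    return previous_opinion


def receive_message(recipient: AgentState, message: Message) -> AgentState:
    """State of the recipient after reading a single message."""
    _check(recipient, "recipient")
    _check(message, "message")
    any_agitated = recipient.emotion == 1 or message.emotion == 1
    e = update_emotion(recipient, message)
    i = update_information(recipient.information, message.information, any_agitated)
    o = resolve_opinion(e, i, recipient.opinion)
    return AgentState(e, i, o)


@dataclass(frozen=True)
class PairOutcome:
    """Final states of a (recipient, sender) pair after one message."""

    sender_final: AgentState
    recipient_final: AgentState


def single_message_table() -> dict[tuple[AgentState, AgentState], PairOutcome]:
    """All 49 single-message outcomes keyed by (recipient, sender).

    The sender never changes; the recipient's final state is
    :func:`receive_message` applied cell by cell.
    """
    return {
        (r, s): PairOutcome(sender_final=s, recipient_final=receive_message(r, s))
        for r in all_states()
        for s in all_states()
    }


@dataclass
class ConversationResult:
    """Outcome of a full conversation between two agents.

    ``chain`` lists the (current recipient, current sender) state pair
    before the first message and after every message, with the roles
    swapping each step -- the conventional reversed-pair notation.
    ``rounds`` counts the messages sent, including the final confirming
    round that detects stability.
    """

    starter_final: AgentState
    second_final: AgentState
    chain: list[tuple[AgentState, AgentState]] = field(default_factory=list)
    rounds: int = 0


def run_conversation(
    first_sender: AgentState,
    first_recipient: AgentState,
    max_rounds: int = DEFAULT_MAX_ROUNDS,
) -> ConversationResult:
    """Alternate messages between two agents until a full two-message
    round changes neither of them.

    ``first_sender`` opens the conversation (the "starter"); the
    ``first_recipient`` is the second agent.  Messages that cause no
    change are still exchanged; the dialogue stops once two consecutive
    messages (one in each direction) leave their recipients unchanged,
    which is the two-sided pair-stability condition
    ``receive_message(a, b) == a and receive_message(b, a) == b``.
    """
    _check(first_sender, "first_sender")
    _check(first_recipient, "first_recipient")
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")

    starter, second = first_sender, first_recipient
    recipient_is_second = True
    chain: list[tuple[AgentState, AgentState]] = [(second, starter)]
    no_change_streak = 0
    messages = 0
    cap = 2 * max_rounds

    while no_change_streak < 2:
        if messages >= cap:
            raise NonTerminationError(
                f"conversation did not stabilize within {max_rounds} rounds"
            )
        if recipient_is_second:
            new = receive_message(second, starter)
            changed = new != second
            second = new
            chain.append((starter, second))
        else:
            new = receive_message(starter, second)
            changed = new != starter
            starter = new
            chain.append((second, starter))
        no_change_streak = 0 if changed else no_change_streak + 1
        recipient_is_second = not recipient_is_second
        messages += 1

    return ConversationResult(
        starter_final=starter, second_final=second, chain=chain, rounds=messages
    )


def conversation_table() -> dict[
    tuple[AgentState, AgentState], tuple[AgentState, AgentState]
]:
    """All 49 full-conversation outcomes.

    Keyed by (second agent, starting agent); each value is
    (starter final, second final).  The table is genuinely asymmetric:
    who speaks first matters.
    """
    out = {}
    for second in all_states():
        for starter in all_states():
            res = run_conversation(starter, second)
            out[(second, starter)] = (res.starter_final, res.second_final)
    return out


def _recv_array() -> np.ndarray:
    arr = np.empty((N_STATES, N_STATES), dtype=np.intp)
    for r in all_states():
        for s in all_states():
            arr[STATE_INDEX[r], STATE_INDEX[s]] = STATE_INDEX[receive_message(r, s)]
    return arr


def _conv_arrays() -> tuple[np.ndarray, np.ndarray]:
    starter_arr = np.empty((N_STATES, N_STATES), dtype=np.intp)
    second_arr = np.empty((N_STATES, N_STATES), dtype=np.intp)
    for (second, starter), (sf, cf) in conversation_table().items():
        i, j = STATE_INDEX[second], STATE_INDEX[starter]
        starter_arr[i, j] = STATE_INDEX[sf]
        second_arr[i, j] = STATE_INDEX[cf]
    return starter_arr, second_arr


#: RECV[r, s] = canonical index of the recipient's state after reading a
#: message from state s while in state r.
RECV: np.ndarray = _recv_array()

#: CONV_SECOND[a, b] (resp. CONV_STARTER[a, b]) = final canonical index of
#: the second agent a (resp. the starter b) after a full conversation
#: opened by b.
CONV_STARTER, CONV_SECOND = _conv_arrays()
RECV.setflags(write=False)
CONV_STARTER.setflags(write=False)
CONV_SECOND.setflags(write=False)


def table_to_dataframe(which: str = "single"):
    """Export a transition table as a labeled DataFrame.

    ``which='single'``: rows are recipients, columns senders, cells the
    recipient's final state.  ``which='conversation'``: rows are second
    agents, columns starting agents, cells ``"starter_final/second_final"``.
    """
    import pandas as pd

    labs = [label(s) for s in all_states()]
    if which == "single":
        cells = [[labs[RECV[i, j]] for j in range(N_STATES)] for i in range(N_STATES)]
    elif which == "conversation":
        cells = [
            [
                f"{labs[CONV_STARTER[i, j]]}/{labs[CONV_SECOND[i, j]]}"
                for j in range(N_STATES)
            ]
            for i in range(N_STATES)
        ]
    else:
        raise ValueError("which must be 'single' or 'conversation'")
    return pd.DataFrame(cells, index=labs, columns=labs)
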