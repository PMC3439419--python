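"""Frozen oracle data for the microscopic interaction rules.

These tables are the published reference behavior of the model, stored
verbatim (state labels in canonical order) and used only as expected
values in tests; the implementation derives everything from the rule
primitives.
"""

# Information update, both parties calm: (recipient info, sender info) -> new
INFO_BOTH_CALM = {
    (-1, -1): -1,
    (-1, 0): -1,
    (-1, 1): 0,
    (0, -1): -1,
    (0, 0): 0,
    (0, 1): 1,
    (1, -1): 0,
    (1, 0): 1,
    (1, 1): 1,
}

# Information update, at least one party agitated
INFO_ANY_AGITATED = {
    (-1, -1): -1,
    (-1, 0): -1,
    (-1, 1): 0,
    (0, -1): 0,
    (0, 0): 0,
    (0, 1): 0,
    (1, -1): 0,
    (1, 0): 1,
    (1, 1): 1,
}

# Single-message outcomes: rows = recipient, columns = sender, both in
# canonical order CMM C00 CPP AMM A0M A0P APP; cell = recipient's final state.
SINGLE_MESSAGE = [
    "CMM CMM C00 CMM CMM AMM A0M",
    "CMM C00 CPP C00 C00 C00 C00",
    "C00 CPP CPP A0P APP CPP CPP",
    "CMM AMM A0M AMM AMM AMM A0M",
    "C00 A0M A0M A0M A0M A0M A0M",
    "A0P A0P C00 A0P A0P A0P A0P",
    "A0P APP CPP A0P APP APP APP",
]

# Full-conversation outcomes: rows = second agent (first recipient),
# columns = starting agent; final state of the starter and of the second.
CONVERSATION_STARTER_FINAL = [
    "CMM CMM CPP CMM CMM A0P APP",
    "CMM C00 CPP AMM A0M A0P APP",
    "CMM CPP CPP AMM A0M CPP CPP",
    "CMM C00 APP AMM A0M A0P APP",
    "CMM C00 APP AMM A0M A0P APP",
    "AMM C00 CPP AMM A0M A0P APP",
    "AMM C00 CPP AMM A0M A0P APP",
]
CONVERSATION_SECOND_FINAL = [
    "CMM CMM CPP CMM CMM AMM A0M",
    "CMM C00 CPP C00 C00 C00 C00",
    "CMM CPP CPP A0P APP CPP CPP",
    "CMM AMM A0M AMM AMM AMM A0M",
    "CMM A0M A0M A0M A0M A0M A0M",
    "A0P A0P CPP A0P A0P A0P A0P",
    "A0P APP CPP A0P APP APP APP",
]

# Published message-by-message conversation chains in reversed-pair
# notation: each entry is the (current recipient, current sender) pair
# before the next message; the last entry is the stable configuration.
# One widely-known typo in the printed source ("AOM" for "A0M") is
# corrected.  The printed chains are inconsistent about how many
# confirming (no-change) messages they show, so tests check that each
# printed chain is an order-preserving subsequence of the simulated one.
CONVERSATION_CHAINS = [
    "(CMM,CMM) (CMM,CMM)",
    "(CMM,C00) (C00,CMM) (CMM,CMM)",
    "(CMM,CPP) (CPP,C00) (C00,CPP) (CPP,CPP)",
    "(CMM,AMM) (AMM,CMM) (CMM,CMM)",
    "(CMM,A0M) (A0M,CMM) (CMM,C00) (CMM,CMM)",
    "(CMM,A0P) (A0P,AMM) (AMM,A0P)",
    "(CMM,APP) (APP,A0M) (A0M,APP)",
    "(C00,CMM) (CMM,CMM)",
    "(C00,C00) (C00,C00)",
    "(C00,CPP) (CPP,CPP)",
    "(C00,AMM) (AMM,C00) (C00,AMM)",
    "(C00,A0M) (A0M,C00) (C00,A0M)",
    "(C00,A0P) (A0P,C00) (C00,A0P)",
    "(C00,APP) (APP,C00) (C00,APP)",
    "(CPP,CMM) (CMM,C00) (C00,CMM) (CMM,CMM)",
    "(CPP,C00) (C00,CPP) (CPP,CPP)",
    "(CPP,CPP) (CPP,CPP)",
    "(CPP,AMM) (AMM,A0P) (A0P,AMM)",
    "(CPP,A0M) (A0M,APP) (APP,A0M)",
    "(CPP,A0P) (A0P,CPP) (CPP,C00) (C00,CPP) (CPP,CPP)",
    "(CPP,APP) (APP,CPP) (CPP,CPP)",
    "(AMM,CMM) (CMM,CMM)",
    "(AMM,C00) (C00,AMM) (AMM,C00)",
    "(AMM,CPP) (CPP,A0M) (A0M,APP) (APP,A0M) (A0M,APP)",
    "(AMM,AMM) (AMM,AMM)",
    "(AMM,A0M) (A0M,AMM) (AMM,A0M)",
    "(AMM,A0P) (A0P,AMM) (AMM,A0P)",
    "(AMM,APP) (APP,A0M) (A0M,APP)",
    "(A0M,CMM) (CMM,C00) (CMM,CMM)",
    "(A0M,C00) (C00,A0M) (A0M,C00)",
    "(A0M,CPP) (CPP,A0M) (A0M,APP) (APP,A0M)",
    "(A0M,AMM) (AMM,A0M) (A0M,AMM)",
    "(A0M,A0M) (A0M,A0M)",
    "(A0M,A0P) (A0P,A0M) (A0M,A0P)",
    "(A0M,APP) (APP,A0M) (A0M,APP)",
    "(A0P,CMM) (CMM,A0P) (A0P,AMM) (AMM,A0P)",
    "(A0P,C00) (C00,A0P) (A0P,C00)",
    "(A0P,CPP) (CPP,C00) (C00,CPP) (CPP,CPP)",
    "(A0P,AMM) (AMM,A0P) (A0P,AMM)",
    "(A0P,A0M) (A0M,A0P) (A0P,A0M)",
    "(A0P,A0P) (A0P,A0P)",
    "(A0P,APP) (APP,A0P) (A0P,APP)",
    "(APP,CMM) (CMM,A0P) (A0P,AMM) (AMM,A0P) (A0P,AMM)",
    "(APP,C00) (C00,APP) (APP,C00)",
    "(APP,CPP) (CPP,CPP)",
    "(APP,AMM) (AMM,A0P) (A0P,AMM)",
    "(APP,A0M) (A0M,APP) (APP,A0M)",
    "(APP,A0P) (A0P,APP) (APP,A0P)",
    "(APP,APP) (APP,APP)",
]


def parse_chain(row: str):
    """Parse a chain string into a list of (recipient, sender) label pairs."""
    pairs = []
    for token in row.split():
        a, b = token.strip("()").split(",")
        pairs.append((a, b))
    return pairs
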