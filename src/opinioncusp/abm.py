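"""Finite-population stochastic simulator on the complete graph.

Every tick is synchronous: each of the N agents draws one message source
from the time-t snapshot of the population -- a media state with
probability ``r_M / (1 + R)``, otherwise the state of a uniformly chosen
*other* agent -- and all agents adopt their new states simultaneously.
In single-message mode the new state is the single-message reception
outcome; in conversation mode the focal agent is the first recipient of a
full conversation and adopts its second-agent final (media messages are
always processed as single messages: there is no talking back to a
broadcast).

Optional probabilistic extensions relax the deterministic rules per agent
and tick: a send decision (bookkeeping), a read probability, a message
effect probability, an "allergic" probability that a calm agent treats an
opposing calm message as if it were agitated, and a calming probability
by which an agitated agent that neither sent nor read relaxes
(AMM -> CMM, APP -> CPP, A0M -> C00, A0P -> C00).  All defaults reproduce
the deterministic model bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .meanfield import MODES, MediaSource, Trajectory, as_composition
from .microdynamics import CONV_SECOND, RECV
from .states import N_STATES, STATE_INDEX, all_states

__all__ = [
    "ProbabilisticParams",
    "SimulationConfig",
    "init_population",
    "tick",
    "run",
    "ensemble_statistics",
]

# calming transitions: AMM->CMM, A0M->C00, A0P->C00, APP->CPP (identity
# elsewhere), in canonical index order
_CALM_DOWN = np.array([0, 1, 2, 0, 1, 1, 2], dtype=np.intp)

# "allergic" reinterpretation: the agitated counterpart of each calm
# informed message (CMM -> AMM, CPP -> APP); other states map to themselves
_AGITATED_TWIN = np.array([3, 1, 6, 3, 4, 5, 6], dtype=np.intp)

_OPINION = np.array([s.opinion for s in all_states()])
_EMOTION = np.array([s.emotion for s in all_states()])


@dataclass(frozen=True)
class ProbabilisticParams:
    """Per-agent, per-tick branch probabilities of the probabilistic
    model extension.  The defaults (1, 0, 0, 1, 1) reproduce the
    deterministic dynamics exactly."""

    effect: float = 1.0     # a read message has any effect
    allergic: float = 0.0   # opposing calm message treated as agitated
    calming: float = 0.0    # inactive agitated agent relaxes
    send: float = 1.0       # agent sends this tick (activity bookkeeping)
    read: float = 1.0       # agent reads a message this tick

    def __post_init__(self):
        for name in ("effect", "allergic", "calming", "send", "read"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} probability must be in [0, 1], got {v}")

    @property
    def is_deterministic(self) -> bool:
        return (
            self.effect == 1.0
            and self.allergic == 0.0
            and self.calming == 0.0
            and self.send == 1.0
            and self.read == 1.0
        )


@dataclass
class SimulationConfig:
    """Configuration of one finite-size run."""

    n_agents: int
    ticks: int
    initial: np.ndarray                      # composition, canonical order
    mode: str = "single"
    media: MediaSource | None = None
    seed: int = 0
    params: ProbabilisticParams | None = None

    def __post_init__(self):
        if self.n_agents < 2:
            raise ValueError("n_agents must be >= 2 (agents need a partner)")
        if self.ticks < 0:
            raise ValueError("ticks must be >= 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        self.initial = as_composition(self.initial)


def init_population(comp: np.ndarray, n_agents: int, seed: int | None = None) -> np.ndarray:
    """Deterministic largest-remainder rounding of ``n_agents * comp`` to
    integer per-state counts, returned as an array of state indices.

    Ties in the fractional remainders are broken by canonical state
    order.  The ``seed`` argument is accepted for interface symmetry but
    the allocation itself is deterministic.
    """
    comp = as_composition(comp)
    target = n_agents * comp
    counts = np.floor(target).astype(int)
    short = n_agents - counts.sum()
    if short > 0:
        remainders = target - counts
        # stable sort descending: canonical order breaks ties
        order = np.argsort(-remainders, kind="stable")
        counts[order[:short]] += 1
    return np.repeat(np.arange(N_STATES), counts)


def _composition_of(population: np.ndarray) -> np.ndarray:
    return np.bincount(population, minlength=N_STATES) / population.size


def _draw_sources(
    population: np.ndarray, media: MediaSource | None, rng: np.random.Generator
) -> np.ndarray:
    """State index of the message source read by each agent (peer or
    media), all drawn from the time-t snapshot."""
    n = population.size
    partners = rng.integers(0, n - 1, size=n)
    partners += partners >= np.arange(n)  # uniform over the other n-1 agents
    sources = population[partners]
    from_media = np.zeros(n, dtype=bool)
    if media is not None and media.total > 0:
        from_media = rng.random(n) < media.total / (1.0 + media.total)
        k = int(from_media.sum())
        if k:
            sources = sources.copy()
            sources[from_media] = rng.choice(
                N_STATES, size=k, p=media.rates / media.total
            )
    return sources, from_media


def tick(
    population: np.ndarray,
    mode: str = "single",
    media: MediaSource | None = None,
    rng: np.random.Generator | None = None,
    params: ProbabilisticParams | None = None,
) -> np.ndarray:
    """One synchronous update of the whole population.

    Returns the new population array; the input is not modified.  All
    message sources are read from the time-t snapshot, so the update
    order of agents is immaterial.
    """
    if population.size < 2:
        raise ValueError("population must contain at least 2 agents")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    rng = np.random.default_rng() if rng is None else rng

    sources, from_media = _draw_sources(population, media, rng)
    peer_table = RECV if mode == "single" else CONV_SECOND

    if params is None or params.is_deterministic:
        new = np.where(
            from_media, RECV[population, sources], peer_table[population, sources]
        )
        return new

    n = population.size
    sends = rng.random(n) < params.send
    reads = rng.random(n) < params.read
    effects = rng.random(n) < params.effect
    allergic = rng.random(n) < params.allergic
    calms = rng.random(n) < params.calming

    # allergic reinterpretation: calm recipient, calm message, opposed
    # nonzero opinions -> message treated as its agitated twin
    opposing_calm = (
        (_EMOTION[population] == 0)
        & (_EMOTION[sources] == 0)
        & (_OPINION[population] * _OPINION[sources] == -1)
    )
    eff_sources = np.where(allergic & opposing_calm, _AGITATED_TWIN[sources], sources)

    outcome = np.where(
        from_media,
        RECV[population, eff_sources],
        peer_table[population, eff_sources],
    )
    new = population.copy()
    updating = reads & effects
    new[updating] = outcome[updating]

    inactive_agitated = ~reads & ~sends & (_EMOTION[population] == 1)
    relaxing = inactive_agitated & calms
    new[relaxing] = _CALM_DOWN[population[relaxing]]
    return new


def run(config: SimulationConfig) -> Trajectory:
    """Execute a full simulation, recording the empirical composition at
    every tick.  Identical configurations and seeds yield bit-identical
    trajectories."""
    rng = np.random.default_rng(config.seed)
    population = init_population(config.initial, config.n_agents)
    history = [_composition_of(population)]
    for _ in range(config.ticks):
        population = tick(population, config.mode, config.media, rng, config.params)
        history.append(_composition_of(population))
    return Trajectory(
        np.asarray(history),
        meta={
            "kind": "abm",
            "n_agents": config.n_agents,
            "mode": config.mode,
            "seed": config.seed,
            "ticks": config.ticks,
        },
    )


def ensemble_statistics(
    config: SimulationConfig,
    n_runs: int,
    horizon_ticks: tuple[int, ...] = (100, 500),
):
    """Distributions of occupation ratios and averages over independent
    replicas, at the given horizons, plus the mean-field reference.

    Replica ``i`` runs with seed ``SeedSequence(config.seed).spawn``-like
    derived seed so runs are independent but reproducible.  Returns a
    tidy DataFrame with one row per (run, horizon) and a dict of
    mean-field reference rows keyed by horizon.
    """
    import pandas as pd

    from .meanfield import averages as mf_averages
    from .meanfield import iterate
    from .states import LABELS

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    horizon_ticks = tuple(int(h) for h in horizon_ticks)
    max_h = max(horizon_ticks)
    seeds = np.random.SeedSequence(config.seed).generate_state(n_runs)

    rows = []
    for i in range(n_runs):
        cfg = replace(config, ticks=max_h, seed=int(seeds[i]))
        traj = run(cfg)
        av = traj.averages
        for h in horizon_ticks:
            row = {"run": i, "tick": h}
            row.update(
                {f"n_{lab}": traj.compositions[h, j] for j, lab in enumerate(LABELS)}
            )
            row["avg_E"], row["avg_I"], row["avg_O"] = av[h]
            rows.append(row)
    df = pd.DataFrame(rows)

    mf_traj, _, _, _ = iterate(
        config.initial, config.mode, config.media, tol=0.0 + 1e-300,
        max_iter=max_h, record=True,
    )
    reference = {}
    for h in horizon_ticks:
        comp = mf_traj.compositions[min(h, mf_traj.ticks)]
        ref = {f"n_{lab}": float(v) for lab, v in zip(LABELS, comp)}
        e, i_, o = mf_averages(comp)
        ref.update({"avg_E": e, "avg_I": i_, "avg_O": o})
        reference[h] = ref
    return df, reference
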