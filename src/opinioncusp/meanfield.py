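"""Deterministic population dynamics on the 6-simplex.

The population state is a *composition*: the vector of occupation
fractions ``n = (n_CMM, n_C00, n_CPP, n_AMM, n_A0M, n_A0P, n_APP)`` in
canonical order.  In the infinite-population (mean-field) limit, one
synchronous communication round maps the composition through a quadratic
polynomial map:

* **single-message mode** -- every agent reads one message drawn from the
  population, ``n'_X = sum_{R,S} n_R n_S [receive(R, S) = X]``;
* **full-conversation mode** -- every agent is the second party (first
  recipient) of a complete conversation with a partner drawn from the
  population and adopts its second-agent final state.

External media inject extra messages at per-state rates ``r_X`` relative
to the agent population, so an agent reads a media message of state M
with probability ``r_M / (1 + R)``, ``R = sum r``, and a peer message
otherwise.  Media are always processed in single-message mode (one cannot
talk back to a broadcast).

The module provides the step maps, trajectory iteration, fixed-point and
stability analysis (including the calm-only submodel), classification of
converged compositions into the model's stationary families, flat simplex
sampling, basin-of-attraction frequencies, and media-rate scans with
critical-rate bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .microdynamics import CONV_SECOND, RECV
from .states import MIRROR_PERM, N_STATES, all_states, parse_label

__all__ = [
    "MODES",
    "MediaSource",
    "StabilityReport",
    "Trajectory",
    "MediaScanResult",
    "as_composition",
    "composition_from_labels",
    "averages",
    "mirror_composition",
    "step_single",
    "step_conversation",
    "step",
    "iterate",
    "jacobian",
    "calm_only_fixed_points",
    "classify_family",
    "sample_uniform_composition",
    "basin_frequencies",
    "media_scan",
    "FAMILY_MINUS",
    "FAMILY_PLUS",
    "RESIDUAL_MINUS",
    "RESIDUAL_PLUS",
    "NEUTRAL_CALM",
    "OTHER",
]

MODES = ("single", "conversation")

_SUM_TOL = 1e-12

# per-state attribute vectors (canonical order) for population averages
_EMOTION = np.array([s.emotion for s in all_states()], dtype=float)
_INFORMATION = np.array([s.information for s in all_states()], dtype=float)
_OPINION = np.array([s.opinion for s in all_states()], dtype=float)

_MIRROR = np.asarray(MIRROR_PERM, dtype=np.intp)

# one-hot transition tensors: T[r, s, x] = 1 iff the focal agent in state r
# paired with source s ends in state x
_EYE = np.eye(N_STATES)
_T_SINGLE = _EYE[RECV]          # (7, 7, 7)
_T_CONV = _EYE[CONV_SECOND]     # (7, 7, 7)

# calm-only single-message submodel: indices of CMM, C00, CPP
_CALM = np.array([0, 1, 2], dtype=np.intp)

# family labels
FAMILY_MINUS = "FAMILY_MINUS"
FAMILY_PLUS = "FAMILY_PLUS"
RESIDUAL_MINUS = "RESIDUAL_MINUS"
RESIDUAL_PLUS = "RESIDUAL_PLUS"
NEUTRAL_CALM = "NEUTRAL_CALM"
OTHER = "OTHER"

FAMILY_LABELS = (
    FAMILY_MINUS,
    FAMILY_PLUS,
    RESIDUAL_MINUS,
    RESIDUAL_PLUS,
    NEUTRAL_CALM,
    OTHER,
)


def as_composition(n, *, check: bool = True) -> np.ndarray:
    """Coerce to a validated composition vector of length 7."""
    arr = np.asarray(n, dtype=float).reshape(-1)
    if arr.shape != (N_STATES,):
        raise ValueError(f"composition must have {N_STATES} entries, got {arr.shape}")
    if check:
        if np.any(arr < -_SUM_TOL) or np.any(arr > 1 + _SUM_TOL):
            raise ValueError("composition entries must lie in [0, 1]")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"composition must sum to 1, got {arr.sum()!r}")
    return arr


def composition_from_labels(fractions: dict) -> np.ndarray:
    """Build a composition from a ``{label: fraction}`` mapping; omitted
    states get fraction 0."""
    from .states import STATE_INDEX

    n = np.zeros(N_STATES)
    for key, value in fractions.items():
        n[STATE_INDEX[parse_label(key)]] = float(value)
    return as_composition(n)


def mirror_composition(n: np.ndarray) -> np.ndarray:
    """Apply the plus/minus mirror symmetry to a composition."""
    return np.asarray(n, dtype=float)[..., _MIRROR]


@dataclass(frozen=True)
class MediaSource:
    """Nonnegative per-state media message rates relative to the agent
    population.  ``rates`` follows the canonical state order."""

    rates: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float).reshape(-1)
        if r.shape != (N_STATES,):
            raise ValueError(f"media rates must have {N_STATES} entries")
        if np.any(r < 0) or not np.all(np.isfinite(r)):
            raise ValueError("media rates must be finite and nonnegative")
        object.__setattr__(self, "rates", r)

    @classmethod
    def from_labels(cls, rates: dict) -> "MediaSource":
        from .states import STATE_INDEX

        r = np.zeros(N_STATES)
        for key, value in rates.items():
            r[STATE_INDEX[parse_label(key)]] = float(value)
        return cls(r)

    @property
    def total(self) -> float:
        return float(self.rates.sum())

    def scaled_to(self, total: float) -> "MediaSource":
        """Rescale the rate mix to a given total rate."""
        if self.total == 0:
            if total == 0:
                return self
            raise ValueError("cannot rescale an all-zero media template")
        return MediaSource(self.rates * (total / self.total))

    def mirrored(self) -> "MediaSource":
        return MediaSource(self.rates[_MIRROR])


def averages(n: np.ndarray) -> tuple[float, float, float]:
    """Occupation-weighted (mean emotion, mean information, mean opinion)."""
    n = as_composition(n)
    return (
        float(n @ _EMOTION),
        float(n @ _INFORMATION),
        float(n @ _OPINION),
    )


def _message_distribution(n: np.ndarray, media: MediaSource | None) -> np.ndarray:
    """Probability distribution over message states read by one agent."""
    if media is None or media.total == 0:
        return n
    return (n + media.rates) / (1.0 + media.total)


def _raw_step(n: np.ndarray, mode: str, media: MediaSource | None) -> np.ndarray:
    """Polynomial step map evaluated without simplex validation (used for
    numerical differentiation, where off-simplex probes are legitimate)."""
    n = np.asarray(n, dtype=float)
    if mode == "single":
        q = _message_distribution(n, media)
        return np.einsum("r,s,rsx->x", n, q, _T_SINGLE)
    if mode == "conversation":
        if media is None or media.total == 0:
            return np.einsum("r,s,rsx->x", n, n, _T_CONV)
        w_peer = 1.0 / (1.0 + media.total)
        peer = np.einsum("r,s,rsx->x", n, n * w_peer, _T_CONV)
        med = np.einsum("r,s,rsx->x", n, media.rates * w_peer, _T_SINGLE)
        return peer + med
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def _normalized_step(n: np.ndarray, mode: str, media: MediaSource | None) -> np.ndarray:
    # the quadratic map sends the simplex-sum error eps to ~2*eps, so the
    # tiny float drift must be projected out at every step
    out = _raw_step(n, mode, media)
    return out / out.sum()


def step_single(n: np.ndarray, media: MediaSource | None = None) -> np.ndarray:
    """One synchronous round in single-message mode."""
    return _normalized_step(as_composition(n), "single", media)


def step_conversation(n: np.ndarray, media: MediaSource | None = None) -> np.ndarray:
    """One synchronous round in full-conversation mode.

    The focal agent is the first recipient (second party) of a complete
    conversation with a partner drawn from the composition; media
    messages, read with probability ``r_M / (1 + R)``, are processed as
    single messages.
    """
    return _normalized_step(as_composition(n), "conversation", media)


def step(n: np.ndarray, mode: str, media: MediaSource | None = None) -> np.ndarray:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    return _normalized_step(as_composition(n), mode, media)


@dataclass
class Trajectory:
    """Time series of compositions and population averages.

    ``compositions`` has shape ``(ticks + 1, 7)``; row 0 is the initial
    composition.  ``averages`` has shape ``(ticks + 1, 3)`` with columns
    (mean emotion, mean information, mean opinion).
    """

    compositions: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def averages(self) -> np.ndarray:
        attrs = np.stack([_EMOTION, _INFORMATION, _OPINION], axis=1)
        return self.compositions @ attrs

    @property
    def ticks(self) -> int:
        return self.compositions.shape[0] - 1

    def to_frame(self):
        """Tidy DataFrame: tick, n_<state>..., avg_E, avg_I, avg_O."""
        import pandas as pd

        from .states import LABELS

        df = pd.DataFrame(
            self.compositions, columns=[f"n_{lab}" for lab in LABELS]
        )
        av = self.averages
        df.insert(0, "tick", np.arange(len(df)))
        df["avg_E"], df["avg_I"], df["avg_O"] = av[:, 0], av[:, 1], av[:, 2]
        return df


def iterate(
    n0: np.ndarray,
    mode: str = "single",
    media: MediaSource | None = None,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    record: bool = True,
) -> tuple[Trajectory, np.ndarray, bool, int]:
    """Iterate the step map until the L1 change drops below ``tol``.

    Returns ``(trajectory, final composition, converged flag, iterations
    used)``.  Non-convergence is reported through the flag, not raised.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    n = as_composition(n0)
    history = [n.copy()] if record else None
    converged = False
    used = 0
    for used in range(1, max_iter + 1):
        nxt = _normalized_step(n, mode, media)
        delta = float(np.abs(nxt - n).sum())
        n = nxt
        if record:
            history.append(n.copy())
        if delta < tol:
            converged = True
            break
    comps = np.asarray(history) if record else np.asarray([n])
    traj = Trajectory(
        comps,
        meta={"mode": mode, "tol": tol, "max_iter": max_iter, "converged": converged},
    )
    return traj, n, converged, used


# ---------------------------------------------------------------------------
# stability analysis
# ---------------------------------------------------------------------------

#: orthonormal basis of the sum-zero tangent space (7 x 6)
def _tangent_basis(dim: int) -> np.ndarray:
    # Helmert-style basis: columns orthonormal, each summing to zero
    basis = np.zeros((dim, dim - 1))
    for k in range(1, dim):
        basis[:k, k - 1] = 1.0
        basis[k, k - 1] = -k
        basis[:, k - 1] /= np.sqrt(k * (k + 1))
    return basis

_B7 = _tangent_basis(N_STATES)
_B3 = _tangent_basis(3)


@dataclass
class StabilityReport:
    """Eigenvalues of the linearized step map on the sum-zero tangent
    space and the resulting classification."""

    eigenvalues: np.ndarray
    classification: str
    marginal_band: float

    @property
    def moduli(self) -> np.ndarray:
        return np.abs(self.eigenvalues)


def _classify_eigenvalues(eigvals: np.ndarray, band: float) -> str:
    mod = np.abs(eigvals)
    if np.all(mod < 1 - band):
        return "attractor"
    if np.all(mod > 1 + band):
        return "repeller"
    if np.any(mod > 1 + band) and np.any(mod < 1 - band) and not np.any(
        np.abs(mod - 1) <= band
    ):
        return "saddle"
    return "marginal"


def _numeric_jacobian(func, x: np.ndarray, basis: np.ndarray, h: float) -> np.ndarray:
    cols = []
    for k in range(basis.shape[1]):
        v = basis[:, k]
        cols.append((func(x + h * v) - func(x - h * v)) / (2 * h))
    J = np.stack(cols, axis=1)       # d(step) / d(tangent coords)
    return basis.T @ J               # project back onto tangent coords


def jacobian(
    n: np.ndarray,
    mode: str = "single",
    media: MediaSource | None = None,
    step_size: float = 1e-6,
    marginal_band: float = 1e-4,
) -> StabilityReport:
    """Central-difference linearization of the step map at a composition,
    restricted to the sum-zero tangent space."""
    n = as_composition(n)
    J = _numeric_jacobian(lambda x: _raw_step(x, mode, media), n, _B7, step_size)
    eig = np.linalg.eigvals(J)
    return StabilityReport(eig, _classify_eigenvalues(eig, marginal_band), marginal_band)


def _calm_step_single(v: np.ndarray) -> np.ndarray:
    """Single-message map restricted to the calm face (m, z, p)."""
    m, z, p = v
    return np.array([m * m + 2 * m * z, z * z + 2 * m * p, p * p + 2 * p * z])


def calm_only_fixed_points(
    mode: str = "single",
    grid: int = 40,
    marginal_band: float = 1e-4,
) -> list[tuple[np.ndarray, StabilityReport]]:
    """Fixed points of the calm-only submodel (support on CMM, C00, CPP).

    ``mode='single'``: locate every fixed point of the restricted
    quadratic map by Newton refinement from a simplex grid and return each
    with its 2-dimensional tangent stability.  The result contains the two
    consensus attractors, the symmetric interior saddle at equal thirds,
    and the repelling pure-C00 point.

    ``mode='conversation'``: on the calm face the uninformed fraction
    obeys ``z' = z**2``, so every composition on the informed calm edge
    (``z = 0``) is stationary; a sample of edge points (plus pure C00) is
    returned with marginal classifications.

    Returned compositions are full 7-vectors (agitated entries zero).
    """
    if mode == "conversation":
        out = []
        for m in np.linspace(0.0, 1.0, grid + 1):
            v = np.array([m, 0.0, 1.0 - m])
            full = np.zeros(N_STATES)
            full[_CALM] = v
            out.append((full, jacobian(full, "conversation",
                                       marginal_band=marginal_band)))
        c00 = np.zeros(N_STATES)
        c00[1] = 1.0
        out.append((c00, jacobian(c00, "conversation", marginal_band=marginal_band)))
        return out
    if mode != "single":
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")

    from scipy.optimize import fsolve

    def residual(mp):
        m, p = mp
        z = 1.0 - m - p
        out = _calm_step_single(np.array([m, z, p]))
        return [out[0] - m, out[2] - p]

    found: list[np.ndarray] = []
    ticks = np.linspace(0.0, 1.0, grid + 1)
    for m0 in ticks:
        for p0 in ticks:
            if m0 + p0 > 1 + 1e-12:
                continue
            sol, _, ier, _ = fsolve(residual, [m0, p0], full_output=True)
            if ier != 1:
                continue
            m, p = sol
            z = 1.0 - m - p
            v = np.array([m, z, p])
            if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
                continue
            v = np.clip(v, 0.0, 1.0)
            v /= v.sum()
            if not any(np.abs(v - w).sum() < 1e-7 for w in found):
                found.append(v)

    results = []
    for v in sorted(found, key=lambda w: (round(w[0], 8), round(w[2], 8))):
        J = _numeric_jacobian(_calm_step_single, v, _B3, 1e-6)
        eig = np.linalg.eigvals(J)
        full = np.zeros(N_STATES)
        full[_CALM] = v
        results.append(
            (full, StabilityReport(eig, _classify_eigenvalues(eig, marginal_band),
                                   marginal_band))
        )
    return results


# ---------------------------------------------------------------------------
# stationary-family classification and basins of attraction
# ---------------------------------------------------------------------------

def classify_family(
    n: np.ndarray,
    tol: float = 1e-6,
    mode: str = "single",
) -> str:
    """Assign an approximately stationary composition to a stationary
    family.

    * ``FAMILY_MINUS`` -- support on {CMM, AMM, A0P} with the agitated
      majority block exactly balanced by the agitated uninformed minority
      (``n_AMM == n_A0P``); includes the pure-CMM consensus.
    * ``FAMILY_PLUS`` -- the mirror image.
    * ``NEUTRAL_CALM`` -- pure C00.
    * ``RESIDUAL_MINUS`` / ``RESIDUAL_PLUS`` -- any other stationary
      composition, split by the sign of its mean opinion.
    * ``OTHER`` -- not stationary within ``tol`` (or mean opinion
      indistinguishable from zero in the residual branch).
    """
    n = as_composition(n)
    if float(np.abs(_raw_step(n, mode, None) - n).sum()) > tol:
        return OTHER
    cmm, c00, cpp, amm, a0m, a0p, app = n
    if c00 >= 1 - tol:
        return NEUTRAL_CALM
    if max(c00, cpp, a0m, app) <= tol and abs(amm - a0p) <= tol:
        return FAMILY_MINUS
    if max(cmm, c00, a0p, amm) <= tol and abs(app - a0m) <= tol:
        return FAMILY_PLUS
    mean_opinion = float(n @ _OPINION)
    if mean_opinion > tol:
        return RESIDUAL_PLUS
    if mean_opinion < -tol:
        return RESIDUAL_MINUS
    return OTHER


def sample_uniform_composition(
    rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Draw from the flat (Dirichlet(1, ..., 1)) distribution on the
    6-simplex.  With ``size`` given, returns a ``(size, 7)`` array."""
    if size is None:
        return rng.dirichlet(np.ones(N_STATES))
    return rng.dirichlet(np.ones(N_STATES), size=size)


def _batch_step(batch: np.ndarray, tensor: np.ndarray) -> np.ndarray:
    out = np.einsum("br,bs,rsx->bx", batch, batch, tensor, optimize=True)
    return out / out.sum(axis=1, keepdims=True)


def basin_frequencies(
    n_samples: int = 10_000,
    mode: str = "single",
    seed: int = 0,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    classify_tol: float = 1e-6,
) -> dict[str, float]:
    """Estimate basin-of-attraction frequencies of the stationary families.

    Samples ``n_samples`` initial compositions uniformly from the simplex,
    iterates the mode's step map to an L1 fixed-point tolerance of
    ``tol``, classifies each converged composition, and returns the
    relative frequency of every family label (the six labels always
    present, frequencies summing to 1; non-converged runs count as
    ``OTHER``).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    tensor = _T_SINGLE if mode == "single" else _T_CONV
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    rng = np.random.default_rng(seed)
    batch = sample_uniform_composition(rng, n_samples)
    active = np.arange(n_samples)
    final = batch.copy()
    for _ in range(max_iter):
        if active.size == 0:
            break
        cur = final[active]
        nxt = _batch_step(cur, tensor)
        delta = np.abs(nxt - cur).sum(axis=1)
        final[active] = nxt
        active = active[delta >= tol]
    counts = {lab: 0 for lab in FAMILY_LABELS}
    converged = np.ones(n_samples, dtype=bool)
    converged[active] = False
    for i in range(n_samples):
        lab = classify_family(final[i], classify_tol, mode) if converged[i] else OTHER
        counts[lab] += 1
    return {lab: c / n_samples for lab, c in counts.items()}


# ---------------------------------------------------------------------------
# external propaganda scans
# ---------------------------------------------------------------------------

@dataclass
class MediaScanResult:
    """Per-rate outcomes of a media scan plus the estimated critical rate."""

    records: list[dict]
    critical_rate: float | None
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)


def _metastable_lifetime(
    traj: Trajectory,
    final: np.ndarray,
    slow_threshold: float = 2e-2,
    separation_threshold: float = 0.5,
) -> int:
    """Number of ticks during which the composition barely moves
    (L1 step change below ``slow_threshold``) while still far from the
    eventual fixed point (L1 distance above ``separation_threshold``)."""
    comps = traj.compositions
    if len(comps) < 2:
        return 0
    steps = np.abs(np.diff(comps, axis=0)).sum(axis=1)
    dist = np.abs(comps[1:] - final).sum(axis=1)
    return int(np.sum((steps < slow_threshold) & (dist > separation_threshold)))


def _final_opinion(
    n0: np.ndarray,
    media: MediaSource,
    mode: str,
    tol: float,
    max_iter: int,
) -> float:
    _, final, _, _ = iterate(n0, mode, media, tol, max_iter, record=False)
    return float(final @ _OPINION)


def media_scan(
    n0: np.ndarray,
    media_template: MediaSource,
    r_grid,
    mode: str = "single",
    tol: float = 1e-10,
    max_iter: int = 100_000,
    slow_threshold: float = 2e-2,
    separation_threshold: float = 0.5,
    bisection_steps: int = 25,
) -> MediaScanResult:
    """Scan total media rates, recording final compositions, averages,
    convergence iterations and metastable lifetimes, and estimate the
    critical rate (where the final mean opinion changes sign) by
    bisection between the bracketing grid points."""
    r_grid = np.asarray(list(r_grid), dtype=float)
    if r_grid.size == 0:
        raise ValueError("r_grid must not be empty")
    n0 = as_composition(n0)
    records = []
    for r in r_grid:
        media = media_template.scaled_to(float(r)) if r > 0 else None
        traj, final, converged, used = iterate(n0, mode, media, tol, max_iter)
        e, i, o = averages(final)
        rec = {
            "r": float(r),
            "iterations": used,
            "converged": converged,
            "lifetime": _metastable_lifetime(
                traj, final, slow_threshold, separation_threshold
            ),
            "avg_E": e,
            "avg_I": i,
            "avg_O": o,
        }
        from .states import LABELS

        rec.update({f"n_{lab}": float(v) for lab, v in zip(LABELS, final)})
        records.append(rec)

    critical = None
    opinions = np.array([rec["avg_O"] for rec in records])
    signs = np.sign(opinions)
    flips = np.nonzero(signs[:-1] * signs[1:] < 0)[0]
    if flips.size:
        k = int(flips[0])
        lo, hi = float(r_grid[k]), float(r_grid[k + 1])
        f_lo = opinions[k]
        for _ in range(bisection_steps):
            mid = 0.5 * (lo + hi)
            f_mid = _final_opinion(
                n0, media_template.scaled_to(mid), mode, tol, max_iter
            )
            if np.sign(f_mid) == np.sign(f_lo):
                lo, f_lo = mid, f_mid
            else:
                hi = mid
        critical = 0.5 * (lo + hi)

    return MediaScanResult(
        records=records,
        critical_rate=critical,
        meta={
            "mode": mode,
            "tol": tol,
            "max_iter": max_iter,
            "slow_threshold": slow_threshold,
            "separation_threshold": separation_threshold,
        },
    )
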