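"""Configuration files, trajectory I/O, named fixtures and scripted
experiments.

Configs are flat YAML-compatible key-value files; compositions and media
rates are written as ``{STATE: fraction}`` mappings using the canonical
three-letter labels.  Every experiment writes a resolved-config echo next
to its outputs so any run can be reproduced bit-identically from the
echo alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import abm, meanfield as mf
from .meanfield import MediaSource, Trajectory, as_composition, composition_from_labels
from .states import LABELS

__all__ = [
    "FIXTURES",
    "Fixture",
    "get_fixture",
    "ExperimentConfig",
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "run_paper_suite",
]

_TRAJECTORY_HEADER = (
    ["tick"] + [f"n_{lab}" for lab in LABELS] + ["avg_E", "avg_I", "avg_O"]
)


@dataclass(frozen=True)
class Fixture:
    """A named, versioned starting composition."""

    name: str
    composition: np.ndarray
    description: str


def _fixture(name: str, fractions: dict, description: str) -> Fixture:
    return Fixture(name, composition_from_labels(fractions), description)


#: Named starting compositions used by the scripted experiments.  The
#: media-scan scenario needs a society that initially leans against the
#: propaganda; the published experiments do not print their starting
#: compositions, so these stand-ins (synthetic by construction) define
#: the package's reference scenarios.
FIXTURES: dict[str, Fixture] = {
    f.name: f
    for f in (
        _fixture(
            "negative-lean",
            {"CMM": 0.30, "C00": 0.20, "CPP": 0.10,
             "AMM": 0.15, "A0M": 0.10, "A0P": 0.05, "APP": 0.10},
            "calm-majority society leaning to the negative opinion "
            "(mean opinion -0.30); reference start for propaganda scans",
        ),
        _fixture(
            "calm-split",
            {"CMM": 0.40, "C00": 0.20, "CPP": 0.40},
            "purely calm society split between the two opinions with an "
            "uninformed middle",
        ),
        _fixture(
            "balanced-minority",
            {"CMM": 0.60, "AMM": 0.20, "A0P": 0.20},
            "member of the negative-majority stationary family: calm "
            "majority, agitated majority block balanced by the agitated "
            "uninformed minority",
        ),
    )
}


def get_fixture(name: str, seed: int | None = None) -> Fixture:
    """Look up a named fixture; ``uniform-random`` draws a flat-simplex
    composition from the given seed."""
    if name == "uniform-random":
        if seed is None:
            raise ValueError("uniform-random fixture requires a seed")
        rng = np.random.default_rng(seed)
        return Fixture(
            f"uniform-random({seed})",
            mf.sample_uniform_composition(rng),
            "flat-simplex random composition",
        )
    try:
        return FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; known: {', '.join(FIXTURES)}, uniform-random"
        ) from None


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_KINDS = ("tables", "converse", "meanfield", "abm", "ensemble", "basins",
          "media-scan", "paper-suite")

_COMMON_KEYS = {"kind", "seed", "out"}
_KIND_KEYS = {
    "tables": set(),
    "converse": {"starter", "second", "max_rounds"},
    "meanfield": {"composition", "fixture", "mode", "media", "tol", "max_iter"},
    "abm": {"composition", "fixture", "mode", "media", "n_agents", "ticks",
            "effect", "allergic", "calming", "send", "read"},
    "ensemble": {"composition", "fixture", "mode", "media", "n_agents",
                 "n_runs", "horizons"},
    "basins": {"mode", "samples", "tol", "max_iter", "classify_tol"},
    "media-scan": {"composition", "fixture", "mode", "media", "r_min", "r_max",
                   "r_steps", "tol", "max_iter"},
    "paper-suite": set(),
}

_DEFAULTS = {
    "seed": 0,
    "mode": "single",
    "tol": 1e-10,
    "max_iter": 100_000,
    "classify_tol": 1e-6,
    "samples": 10_000,
    "n_agents": 2000,
    "ticks": 500,
    "n_runs": 100,
    "horizons": [100, 500],
    "max_rounds": 8,
}


@dataclass
class ExperimentConfig:
    """A validated experiment description."""

    kind: str
    options: dict

    def echo(self) -> dict:
        out = {"kind": self.kind}
        out.update(self.options)
        return out


def _validate_mapping(mapping: dict, what: str) -> dict:
    bad = [k for k in mapping if str(k).upper() not in LABELS]
    if bad:
        raise ValueError(
            f"unknown state label(s) {bad} in {what}; valid labels: "
            f"{', '.join(LABELS)}"
        )
    return {str(k).upper(): float(v) for k, v in mapping.items()}


def load_config(path) -> ExperimentConfig:
    """Load and validate an experiment configuration file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if "kind" not in raw:
        raise ValueError(f"{path}: missing required key 'kind'")
    kind = raw["kind"]
    if kind not in _KINDS:
        raise ValueError(f"{path}: unknown kind {kind!r}; valid kinds: {_KINDS}")
    allowed = _COMMON_KEYS | _KIND_KEYS[kind]
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(
            f"{path}: unknown key(s) {sorted(unknown)} for kind {kind!r}; "
            f"allowed: {sorted(allowed)}"
        )
    options = {k: v for k, v in raw.items() if k != "kind"}
    for key, default in _DEFAULTS.items():
        if key in allowed and key not in options:
            options[key] = default
    if "composition" in options and options["composition"] is not None:
        frac = _validate_mapping(options["composition"], "composition")
        total = sum(frac.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"{path}: composition fractions must sum to 1, got {total}"
            )
        options["composition"] = frac
    if "media" in options and options["media"] is not None:
        options["media"] = _validate_mapping(options["media"], "media rates")
    return ExperimentConfig(kind=kind, options=options)


def resolve_composition(options: dict, seed: int | None = None) -> np.ndarray:
    """Composition from an options dict: explicit mapping wins, else a
    named fixture."""
    if options.get("composition"):
        return composition_from_labels(options["composition"])
    if options.get("fixture"):
        return get_fixture(options["fixture"], seed).composition
    raise ValueError("config needs either 'composition' or 'fixture'")


def resolve_media(options: dict) -> MediaSource | None:
    if options.get("media"):
        return MediaSource.from_labels(options["media"])
    return None


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV with the fixed column order
    tick, n_CMM..n_APP, avg_E, avg_I, avg_O at full float precision."""
    df = traj.to_frame()
    df.to_csv(path, index=False, columns=_TRAJECTORY_HEADER, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    import csv

    comps = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}:1: empty trajectory file") from None
        if header != _TRAJECTORY_HEADER:
            raise ValueError(
                f"{path}:1: bad header {header!r}, expected {_TRAJECTORY_HEADER!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_TRAJECTORY_HEADER):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(_TRAJECTORY_HEADER)} fields, "
                    f"got {len(row)}"
                )
            try:
                comps.append([float(x) for x in row[1:8]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return Trajectory(np.asarray(comps).reshape(-1, 7), meta={"source": str(path)})


# ---------------------------------------------------------------------------
# scripted verification / experiment suite
# ---------------------------------------------------------------------------

def _check(report: list, name: str, passed: bool, detail: str) -> None:
    report.append({"check": name, "passed": bool(passed), "detail": detail})


def run_paper_suite(outdir, seed: int = 0, quick: bool = False) -> dict:
    """Run the package's scripted study designs and verification checks.

    Executes (a) transition-table self-verification and CSV export,
    (b) the calm-only fixed-point analysis, (c) the basin-frequency
    experiment on flat-simplex starts, (d) a finite-size vs mean-field
    comparison at N = 2000, and (e) media scans on the ``negative-lean``
    fixture in both communication modes, reporting the paradoxical
    regime, the critical rate and metastable lifetimes.  Writes CSV/JSON
    outputs plus a human-readable report; returns the report dict.

    ``quick`` shrinks sample counts for smoke tests.
    """
    from .microdynamics import (
        CONV_SECOND,
        CONV_STARTER,
        RECV,
        receive_message,
        run_conversation,
        single_message_table,
        table_to_dataframe,
    )
    from .states import STATE_INDEX, all_states

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checks: list[dict] = []
    rng_seed = int(seed)

    # (a) transition tables: export and self-verification against the
    # rule primitives
    table_to_dataframe("single").to_csv(outdir / "table_single_message.csv")
    table_to_dataframe("conversation").to_csv(outdir / "table_conversation.csv")
    single_ok = all(
        RECV[STATE_INDEX[r], STATE_INDEX[s]] == STATE_INDEX[receive_message(r, s)]
        for r in all_states()
        for s in all_states()
    )
    conv_ok = True
    for second in all_states():
        for starter in all_states():
            res = run_conversation(starter, second)
            i, j = STATE_INDEX[second], STATE_INDEX[starter]
            conv_ok &= CONV_STARTER[i, j] == STATE_INDEX[res.starter_final]
            conv_ok &= CONV_SECOND[i, j] == STATE_INDEX[res.second_final]
    _check(checks, "single_message_table", single_ok, "49/49 cells recomputed")
    _check(checks, "conversation_table", conv_ok, "49/49 cells recomputed")

    # (b) calm-only fixed points of the single-message map
    fps = mf.calm_only_fixed_points("single")
    kinds = sorted(rep.classification for _, rep in fps)
    attractors = [c for c, rep in fps if rep.classification == "attractor"]
    saddles = [c for c, rep in fps if rep.classification == "saddle"]
    ok = (
        len(attractors) == 2
        and len(saddles) == 1
        and np.allclose(saddles[0][:3], 1 / 3, atol=1e-6)
    )
    _check(
        checks, "calm_only_fixed_points", ok,
        f"classifications: {kinds}; saddle at {np.round(saddles[0][:3], 4).tolist() if saddles else None}",
    )

    # (c) basin frequencies from flat-simplex starts
    n_samples = 500 if quick else 10_000
    freqs = mf.basin_frequencies(n_samples=n_samples, mode="single", seed=rng_seed)
    with open(outdir / "basin_frequencies.json", "w") as fh:
        json.dump({"seed": rng_seed, "samples": n_samples, "frequencies": freqs}, fh,
                  indent=2)
    fam = freqs["FAMILY_MINUS"], freqs["FAMILY_PLUS"]
    ok = all(abs(f - 0.47) < 0.04 for f in fam)
    _check(
        checks, "basin_frequencies", ok,
        f"mirror families at {fam[0]:.3f}/{fam[1]:.3f}, residuals "
        f"{freqs['RESIDUAL_MINUS']:.3f}/{freqs['RESIDUAL_PLUS']:.3f}",
    )

    # (d) finite-size vs mean-field at N = 2000
    fixture = FIXTURES["negative-lean"]
    n_seeds = 3 if quick else 20
    horizon = 100
    mft, _, _, _ = mf.iterate(fixture.composition, "single", tol=1e-300,
                              max_iter=horizon)
    devs = []
    for k in range(n_seeds):
        cfg = abm.SimulationConfig(
            n_agents=2000, ticks=horizon, initial=fixture.composition,
            seed=rng_seed + 1 + k,
        )
        traj = abm.run(cfg)
        devs.append(np.abs(traj.compositions - mft.compositions).max())
        if k == 0:
            write_trajectory(traj, outdir / "abm_trajectory_N2000.csv")
    write_trajectory(mft, outdir / "meanfield_trajectory.csv")
    mean_dev = float(np.mean(devs))
    _check(
        checks, "finite_size_concentration", mean_dev < 0.05,
        f"mean sup-norm deviation {mean_dev:.4f} over {n_seeds} seeds (N=2000)",
    )

    # (e) media scans on the negative-lean fixture
    cpp_media = MediaSource.from_labels({"CPP": 1.0})
    grid = np.linspace(0.01, 0.3, 7 if quick else 13)
    scan_single = mf.media_scan(fixture.composition, cpp_media, grid, "single")
    scan_single.to_frame().to_csv(outdir / "media_scan_single.csv", index=False)
    _, no_media_final, _, _ = mf.iterate(fixture.composition, "single", record=False)
    base_opinion = mf.averages(no_media_final)[2]
    low = scan_single.records[0]
    agitated_low = sum(low[f"n_{lab}"] for lab in LABELS[3:])
    paradox = (
        low["avg_O"] < base_opinion  # propaganda strengthens the opposition
        and low["n_CMM"] > 0.5
        and agitated_low < 1e-6
    )
    _check(
        checks, "paradoxical_regime", paradox,
        f"weak-rate final opinion {low['avg_O']:.3f} vs no-media "
        f"{base_opinion:.3f}, all-calm CMM majority {low['n_CMM']:.3f}",
    )
    _check(
        checks, "critical_rate", scan_single.critical_rate is not None,
        f"critical rate {scan_single.critical_rate}",
    )

    scan_conv = mf.media_scan(fixture.composition, cpp_media, grid, "conversation")
    scan_conv.to_frame().to_csv(outdir / "media_scan_conversation.csv", index=False)
    opinions = [rec["avg_O"] for rec in scan_conv.records]
    iters = [rec["iterations"] for rec in scan_conv.records]
    reversal = all(o > 0 for o in opinions) and all(
        a >= b for a, b in zip(iters, iters[1:])
    )
    _check(
        checks, "conversation_reversal", reversal,
        "propaganda reverses the majority at every rate; reversal time "
        f"decreases with rate ({iters[0]} -> {iters[-1]} iterations)",
    )

    summary = {
        "seed": rng_seed,
        "quick": quick,
        "critical_rate": scan_single.critical_rate,
        "checks": checks,
        "passed": sum(c["passed"] for c in checks),
        "total": len(checks),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    lines = [f"verification suite (seed={rng_seed})"]
    for c in checks:
        lines.append(f"[{'PASS' if c['passed'] else 'FAIL'}] {c['check']}: {c['detail']}")
    lines.append(f"{summary['passed']}/{summary['total']} checks passed")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return summary
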