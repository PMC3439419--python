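# opinioncusp

Discrete opinion dynamics with **information** and **emotional arousal**
as control variables — a seven-state, message-based agent model for
studying when societies reach consensus, when obstinate minorities
survive, and how one-sided propaganda can backfire.

## The model in one paragraph

Each agent carries a triple `(E, I, O)`: arousal `E ∈ {0 calm, 1
agitated}`, information `I ∈ {−1, 0, +1}` and opinion `O ∈ {−1, 0, +1}`.
Opinion is dependent: `I ≠ 0 ⇒ O = I`; a calm uninformed agent is
neutral; an *agitated* uninformed agent keeps a committed opinion of
either sign. This is a discretization of the cusp catastrophe —
information is the normal factor, arousal the splitting factor, and the
two agitated-uninformed states A0M/A0P are the fold where identical
control variables support conflicting opinions (hysteresis). Exactly
seven states exist: CMM, C00, CPP, AMM, A0M, A0P, APP. Agents exchange
messages that mirror their sender's state; reception rules update
arousal (opposing agitated messages anger calm agents, supportive calm
messages soothe agitated ones), information (the recipient's evidence
counts double as soon as anyone is agitated — agitated uninformed agents
cannot be convinced), and then opinion. From these microscopic rules the
package derives everything else exactly.

## What the package provides

- `opinioncusp.states` — the state algebra: validation, canonical order,
  labels, the plus/minus `mirror` symmetry.
- `opinioncusp.microdynamics` — the reception rules, both 49-pair
  transition tables (single message and full conversation) and the
  message-by-message conversation iterator.
- `opinioncusp.meanfield` — the deterministic composition dynamics
  `n'_X = Σ n_R n_S [receive(R,S)=X]` on the 6-simplex for both
  communication modes, with optional media forcing; fixed points,
  Jacobian stability, stationary-family classification, flat-simplex
  sampling, basin-of-attraction frequencies, and media-rate scans with
  critical-rate bisection.
- `opinioncusp.abm` — a finite-population synchronous simulator on the
  complete graph (reference N = 2000) with seeded reproducibility and
  probabilistic extensions (message effect, allergic arousal, calming,
  send/read activity).
- `opinioncusp.experiments` / the `opinioncusp` CLI — YAML configs,
  trajectory CSV I/O, named fixtures and a scripted verification suite.

## Worked example

Iterate the single-message mean-field dynamics from a calm-majority
society that leans negative:

```python
import numpy as np
from opinioncusp import meanfield as mf, composition_from_labels, averages

n0 = composition_from_labels({"CMM": 0.30, "C00": 0.20, "CPP": 0.10,
                              "AMM": 0.15, "A0M": 0.10, "A0P": 0.05, "APP": 0.10})
traj, final, converged, used = mf.iterate(n0, mode="single")
print("converged:", converged, "after", used, "iterations")
print("final composition:", np.round(final, 4))
print("averages (E, I, O):", np.round(averages(final), 4))
print("family:", mf.classify_family(final))
```

prints

```
converged: True after 31 iterations
final composition: [0.6646 0.     0.     0.1677 0.     0.1677 0.    ]
averages (E, I, O): [ 0.3354 -0.8323 -0.6646]
family: FAMILY_MINUS
```

The society settles into the negative *balanced-minority* family
`(1−2a, 0, 0, a, 0, a, 0)`: no undecided agents remain, a calm negative
majority (66%) coexists with an agitated negative bloc (17%) that is
exactly balanced by an agitated, uninformed, obstinately positive
minority (17%). The minority survives pure peer pressure forever — the
signature of the arousal/hysteresis mechanism.

The same from the command line, plus a conversation trace in the
reversed-pair `(recipient, sender)` notation:

```sh
$ opinioncusp converse --starter APP --second CMM
(CMM,APP) -> (APP,A0M) -> (A0M,APP) -> (APP,A0M)
finals: starter APP, second A0M; 3 messages
```

Other subcommands: `tables`, `meanfield`, `abm`, `ensemble`, `basins`,
`media-scan`, `paper-suite` (all take `--seed`, `--out` and, where
relevant, `--config`; every run writes a config echo sufficient to
reproduce it bit-identically).

Propaganda example — calm positive media on the same starting society
exhibits a *paradoxical* low-rate regime in which the opposing majority
is strengthened (final mean opinion −0.99 vs −0.66 without media), a
sharp flip at a critical rate r_c ≈ 0.084 found by bisection, and
metastable states whose lifetime diverges near r_c:

```python
scan = mf.media_scan(n0, mf.MediaSource.from_labels({"CPP": 1.0}),
                     np.linspace(0.01, 0.3, 13), mode="single")
print(scan.critical_rate)   # 0.0844820740943...
```

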