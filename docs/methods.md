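# Methods

## The model

`opinioncusp` implements a discrete opinion-dynamics model in which an
agent's opinion is a *dependent* variable determined by two control
variables, in the spirit of the cusp catastrophe: the **information** the
agent holds about the issue (the normal factor, `I ∈ {−1, 0, +1}`) and
its **emotional arousal** (the splitting factor, `E ∈ {0 calm, 1
agitated}`). The opinion `O ∈ {−1, 0, +1}` follows the rules

- `I ≠ 0  ⇒  O = I` (decisive information dictates the opinion),
- `I = 0, E = 0  ⇒  O = 0` (a calm uninformed agent is neutral),
- `I = 0, E = 1  ⇒  O ∈ {−1, +1}` (an agitated uninformed agent keeps a
  committed opinion of either sign).

The last rule is the discrete analogue of the bistable fold of the cusp
surface: at high arousal the same control variables admit two opinions,
and which one an agent holds depends on its history (hysteresis).
Exactly seven `(E, I, O)` triples are admissible — CMM, C00, CPP (calm)
and AMM, A0M, A0P, APP (agitated) — labelled first by emotion, then
information, then opinion. All vectors and files use this canonical
order. The `mirror` operator (negate `I` and `O`, keep `E`) is the
model's plus/minus symmetry; it is an index permutation in the canonical
order, and all dynamics are equivariant under it.

## Microscopic interaction

Agents communicate by messages that carry their author's full state. On
reception:

- **Emotion.** An agitated message angers a calm recipient holding the
  opposite nonzero opinion (it becomes agitated) and leaves everyone
  else's arousal unchanged; a calm message calms an agitated recipient
  only if it voices the same nonzero opinion, and never agitates anyone.
  Neutral C00 messages neither calm nor agitate.
- **Information.** When both parties are calm, the two evidence values
  carry equal weight: opposite decisive values cancel to 0 and a decisive
  message convinces an uninformed recipient. As soon as either party is
  agitated, the recipient's own evidence counts double: uninformed
  recipients are never convinced, while opposed decisive values still
  cancel.
- **Opinion** then follows from the new `(E, I)` with the hysteresis rule
  above.

Both updates read the *pre-interaction* states; in particular, the
"anyone agitated?" flag of the information rule ignores the emotional
outcome of the same event. This simultaneity is required to reproduce
the reference single-message table (e.g. A0P reading a CPP message must
end C00, not CPP).

Two interaction units exist. In **single-message mode** one directed
message is processed and only the recipient changes. In **full
conversation mode** the two agents alternate messages — no-effect
messages are still exchanged — until a full two-message round changes
neither agent (two-sided stability). All 49 ordered pairs stabilize
within at most six messages; the configurable cap (default 8 rounds)
exists only to guard hypothetical rule variants. The conversation matrix
is genuinely asymmetric: between calm informed opponents the *starter*
wins (CPP starting against CMM converts it, and vice versa).

An important consequence of the rules is **obstinacy**: an agitated
uninformed agent (A0M/A0P) confronted with any stream of agitated
opposing messages never changes its opinion. This single mechanism makes
stable mixed societies and resistant minorities possible without any
network structure.

## Mean-field dynamics

With all-to-all communication and every agent reading one message per
round, the composition `n` (the vector of the seven occupation
fractions) evolves by a quadratic map on the 6-simplex:

- single-message mode: `n'_X = Σ_{R,S} n_R n_S [receive(R, S) = X]`;
- conversation mode: the focal agent is the *first recipient* of a full
  conversation with a partner drawn from the composition and adopts its
  second-agent final. Only the focal agent updates: its partner is
  concurrently updating from its own draw, so a both-update rule would
  double-count transitions and break the stationarity of the balanced
  families.

Media messages with per-state rates `r_X` (relative to the agent
population, total `R`) enter the message pool: an agent reads a media
message of state M with probability `r_M / (1 + R)`, and media are always
processed as single messages even in conversation mode (no talking
back).

A numerical detail: the quadratic map sends a simplex-sum error `ε` to
`≈ 2ε`, so iterating the raw polynomial amplifies float roundoff
geometrically. Every public step therefore renormalizes the output sum;
the raw polynomial is retained internally for Jacobian probes, which
legitimately evaluate off-simplex points.

### Fixed points, families and stability

Known stationary structures, all verified by the test suite:

- **Balanced-minority families.** `(n_CMM, n_AMM, n_A0P) = (1−2a, a, a)`
  is a fixed point of *both* mode maps for all `a ∈ [0, ½]`, as is its
  mirror. These describe a society with no undecided agents where the
  agitated part of the majority is exactly balanced by an agitated,
  uninformed, obstinate minority. Consensus (`a = 0`) is the family
  endpoint, so consensus is *marginal* in the full state space (it ends a
  continuum of fixed points) even though it is attracting within the calm
  face.
- **Calm-only submodel** (support on CMM, C00, CPP; closed under
  single-message dynamics). Writing `m, z, p` for the three fractions,
  the map is `m' = m² + 2mz`, `z' = z² + 2mp`, `p' = p² + 2pz`. Root
  finding over the face (Newton refinement from a 40×40 grid, duplicates
  merged at 1e−7) finds four fixed points: the two consensus attractors,
  the symmetric interior point at equal thirds — a saddle, its tangent
  eigenvalues (0, 4/3) straddling modulus 1 — and the pure-C00 point,
  which is a repeller (all eigenvalue moduli 2) and is reported rather
  than suppressed.
- In conversation mode the uninformed calm fraction obeys `z' = z²`, so
  any composition on the informed calm edge (`z = 0`) is stationary,
  while the signed imbalance grows as `(m − p)' = (1 + z)(m − p)` until
  `z` vanishes.
- **Residual families.** Random simplex starts occasionally converge to
  stationary compositions outside the balanced families; empirically
  these have `n_CMM = n_CPP = 0`, a persistent C00 fraction and a
  majority of agitated agents. Their algebraic form is not derived here;
  they are classified operationally by the sign of the mean opinion
  (`RESIDUAL_MINUS` / `RESIDUAL_PLUS`).

Stability is assessed by central-difference linearization (default step
1e−6) projected on the sum-zero tangent space, classifying eigenvalue
moduli against 1 with a marginal band (default 1e−4). Points with any
modulus inside the band — e.g. every balanced-family member, whose
family direction is neutral — are reported `marginal`.

### Basins of attraction

`basin_frequencies` draws initial compositions from the flat Dirichlet
distribution on the full 6-simplex, iterates to an L1 fixed-point
tolerance of 1e−10 (cap 1e5; in practice a few hundred iterations
suffice), and classifies with tolerance 1e−6 (a converged point sits
well inside 1e−6 of its family; the classification is insensitive to
this value over several orders of magnitude). With 10,000 samples the
single-message map yields the two balanced families at ≈47% each and the
two residual classes at ≈3% each; the mirror symmetry of sampler and
dynamics forces the paired frequencies to agree within Monte-Carlo
error.

### Propaganda scans

`media_scan` iterates the forced map over a grid of total media rates
and reports final compositions, averages, iterations and a metastable
lifetime, then brackets the **critical rate** — the rate at which the
sign of the final mean opinion flips — by bisection (25 steps).

On the `negative-lean` fixture with calm positive (CPP) media in
single-message mode the model shows the characteristic phenomenology:

- *Paradoxical regime.* Below the critical rate the final population is
  entirely calm with a **strengthened** negative majority (the media calm
  down agitated positive agents, who are then absorbed by the larger
  calm negative bloc).
- *Sharp transition.* Above the critical rate the media majority takes
  over; the flip is discontinuous in the final state.
- *Metastability.* Near the critical rate the trajectory lingers on a
  plateau with a persistent calm-uninformed fraction before collapsing
  to either final state. The lifetime detector counts ticks whose L1
  step change is below 2e−2 while the L1 distance to the eventual fixed
  point exceeds 0.5; these thresholds were set by inspecting the plateau
  (it moves at step ≈5e−3 while sitting ≈1.5 away from the final state)
  and make the lifetime grow monotonically, roughly like
  `−log|r − r_c|`, as the rate approaches the critical value from either
  side.

In conversation mode there is no paradoxical regime: any positive rate
of calm positive media eventually reverses the majority, and what the
rate controls is the reversal *time*, which decreases monotonically with
the rate (the final mean opinion itself drifts slightly *down* with the
rate as stronger forcing leaves more residual agitation).

## Finite-size simulator

The ABM places N agents (reference size 2000, matching the deterministic
comparisons; any N ≥ 2 is accepted) on the complete graph. A tick is
synchronous: every agent draws one source from the time-t snapshot — a
media state with probability `r_M/(1+R)`, else the state of a uniformly
chosen *other* agent — and all agents adopt their new states at once.
Initial populations are built by largest-remainder rounding of `N·n`
(ties by canonical order), so empirical fractions recover the target
within 1/N per state. One named RNG stream (`numpy.random.default_rng`)
per run, seed echoed in outputs, makes trajectories bit-reproducible.

The simulator differs from the mean-field map only through multinomial
sampling noise and the self-exclusion of partner draws (an O(1/N)
effect): at N = 2000 the sup-norm deviation from the deterministic
trajectory over 100 ticks, averaged over 20 seeds, stays below 0.05.

### Probabilistic extensions

Optional per-agent, per-tick branch probabilities relax the
deterministic rules; the defaults (effect 1, allergic 0, calming 0,
send 1, read 1) reproduce the deterministic tick bit-for-bit (the
deterministic branch draws no extra randoms). Branch order per agent:
decide send (activity bookkeeping only — the message pool is always the
population snapshot), decide read; a read message takes effect with the
effect probability; an **allergic** calm agent treats an opposing calm
message as its agitated twin (CPP reading CMM becomes A0P instead of
C00) with the allergic probability, which is the only mechanism that
creates arousal in an initially calm society; an agitated agent that
neither sent nor read **calms** with the calming probability via
AMM→CMM, APP→CPP, A0M→C00, A0P→C00. In conversation mode the allergic
reinterpretation substitutes the partner's state with its agitated twin
before the conversation lookup; the published description covers only
the single-message case, so this is a deliberate generalization.

## Synthetic fixtures

The reference experiments behind the published trajectory and scan
figures do not come with printed initial compositions, so the package
defines named synthetic fixtures: `negative-lean` (calm-majority society
with mean opinion −0.30; the propaganda-scan start), `calm-split`, and
`balanced-minority`, plus seeded `uniform-random` draws. The generators
emulate the study conditions — composition-level initial states,
complete-graph mixing, one read per tick — but none of the structure of
real communication (degree heterogeneity, bursty activity, message
selection), so passing tests validate the dynamics, not any empirical
claim about real fora.

## Problem sizes and defaults

| quantity | default | note |
|---|---|---|
| fixed-point tolerance (L1) | 1e−10 | quadratic map, cheap steps |
| iteration cap | 1e5 | never reached in practice |
| family classification tolerance | 1e−6 | see above |
| basin samples | 10,000 | per-class Monte-Carlo s.e. ≈ 0.5 pp |
| ABM size / ticks | 2000 / 500 | reference finite-size setup |
| ensemble replicas | 100 (configurable) | distributions at ticks 100/500 |
| Jacobian step / marginal band | 1e−6 / 1e−4 | central differences |
| conversation round cap | 8 | observed maximum is 3 rounds |

## Known limitations

- Only the complete interaction graph is implemented; the interface
  takes a population vector, so topologies would require a different
  tick kernel.
- The residual stationary families and the conversation-mode mixed
  family are characterized operationally (by classification), not
  symbolically.
- The critical rate is estimated for a *fixed* initial composition; it
  genuinely depends on the start, and no attempt is made to map the full
  phase boundary.
- Emotion has two levels and no valence; messages cannot differ from
  their author's state; agents are homogeneous apart from the shared
  branch probabilities.
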