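# Methods

`dnfreach` simulates context-dependent reach-goal selection with an adaptive
dynamic neural field (DNF) model: a small network of continuous attractor
fields that perceives spatial and contextual cues, holds them in working
memory, learns arbitrary cue-to-goal mappings from binary reward, and selects
a single reach direction by winner-take-all competition.  This note describes
the model, the choices made where the design was genuinely open, and what the
simulations do and do not show.

## Field dynamics

Every field obeys the Amari rate equation

    tau du(x,t)/dt = -u + h + s(x,t) + (k * f(u))(x) + q xi(t),

with logistic output `f(u) = 1/(1+exp(-beta u))` (soft threshold at zero),
resting level `h < 0`, external input `s`, lateral interaction kernel `k`
(local Gaussian excitation, global inhibition), and additive Gaussian noise.
Integration is explicit Euler at `dt = 1` model time unit with `tau = 10`
(so `dt = tau/10`); the per-step noise increment scales with `sqrt(dt)` so
the injected variance per unit time is step-size invariant.  Kernels are
applied with grid-spacing (integral) weighting, which makes the dynamic
regimes approximately invariant under lattice resampling.

Three regimes are used and are enforced by explicit *regime gates* that run
when a model is constructed (they simulate each field briefly and raise if
the required behavior is absent):

* **input-driven** (spatial input field, motor preparation field): peaks
  require input and decay after its removal;
* **memory** (association field): sufficiently strong self-excitation makes
  a peak self-sustained after input offset;
* **selection** (association and motor fields): global inhibition lets only
  one peak survive.

## Architecture

* **Spatial input field** — 1-D over reach/cue direction (circular, 360
  degrees, 72 samples at 5 degrees).  Its output is deliberately graded
  (`beta = 1.5`) with near-marginal self-excitation, so a cue leaves a
  smoothly decaying sensory trace (roughly 40-60 time units) after offset.
  This trace is load-bearing: it lets a late target cue override an ongoing
  plan during the selection epoch, and it reproduces the transient
  direct-plan activation seen early in memory periods.
* **Context nodes** — one self-excitatory, mutually inhibitory node per
  mapping rule; a briefly cued node latches for the rest of the trial.
* **Association field** — 2-D (direction x abstract context dimension,
  bounded, 10 units at 10 samples).  Strong self-excitation plus global
  inhibition: exactly one self-sustained peak, which stores the spatial cue
  through the memory period.  Its output is graded (`beta = 2`) so the peak
  remains *movable*: a later context input can pull it toward a
  context-preferring region.  On the bounded context dimension, truncated
  lateral support at the borders is only partially compensated
  (renormalization exponent 0.5): a mild border penalty remains, so
  spontaneous peaks form away from the borders while context-steered drive
  can still place peaks there.
* **Motor preparation field** — 1-D, soft competition (weak local
  excitation, moderate global inhibition, graded output).  Sums the direct
  pathway (spatial input, gain 3.5), the learned associative pathway, and
  reciprocal motor feedback.  Gains are arranged so a *visible* stimulus
  always dominates preparation, while in the absence of stimuli the learned
  associative drive does.
* **Motor field** — 1-D, strong self-excitation and global inhibition
  (winner-take-all), held far below threshold until the go signal adds a
  uniform disinhibition.  Once a peak forms it is self-stabilized, and its
  feedback reinforces the selected plan in the preparation field while
  suppressing alternatives globally.

Fixed projections are topological Gaussian blurs normalized so that a
saturated localized source peak delivers approximately its gain at the
target.  The two plastic projections are the context-to-association weights
`W_ca` (initialized as small uniform noise) and the association-to-
preparation weights `W_ap` (initialized as a wrapped-Gaussian topological
map, i.e. zero index shift; this implements the default direct mapping for
memory-guided reaches).

## Learning

A response is read out by circularly smoothing the motor output (Gaussian,
6 degrees) and taking the circular centroid of the above-threshold region
containing the tallest peak (threshold 0.5; exact ties are broken by the
seeded session RNG and logged).  Reward is `+1` if the reach lies within a
closed +/-8-degree window of the rewarded goal and `-1` otherwise.

Once per trial, from output snapshots averaged over the final two thirds of
the selection window (after the winner-take-all transient has settled):

* **instar** (context -> association): on reward, active association sites
  move their incoming weight vector toward the context-node output pattern;
  on failure, co-active weights decay, normalized per trial so the summed
  change matches the drive of a rewarded trial at the failure rate.
  There is no presynaptic normalization, so many regions can come to prefer
  the same context (divergent projection).
* **outstar** (association -> preparation): on reward, active sites move
  their outgoing weight vector toward the preparation output (the executed
  reach); on failure, weight to the active preparation region is removed and
  redistributed over inactive targets *in proportion to their current
  weights*, preserving each source's total outgoing weight.  Proportional
  (rather than uniform) redistribution concentrates the strengthening on the
  strongest alternative response; spread uniformly over a 72-sample lattice
  the redistribution would be too dilute to make a different response more
  likely on the next trial, which is the rule's purpose.

Learning rates are `eps+ = 0.1` (reward) and `eps- = 0.06` (failure);
weights are clipped to `[0, 1.5]`.  Aborted trials (no above-threshold
motor output by trial end) trigger no learning and are excluded from
performance denominators but logged.

## Task protocols

Trials follow the standard epoch structure: cue presentation 100 time
units, unstimulated memory period 300, late instruction / target window
220, selection (post-go) 120.  The instruction window is deliberately long
relative to the cue epoch: relocating a self-sustained association peak
onto an instructed context region is an attractor drift with a timescale of
roughly 20 tau, and with shorter windows the late context instruction
cannot act before the go signal (instruction-following drops from ~99% to
~75% at 80 time units).

* **IR training** (default 1000 trials): spatial + context cue at onset;
  target cue at the rewarded goal at the end of the memory period with
  salience fading linearly from 1 to 0 across the session; go at target
  offset.  Default mixture: 80% inferred (cue+180) / 20% direct, cues on
  the four cardinal directions.
* **DMG**: both cues at onset, learning off — the probe of the learned
  mapping.
* **PMG-CI / PMG-NC**: spatial cue first; the context cue arrives at the end
  of the memory period (CI) or never (NC, free choice).  NC trials are
  intermixed 40:60 with CI trials.  Reward schedules for NC: EPRS (fair
  coin between the two potential goals) or BMRS (reward probability of a
  goal is one minus its recent choice fraction over a sliding 20-trial
  window, so only balanced behavior earns the maximal 50%).
* **Generalization**: after cardinal-direction training, probes at the four
  oblique directions, learning off.

With more than two contexts, the context dimension is scaled in proportion
to the number of contexts (`with_contexts`), keeping per-context territory
constant — the analogue of recruiting more neurons for a harder
association task.

## What the simulations show (and what they do not)

At the default desk-scale resolution the model: learns the two-context
mapping to ~100% DMG performance across seeds with zero aborted probe
trials; develops the characteristic weight structure (context-preferring
patches at trained directions only; association-to-preparation index shift
of ~180 degrees exactly in inferred-preferring regions); follows a late
context instruction in ~99% of PMG-CI trials; produces the two
characteristic generalization errors (adjacent-direction at 45 degrees and
context errors at 180 degrees) with near-zero correct reaches on oblique
inferred probes while oblique direct probes stay near ceiling; and adapts
its free-choice fractions under the bias-minimizing schedule.

Known limitations, all traceable to the reduced field sizes chosen for
desk-scale simulation:

* The *inherent free-choice bias* after 80%-inferred training is weak
  (~45-60% inferred rather than ~93%).  The learned context territories
  split the 10-unit context dimension roughly into one direct and one
  inferred patch per trained column, and spontaneous (no-context) peaks
  land on either with similar probability.  The strong bias requires
  inferred regions that dominate the center of a larger field with direct
  regions confined to small border patches; every reduced-size geometry
  that produced a strong bias broke context steering, instruction
  following, or seed robustness instead.
* Multi-context capacity is below the two-context level by more than the
  reference amount (three or four rules reach roughly 65-80% rather than
  ~90%): with proportionally more patches, peak placement and patch
  separation interfere more strongly at this resolution.
* The generalization error mix leans toward context errors over
  adjacent-direction errors (the reverse of the reference ratio), because
  the association peak's spatial footprint (sigma 10 degrees) is small
  relative to the 45-degree gap to the nearest trained column, making the
  context-driven jump to an adjacent trained region the rarer outcome.

The synthetic protocols emulate the trial statistics of the behavioral
experiments (mixture ratios, fade schedule, schedules, epoch structure) but
not motivational or motor-execution variability; passing tests demonstrate
properties of the model dynamics, not claims about biological tissue.

## Numerical choices

Explicit Euler (`dt = 1`, `tau >= 10 dt`); two-branch/clipped logistic for
numerical stability; circular quantities handled by wrapped distances; the
compiled (numba) trial loop is an exact specialization of the reference
dynamics (the test suite asserts noise-free agreement to 1e-9) with noise
pregenerated per trial from the session's noise stream.  Desk-scale problem
sizes used throughout: 72 direction samples, 10 context samples, 1000
training trials, 200-400 probe trials per condition.
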