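# Methods

## The replay model

A narrative round is a *history*: an initial `WorldState` (every entity's
finite-symbol variables) plus an ordered sequence of timestamped
`ActionInstance`s.  The state trajectory is derived, never stored: the
state at time *t* is the left fold of the effects of all non-omitted
actions with start ≤ *t* over the initial state.  This makes determinism
and auditability structural: two refolds of the same history agree
exactly, and a serialized history round-trips bit-exactly.

Causality is tracked by partitioning entities into three classes:

* the **participant**, whose actions always execute and are never
  precondition-checked (anything they could physically do at the controls
  is by construction possible);
* **physical objects** (elevator, alarm), re-simulated deterministically
  every round by a per-tick state machine;
* **agents** (scripted characters and clones), whose recorded actions are
  replayed at their recorded virtual start times subject to precondition
  checks, with rule-based substitution (retargeting) or omission on
  failure.

The asymmetry between physical objects and agents is deliberate: replaying
a physical trajectory verbatim would desynchronize from even a slightly
divergent world, whereas human-like behaviour is treated as idiosyncratic
and is preserved *as actions*, not as outcomes.  The canonical
illustration is the alarm toggle: if the participant switches the alarm on
during the replay, the clone's recorded press later switches it off.

A backward travel builds a `ReplayContext`: the participant's recorded
actions are re-attributed to a fresh agent clone (P1 for round 1's
participant, P2 for round 2's, ...), and all non-omitted agent actions at
or after the destination time form the due-action queue.  Physical
transitions are never queued.  After a travel the previous history is the
sole frame of reference; earlier rounds are unreachable through the
engine API.

## Time, ticks, and tie-breaking

Virtual time lives on a fixed grid, tick = 0.1 s (configurable).
Internally times are integer tick counts; seconds appear only at I/O
boundaries, so scheduled-vs-current-time comparisons never suffer float
drift.  Within one tick, phases run in a fixed order: participant
injections, then due agent actions (in recorded order), then physical
transitions.  This order is what lets an alarm press injected "immediately
after" a clone's up-command take effect before the elevator starts moving.

Trial termination is decided at the *start* of a tick against the world as
the previous tick left it.  This matters in one corner: a gunman trapped
for exactly the full termination window must end the trial even if a
replayed alarm press at that same tick would have released him.

## The gallery instance

Entities: participant `P` at a ground-floor workbench; visitors `V1`–`V6`;
gunman `G`; elevator; alarm.  Person state is location
(`outside | ground | upper | elevator`) and a boolean `alive`; the fourth
location value `elevator` exists because the exit-correction rule needs to
know who is aboard.  Elevator state is position
(`ground | upper | between`), motion, a `frozen` flag coupled to the
alarm, and a pending command.  All values are finite symbols; no numeric
state exists anywhere, which keeps precondition evaluation exact.

**Effective floor.**  A person standing in an elevator that is stationary
at a floor is co-located with that floor — the gunman shoots from the
elevator platform, and a gunman in a car frozen at ground level can reach
(and be reached from) the ground floor.  Precondition templates opt into
this with a dedicated predicate mode (`at_floor`); plain predicates use
exact equality.  A person in a moving or between-floors car is on no
floor.

**Physics.**  A button press stores a pending command; motion starts
`start_delay` (0.5 s) after the press, a floor-to-floor ride takes
`travel_duration` (5 s), and arrival, starts, freezes and unfreezes are
emitted as ordinary physical actions so the derived state trajectory
remains a pure fold.  Switching the alarm on freezes the car instantly
wherever it is and cancels any pending command; switching it off never
resumes a cancelled ride (a fresh command is required), and commands
issued while frozen are ignored.  A car restarted from between floors
travels `travel_duration/2` — only half the shaft remains; nothing in the
packaged scenario depends on this value.

**Replacement rules.**  (1) *Shooting retarget*: a failed shot is re-aimed
at the first living person co-located with the gunman — visitors in
ascending id order, then the participant; clones are excluded by default
(`clone_targetable: false`).  Each attempt is substituted independently,
so five recorded shots against an audience of two become two retargeted
shots and three omissions.  (2) *Exit correction*: a rider whose recorded
exit floor is unreachable exits wherever the car actually stands, if it
stands at a floor; between floors the exit is omitted.

**The participant can be shot.**  The event is recorded and the abstract
`alive` flag cleared (so the gunman does not shoot them twice), but their
controls stay live and injections continue to be accepted — an immersive
participant does not die, and sessions continue after the event.  Outcome
counting reports visitor deaths and the participant-shot flag separately.

**Termination.**  A round ends 7 s after the last executed shot once the
gunman can shoot nobody (car stationary, no living candidate target within
reach), or after the gunman has spent 7 s continuously *trapped*.  Trapped
means frozen in the car between floors: a car frozen at a floor does not
trap anyone — the platform is level with the floor and the exit-correction
rule would let the gunman step off.  A configurable `max_time` (60 s)
bounds rounds in which neither rule can fire (e.g. a fully idle operator).
Outcome classification likewise calls the gunman trapped whenever he ends
the round in the car between floors, frozen or not, since an unfrozen car
standing mid-shaft still isolates him.

**Round 1 is precondition-checked too.**  The script plays through the
same machinery as a replay, but failures are silently skipped rather than
replaced — replacement is defined relative to a recorded history, which a
first round does not have.  This makes divergent first rounds (an idle or
contrary operator) well-defined: visitors refused transport simply wait,
and scripted shots against absent targets do not occur.

## The packaged script and its timings

The configuration (see `retroplay.gallery.default_config`) fixes the
narrative the engine ships with: three visitors arrive and ride up
together, two more follow on a second ride, one visitor stays downstairs
(and asks the participant for the time — utterances are empty-effect agent
actions, replayed at their recorded moments with no causal consequences);
the gunman enters at 31 s, rides up at 32.5 s, and fires five shots at
0.5 s intervals starting 0.5 s after arrival.  The compliant button
schedule lives in the same config.  None of these instants is privileged —
the engine only sees the script — but they make the reference narrative
deterministic, and the acceptance script and test fixtures assert against
them.  With them, a single alarm press partitions into exactly three
outcome classes: press before the ride starts (≤ 33.0 s) → the car
freezes at ground and the gunman shoots the downstairs visitor and the
participant (1, shot-participant); press during the ride (33.1–38.0 s) →
trapped, nobody shot; press after arrival → the massacre replays (5).

## Policies and stochasticity

The engine itself is seedless-deterministic: identical scenario, policies
and seeds give byte-identical event logs.  Policies are engine-exercising
stand-ins for an operator, not models of human behaviour; they observe the
world once per tick plus the previous tick's executed actions, so
reactions land one tick (0.1 s) after their trigger.  The only stochastic
policy (`random_alarm`) draws a single press time uniformly from a window
at round start, from a numpy Generator supplied per round; with the
packaged timings and the window 31–40 s, the expected number of visitors
shot is the interval-weighted mixture (2/9)·1 + (5/9)·0 + (2/9)·5 = 4/3,
which the batch-summary test checks to within three standard errors.

## What the synthetic narrative does and does not show

The packaged script, policies, and fixtures exercise the *mechanics* of
counterfactual replay — precondition soundness, retargeting, omission,
clone re-attribution, physical re-simulation, termination.  They say
nothing about human behaviour: the numbers of actions or victims produced
by the built-in policies are properties of those policies, not predictions
about participants, and no behavioural statistics are modelled or
reproduced.  The VR presentation layer (geometry, animation, audio,
embodiment) is likewise out of scope; utterances stand in for speech
only as timed causal no-ops.

## Numerical and design choices

* Tick 0.1 s; all script and injection times are quantized to it.
* Tie-break within a tick: injected → replayed → physical.
* Clone ids are `P<k>` for source round *k*; clones start each replay
  wherever the participant stood at the destination time (their initial
  state for destination 0).
* Destinations after time 0 are supported: pre-destination actions are
  immutable history, folded into the replay's initial state rather than
  copied into the new round; elevator runtime (a ride in progress) is
  reconstructed from the last start event before the destination.
* Replacement-rule search visits rules in declaration order and candidate
  targets in ascending entity-id order, for reproducibility.
* Property-suite sizes (hypothesis at 60 derandomized examples per
  invariant, the exhaustive 0.1 s press grid of 81 full two-round
  simulations, an 80-session stochastic batch) keep the default test run
  under ten seconds on one core while covering every press-time interval
  boundary exhaustively.

## Known limitations

* Values are finite symbols; no numeric or probabilistic state.
* One elevator, two floors, one alarm: the physics simulator is specific
  to the gallery instance (the engine core is scenario-agnostic).
* A gunman left upstairs with no living targets has no recorded "descend
  and continue" behaviour to replay, so replays simply omit his shots and
  the termination rule ends the round.
* Refused visitors wait where they are indefinitely; the second
  zero-casualty solution (send the gunman up alone) therefore works, but
  no packaged fixture depends on how long visitors would realistically
  wait.
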