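# retroplay

A causality-tracking reasoning engine for *counterfactual replay* of
interactive narratives — the "logic layer" of a backwards-time-travel
simulation.  The engine records a round of a narrative as a **history**
(an initial world state plus an ordered sequence of timestamped actions),
lets the participant travel back to an earlier virtual time, and then
replays the past while the participant intervenes freely.  The packaged
reference instance is a two-level art-gallery moral dilemma: an elevator
operator must choose between letting a gunman shoot five visitors
upstairs, sending him down to where one visitor stands, or finding the
timing that saves everyone.

## The model

Every entity belongs to one of three **causal classes**:

* **participant** — the live human.  Their actions always execute (free
  will): `inject` never checks preconditions, and injected actions are
  recorded so that further travels replay them.
* **physical** — deterministic objects (the elevator, the alarm).  They are
  never replayed; each round re-simulates them from scratch, so the
  physical world stays coherent however far the narrative diverges.
* **agent** — scripted characters and past clones of the participant.
  Their recorded actions replay verbatim at the recorded virtual times.

Actions are declarative schemas with **preconditions** (state predicates
that must hold for the action to occur) and **effects** (state
assignments).  During a replay, whenever the virtual clock reaches the
recorded start time of a due agent action the engine checks its
preconditions:

* hold → the action executes exactly as recorded (`replayed`);
* fail → a scenario **replacement rule** may substitute a similar action
  (`retargeted`) — e.g. a shooting is re-aimed at whoever is now within
  the gunman's reach, and an elevator exit is corrected to whatever floor
  the car actually stands at;
* no rule applies → the action is dropped (`omitted`).

After each travel the previous history is discarded as a frame of
reference: the next replay derives solely from the latest round.  Each
travel re-attributes the participant's recorded actions to a fresh clone
(P1, P2, ...), so repeated travels accumulate co-existing past selves.
A *Repetition* mode runs the identical script each round with no clones
and no replay machinery, as a control.

## Worked example

```python
from retroplay import ReplayEngine, build_gallery, count_shot
from retroplay.policies import ComplyThenAlarm, FreezeAtGround

engine = ReplayEngine(build_gallery())

# Round 1: a compliant operator ferries the visitors, then the gunman.
h1 = engine.record_round(ComplyThenAlarm())
print(count_shot(h1))            # (5, False) — five visitors shot

# Travel back and intervene: press the alarm right after the previous
# clone's up-command, freezing the elevator at the ground floor.
ctx = engine.travel_back(h1)     # participant's actions now belong to P1
h2 = engine.replay_round(ctx, FreezeAtGround())
print(count_shot(h2))            # (1, True) — V6 shot, participant shot
```

The round-2 transcript (`retroplay.session.render_transcript`) shows the
causal bookkeeping around the gunman's entry:

```
   31.0   G enters gallery
   31.5   G speaks (asks to be taken to the upper level)
   31.5   Elevator arrives ground floor
   32.0   G enters elevator
   32.5   P1 pushes elevator up
   32.6 * P pushes alarm
   32.6   alarm on
   38.5   [retargeted] G shoots V6 (was V1)
   39.0   [retargeted] G shoots P (was V2)
   39.5   [omitted] G shoots V3
   40.0   [omitted] G shoots V4
   40.5   [omitted] G shoots V5
   42.0   P1 pushes alarm
   42.0   alarm off
   46.0   -- round ends --
```

The elevator never starts its ride (physical objects are re-simulated, not
replayed), the gunman's five shooting attempts are retargeted to the two
people within reach at ground level and otherwise omitted, and the clone's
recorded alarm press — an action, not an outcome — now switches the alarm
*off*, because the participant had already switched it on.

A command-line entry point wraps the same machinery:

```bash
retroplay --mode time_travel --rounds 3 \
    --policy r1=comply_then_alarm --policy r2=trap_gunman --policy r3=do_nothing \
    --seed 1 --out out/
retroplay --selftest   # replays the worked example and diffs it
```

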