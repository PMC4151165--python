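"""The two-level gallery scenario.

An art gallery on two levels.  The participant stands at a workbench with
three controls: elevator up, elevator down, and a red alarm button that is a
toggle — switching the alarm on freezes the elevator wherever it is, and
switching it off releases it.  Six visitors arrive; with a compliant
operator five end up browsing upstairs and one stays on the ground floor.
A seventh person asks to be taken up and, on arrival — still on the elevator
platform — starts shooting the five people there.  The participant can do
nothing, send the elevator (and the gunman) back down, or freeze the
elevator.  Two interventions prevent any shooting: trapping the gunman
between floors with the alarm, or never sending the visitors up in the
first place.  Keeping the gunman on the ground floor always costs at least
one life — the visitor who stays downstairs.

This module provides the scenario as data (entities, action schemas, the
first-round script, the two scenario-specific replacement rules), the
deterministic elevator/alarm simulator, the trial-termination rules, outcome
counting, and a brute-force enumerator over alarm-press times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable, Mapping, Sequence

import yaml

from .engine import (
    EngineConfig,
    ReplacementRule,
    ReplayContext,
    ReplayEngine,
    Scenario,
    ScenarioError,
)
from .timeline import (
    ActionInstance,
    ActionSchema,
    CausalClass,
    Effect,
    Entity,
    History,
    Predicate,
    VirtualTime,
    WorldState,
    effective_floor,
)

PARTICIPANT = "P"
GUNMAN = "G"
VISITORS = ("V1", "V2", "V3", "V4", "V5", "V6")
ELEVATOR = "elevator"
ALARM = "alarm"

FLOORS = ("ground", "upper")


# ---------------------------------------------------------------------------
# configuration

def default_config() -> dict:
    """The packaged scenario configuration, including the round-1 script.

    Timing constants (tick 0.1 s, elevator travel 5 s, 0.5 s between shots,
    0.5 s from arrival to first shot, 7 s termination window) are fixed
    defaults chosen to make the worked narrative deterministic; all are
    overridable here.
    """
    timing = {
        "travel_duration": 5.0,   # s, full floor-to-floor elevator ride
        "start_delay": 0.5,       # s, button press to start of motion
        "inter_shot_interval": 0.5,
        "arrival_to_shooting": 0.5,
        "termination_window": 7.0,
    }
    cfg = {
        "name": "gallery",
        "engine": {"tick": 0.1, "max_time": 60.0, "clone_targetable": False},
        "timing": timing,
        "entities": {
            "participant": PARTICIPANT,
            "gunman": GUNMAN,
            "visitors": list(VISITORS),
        },
        "script": _default_script(timing),
        # What a fully compliant operator does, as (time, button) pairs.
        # Used by the built-in compliant policies.
        "compliant_pushes": [
            [4.5, "up"],
            [12.0, "down"],
            [19.0, "up"],
            [26.0, "down"],
            [32.5, "up"],
        ],
    }
    return cfg


def _default_script(timing: Mapping[str, float]) -> list[dict]:
    """Round-1 scripted agent actions: arrivals, boarding, the shooting."""

    def ev(t: float, actor: str, action: str, **kw) -> dict:
        d: dict[str, Any] = {"t": t, "actor": actor, "action": action}
        d.update(kw)
        return d

    script = [
        ev(1.0, "V1", "enter_gallery"),
        ev(1.5, "V2", "enter_gallery"),
        ev(2.0, "V3", "enter_gallery"),
        ev(2.5, "V1", "utterance", content="asks to go up"),
        ev(3.0, "V1", "enter_elevator", floor="ground"),
        ev(3.5, "V2", "enter_elevator", floor="ground"),
        ev(4.0, "V3", "enter_elevator", floor="ground"),
        # compliant operator sends the elevator up at 4.5; arrives 10.0
        ev(10.5, "V1", "enter_floor", floor="upper"),
        ev(11.0, "V2", "enter_floor", floor="upper"),
        ev(11.5, "V3", "enter_floor", floor="upper"),
        # down at 12.0; arrives ground 17.5
        ev(13.0, "V4", "enter_gallery"),
        ev(13.5, "V5", "enter_gallery"),
        ev(14.0, "V6", "enter_gallery"),
        ev(15.0, "V6", "utterance", content="asks the participant for the time"),
        ev(18.0, "V4", "enter_elevator", floor="ground"),
        ev(18.5, "V5", "enter_elevator", floor="ground"),
        # up at 19.0; arrives 24.5
        ev(25.0, "V4", "enter_floor", floor="upper"),
        ev(25.5, "V5", "enter_floor", floor="upper"),
        # down at 26.0; arrives ground 31.5
        ev(31.0, GUNMAN, "enter_gallery"),
        ev(31.5, GUNMAN, "utterance", content="asks to be taken to the upper level"),
        ev(32.0, GUNMAN, "enter_elevator", floor="ground"),
        # up at 32.5; starts 33.0; arrives upper 38.0
    ]
    first_shot = 38.0 + timing["arrival_to_shooting"]
    for i, v in enumerate(("V1", "V2", "V3", "V4", "V5")):
        script.append(
            ev(
                round(first_shot + i * timing["inter_shot_interval"], 6),
                GUNMAN,
                "shoot",
                target=v,
                floor="upper",
            )
        )
    return script


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_config(config: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# schemas

def _schemas() -> dict[str, ActionSchema]:
    P, E = Predicate, Effect
    schemas = [
        ActionSchema(
            "enter_gallery",
            CausalClass.AGENT,
            preconditions=(P("{actor}", "at", "outside"),),
            effects=(E("{actor}", "at", "ground"),),
        ),
        ActionSchema("utterance", CausalClass.AGENT),  # speech: no causal effects
        ActionSchema(
            "enter_elevator",
            CausalClass.AGENT,
            preconditions=(
                P("{actor}", "at", "{floor}"),
                P(ELEVATOR, "position", "{floor}"),
                P(ELEVATOR, "motion", "stationary"),
                P(ELEVATOR, "frozen", False),
            ),
            effects=(E("{actor}", "at", "elevator"),),
        ),
        ActionSchema(
            "enter_floor",
            CausalClass.AGENT,
            preconditions=(
                P("{actor}", "at", "elevator"),
                P(ELEVATOR, "position", "{floor}"),
                P(ELEVATOR, "motion", "stationary"),
            ),
            effects=(E("{actor}", "at", "{floor}"),),
            replaceable="enter_floor_correction",
        ),
        ActionSchema(
            "shoot",
            CausalClass.AGENT,
            preconditions=(
                P("{actor}", "at", "{floor}", mode="at_floor"),
                P("{target}", "at", "{floor}", mode="at_floor"),
                P("{target}", "alive", True),
            ),
            effects=(E("{target}", "alive", False),),
            has_target=True,
            replaceable="shooting_retarget",
        ),
        # workbench controls — participant class, always executable
        ActionSchema(
            "push_up", CausalClass.PARTICIPANT, effects=(E(ELEVATOR, "command", "up"),)
        ),
        ActionSchema(
            "push_down", CausalClass.PARTICIPANT, effects=(E(ELEVATOR, "command", "down"),)
        ),
        ActionSchema(
            "press_alarm",
            CausalClass.PARTICIPANT,
            effects=(E(ALARM, "on", op="toggle"),),
        ),
        # physical transitions, emitted only by the simulator
        ActionSchema(
            "elevator_start_up",
            CausalClass.PHYSICAL,
            preconditions=(
                P(ELEVATOR, "position", "{from}"),
                P(ELEVATOR, "motion", "stationary"),
                P(ELEVATOR, "frozen", False),
                P(ELEVATOR, "command", "up"),
            ),
            effects=(
                E(ELEVATOR, "motion", "moving_up"),
                E(ELEVATOR, "position", "between"),
                E(ELEVATOR, "command", "none"),
            ),
        ),
        ActionSchema(
            "elevator_start_down",
            CausalClass.PHYSICAL,
            preconditions=(
                P(ELEVATOR, "position", "{from}"),
                P(ELEVATOR, "motion", "stationary"),
                P(ELEVATOR, "frozen", False),
                P(ELEVATOR, "command", "down"),
            ),
            effects=(
                E(ELEVATOR, "motion", "moving_down"),
                E(ELEVATOR, "position", "between"),
                E(ELEVATOR, "command", "none"),
            ),
        ),
        ActionSchema(
            "elevator_arrive_upper",
            CausalClass.PHYSICAL,
            preconditions=(
                P(ELEVATOR, "motion", "moving_up"),
                P(ELEVATOR, "position", "between"),
            ),
            effects=(E(ELEVATOR, "motion", "stationary"), E(ELEVATOR, "position", "upper")),
        ),
        ActionSchema(
            "elevator_arrive_ground",
            CausalClass.PHYSICAL,
            preconditions=(
                P(ELEVATOR, "motion", "moving_down"),
                P(ELEVATOR, "position", "between"),
            ),
            effects=(E(ELEVATOR, "motion", "stationary"), E(ELEVATOR, "position", "ground")),
        ),
        # the audible alarm state change; freezing/unfreezing the elevator
        # is its physical consequence, and either transition cancels any
        # pending elevator command
        ActionSchema(
            "alarm_on",
            CausalClass.PHYSICAL,
            preconditions=(P(ALARM, "on", True), P(ELEVATOR, "frozen", False)),
            effects=(
                E(ELEVATOR, "frozen", True),
                E(ELEVATOR, "motion", "stationary"),
                E(ELEVATOR, "command", "none"),
            ),
        ),
        ActionSchema(
            "alarm_off",
            CausalClass.PHYSICAL,
            preconditions=(P(ALARM, "on", False), P(ELEVATOR, "frozen", True)),
            effects=(E(ELEVATOR, "frozen", False), E(ELEVATOR, "command", "none")),
        ),
    ]
    return {s.name: s for s in schemas}


# ---------------------------------------------------------------------------
# physics

class ElevatorAlarmPhysics:
    """Deterministic tick simulator for the elevator and alarm.

    Rules: an alarm state change freezes/unfreezes the elevator immediately
    (freezing mid-ride leaves it between floors) and cancels any pending
    command; a pending up/down command on an unfrozen, stationary elevator
    starts motion ``start_delay`` after the button press; arrival follows
    ``travel_duration`` later (half that when resuming from between floors,
    where only half the shaft remains).  Commands issued while frozen are
    ignored.  Unfreezing never resumes the interrupted ride — a fresh
    command is required.
    """

    def __init__(self, scenario: Scenario) -> None:
        timing = scenario.metadata["timing"]
        tick = scenario.config.tick
        self.start_delay = round(timing["start_delay"] / tick)
        self.travel = round(timing["travel_duration"] / tick)
        self._pending: tuple[str, int] | None = None  # (command, tick first seen)
        self._motion: tuple[int, int] | None = None  # (start tick, duration ticks)

    def prime(self, history: History, destination: VirtualTime, schemas) -> None:
        """Rebuild runtime for a travel destination mid-round by scanning the
        physical events recorded strictly before the destination."""
        self._pending = None
        self._motion = None
        for a in history.actions:
            if a.start.ticks >= destination.ticks or a.status == "omitted":
                continue
            if a.schema in ("elevator_start_up", "elevator_start_down"):
                dur = self.travel if a.params.get("from") != "between" else self.travel // 2
                self._motion = (a.start.ticks, dur)
            elif a.schema in ("elevator_arrive_upper", "elevator_arrive_ground", "alarm_on"):
                self._motion = None
            elif a.schema in ("push_up", "push_down"):
                self._pending = ({"push_up": "up", "push_down": "down"}[a.schema], a.start.ticks)
            elif a.schema == "alarm_off":
                self._pending = None

    def step(self, world: WorldState, t: VirtualTime) -> list[ActionInstance]:
        on = world.get(ALARM, "on")
        frozen = world.get(ELEVATOR, "frozen")
        if on and not frozen:
            self._pending = None
            self._motion = None
            return [ActionInstance(schema="alarm_on", actor=ALARM)]
        if not on and frozen:
            self._pending = None
            return [ActionInstance(schema="alarm_off", actor=ALARM)]

        command = world.get(ELEVATOR, "command")
        motion = world.get(ELEVATOR, "motion")
        position = world.get(ELEVATOR, "position")
        if frozen:
            self._pending = None
            return []
        if motion in ("moving_up", "moving_down"):
            assert self._motion is not None
            start, dur = self._motion
            if t.ticks >= start + dur:
                self._motion = None
                name = "elevator_arrive_upper" if motion == "moving_up" else "elevator_arrive_ground"
                return [ActionInstance(schema=name, actor=ELEVATOR)]
            return []
        if command in ("up", "down"):
            target = "upper" if command == "up" else "ground"
            if position == target:
                return []  # already there; command sits inert
            if self._pending is None or self._pending[0] != command:
                self._pending = (command, t.ticks)
            since = self._pending[1]
            if t.ticks >= since + self.start_delay:
                dur = self.travel if position != "between" else self.travel // 2
                self._motion = (t.ticks, dur)
                self._pending = None
                name = "elevator_start_up" if command == "up" else "elevator_start_down"
                return [
                    ActionInstance(schema=name, actor=ELEVATOR, params={"from": position})
                ]
            return []
        self._pending = None
        return []


# ---------------------------------------------------------------------------
# termination

class GalleryTermination:
    """Trial-termination rules.

    A round ends 7 s after the last shooting once the gunman cannot shoot
    again (elevator not moving, nobody alive within his reach), or once he
    has been trapped — frozen inside the elevator between floors — for 7 s
    continuously.  The decision is made at the start of a tick against the
    world as the previous tick left it, so a same-tick action cannot undo a
    termination that is already due.
    """

    def __init__(self, scenario: Scenario) -> None:
        tick = scenario.config.tick
        self.window = round(scenario.metadata["timing"]["termination_window"] / tick)
        self.scenario = scenario
        self._seen = 0
        self._last_shot: int | None = None
        self._trapped_since: int | None = None
        self._world: WorldState | None = None

    def observe(self, world: WorldState, history: History, t: VirtualTime) -> None:
        for a in history.actions[self._seen:]:
            if a.schema == "shoot" and a.status != "omitted":
                self._last_shot = a.start.ticks
        self._seen = len(history.actions)
        trapped = (
            world.get(GUNMAN, "at") == "elevator"
            and world.get(ELEVATOR, "frozen")
            and world.get(ELEVATOR, "position") == "between"
        )
        if trapped:
            if self._trapped_since is None:
                self._trapped_since = t.ticks
        else:
            self._trapped_since = None
        self._world = world

    def should_terminate(self, t: VirtualTime) -> bool:
        world = self._world
        if world is None:
            return False
        if (
            self._trapped_since is not None
            and t.ticks - self._trapped_since >= self.window
        ):
            return True
        if self._last_shot is not None and t.ticks - self._last_shot >= self.window:
            if world.get(ELEVATOR, "motion") == "stationary" and not _targets_in_reach(
                world, self.scenario, None
            ):
                return True
        return False


def _candidate_targets(
    world: WorldState, scenario: Scenario, ctx: ReplayContext | None
) -> list[str]:
    """Living persons co-located with the gunman, in retargeting order:
    visitors by ascending id, then the participant, then (only if configured
    targetable) the clones."""
    g = effective_floor(world, GUNMAN)
    if g is None:
        return []
    order = list(VISITORS) + [PARTICIPANT]
    if scenario.config.clone_targetable and ctx is not None:
        order += ctx.clone_map.clone_ids()
    out = []
    for pid in order:
        if pid not in world.data:
            continue
        if world.get(pid, "alive") and effective_floor(world, pid) == g:
            out.append(pid)
    return out


def _targets_in_reach(world, scenario, ctx) -> bool:
    return bool(_candidate_targets(world, scenario, ctx))


# ---------------------------------------------------------------------------
# replacement rules

def make_shooting_retarget(scenario_getter) -> ReplacementRule:
    """Retarget a failed shooting to whoever is within the gunman's reach.

    Replays attempt the same number of shots at the same virtual times; each
    failed attempt is matched to the first living person co-located with the
    gunman (visitors in ascending id order, then the participant).  With the
    gunman in motion or between floors there is no one in reach and the
    attempt is omitted.
    """

    def substitute(
        action: ActionInstance, world: WorldState, ctx: ReplayContext | None
    ) -> ActionInstance | None:
        scenario = scenario_getter()
        g = effective_floor(world, action.actor)
        if g is None:
            return None
        for cand in _candidate_targets(world, scenario, ctx):
            return ActionInstance(
                schema="shoot",
                actor=action.actor,
                targets=(cand,),
                params={"floor": g},
                start=action.start,
                status="retargeted",
                original_targets=action.targets,
                original_params=dict(action.params),
            )
        return None

    return ReplacementRule("shooting_retarget", "shoot", substitute)


def make_enter_floor_correction() -> ReplacementRule:
    """Let a rider exit wherever the elevator actually stands.

    If the recorded exit floor is unreachable but the person is in the
    elevator and it is stationary at *some* floor, they exit there instead —
    regardless of whether it is the recorded floor.  Between floors, or if
    the person is not aboard, the exit is omitted.
    """

    def substitute(
        action: ActionInstance, world: WorldState, ctx: ReplayContext | None
    ) -> ActionInstance | None:
        if world.get(action.actor, "at") != "elevator":
            return None
        if world.get(ELEVATOR, "motion") != "stationary":
            return None
        position = world.get(ELEVATOR, "position")
        if position == "between":
            return None
        return ActionInstance(
            schema="enter_floor",
            actor=action.actor,
            params={"floor": position},
            start=action.start,
            status="retargeted",
            original_params=dict(action.params),
        )

    return ReplacementRule("enter_floor_correction", "enter_floor", substitute)


# ---------------------------------------------------------------------------
# scenario assembly

def build_gallery(config: Mapping | None = None) -> Scenario:
    """Assemble and validate the gallery scenario from a configuration.

    Raises :class:`ScenarioError` listing every offending script entry if the
    script references undeclared entities, schemas, or missing parameters.
    """
    cfg = default_config() if config is None else dict(config)
    eng = cfg.get("engine", {})
    engine_cfg = EngineConfig(
        tick=eng.get("tick", 0.1),
        max_time=eng.get("max_time", 60.0),
        clone_targetable=eng.get("clone_targetable", False),
    )
    ents_cfg = cfg.get("entities", {})
    participant = ents_cfg.get("participant", PARTICIPANT)
    gunman = ents_cfg.get("gunman", GUNMAN)
    visitors = list(ents_cfg.get("visitors", VISITORS))

    person = lambda at: {"at": at, "alive": True}
    entities = [
        Entity(participant, CausalClass.PARTICIPANT, person("ground")),
        *[Entity(v, CausalClass.AGENT, person("outside")) for v in visitors],
        Entity(gunman, CausalClass.AGENT, person("outside")),
        Entity(
            ELEVATOR,
            CausalClass.PHYSICAL,
            {"position": "ground", "motion": "stationary", "frozen": False, "command": "none"},
        ),
        Entity(ALARM, CausalClass.PHYSICAL, {"on": False}),
    ]
    schemas = _schemas()

    declared = {e.id for e in entities}
    tick = engine_cfg.tick
    script: list[ActionInstance] = []
    problems: list[str] = []
    for i, entry in enumerate(cfg.get("script", [])):
        entry = dict(entry)
        t = entry.pop("t", None)
        actor = entry.pop("actor", None)
        name = entry.pop("action", None)
        target = entry.pop("target", None)
        if name not in schemas:
            problems.append(f"script[{i}]: unknown action {name!r}")
            continue
        if actor not in declared:
            problems.append(f"script[{i}]: undeclared actor {actor!r}")
            continue
        if target is not None and target not in declared:
            problems.append(f"script[{i}]: undeclared target {target!r}")
            continue
        if schemas[name].has_target and target is None:
            problems.append(f"script[{i}]: action {name!r} requires a target")
            continue
        if t is None or t < 0:
            problems.append(f"script[{i}]: bad time {t!r}")
            continue
        script.append(
            ActionInstance(
                schema=name,
                actor=actor,
                targets=(target,) if target is not None else (),
                params=entry,
                start=VirtualTime.of(t, tick),
                status="scripted",
            )
        )
    if problems:
        raise ScenarioError("invalid scenario config: " + "; ".join(problems))

    holder: list[Scenario] = []
    rules = [make_shooting_retarget(lambda: holder[0]), make_enter_floor_correction()]
    scenario = Scenario(
        name=cfg.get("name", "gallery"),
        entities=entities,
        schemas=schemas,
        script=script,
        participant_id=participant,
        rules=rules,
        make_physics=ElevatorAlarmPhysics,
        make_termination=GalleryTermination,
        config=engine_cfg,
        metadata={
            "timing": dict(cfg["timing"]),
            "compliant_pushes": [tuple(p) for p in cfg.get("compliant_pushes", [])],
            "gunman": gunman,
            "visitors": visitors,
            "config": cfg,
        },
    )
    holder.append(scenario)
    return scenario


# ---------------------------------------------------------------------------
# state views

@dataclass(frozen=True)
class ElevatorState:
    position: str
    motion: str
    frozen: bool
    occupants: frozenset[str]

    @staticmethod
    def from_world(world: WorldState) -> "ElevatorState":
        occupants = frozenset(
            e for e in world.entities()
            if "at" in world.data[e] and world.get(e, "at") == "elevator"
        )
        return ElevatorState(
            position=world.get(ELEVATOR, "position"),
            motion=world.get(ELEVATOR, "motion"),
            frozen=world.get(ELEVATOR, "frozen"),
            occupants=occupants,
        )


@dataclass(frozen=True)
class AlarmState:
    on: bool

    @staticmethod
    def from_world(world: WorldState) -> "AlarmState":
        return AlarmState(on=world.get(ALARM, "on"))


@dataclass(frozen=True)
class PersonState:
    location: str
    alive: bool

    @staticmethod
    def from_world(world: WorldState, person_id: str) -> "PersonState":
        return PersonState(world.get(person_id, "at"), world.get(person_id, "alive"))


# ---------------------------------------------------------------------------
# outcomes

def count_shot(history: History, visitors: Iterable[str] = VISITORS,
               participant: str = PARTICIPANT) -> tuple[int, bool]:
    """(number of visitors actually shot, whether the participant was shot).

    Counts executed (non-omitted) shoot actions; visitor and participant
    targets are tallied separately since the participant event is an
    abstract recording — a VR participant does not die.
    """
    vset = set(visitors)
    visitors_shot = 0
    participant_shot = False
    for a in history.actions:
        if a.schema != "shoot" or a.status == "omitted":
            continue
        for tgt in a.targets:
            if tgt in vset:
                visitors_shot += 1
            elif tgt == participant:
                participant_shot = True
    return visitors_shot, participant_shot


def round_outcome(history: History, scenario: Scenario) -> dict:
    """Summary of one finalized round: counts plus whether the gunman ended
    the round trapped between floors."""
    from .timeline import state_at

    visitors = scenario.metadata.get("visitors", VISITORS)
    shot, p_shot = count_shot(history, visitors, scenario.participant_id)
    end = history.end_time or history.end
    final = state_at(history, end, scenario.schemas)
    # A gunman ending the round in the elevator between floors is trapped
    # whether or not the elevator is still frozen: there is no floor to exit
    # onto, so nobody is within his reach.
    trapped = (
        final.get(scenario.metadata.get("gunman", GUNMAN), "at") == "elevator"
        and final.get(ELEVATOR, "position") == "between"
    )
    return {
        "visitors_shot": shot,
        "participant_shot": p_shot,
        "gunman_trapped": trapped,
        "end_time": end.seconds(scenario.config.tick),
    }


def enumerate_alarm_strategies(
    scenario: Scenario | None = None,
    press_times: Sequence[float] | None = None,
    step: float = 0.5,
) -> dict[tuple[int, bool, bool], list[float]]:
    """Brute-force the counterfactual round over a grid of alarm-press times.

    Round 1 is played by a compliant operator; the replay round's only
    intervention is a single alarm press at each candidate time.  Returns
    outcome equivalence classes keyed by (visitors_shot, participant_shot,
    gunman_trapped).  On any grid refining the three press intervals —
    before the gunman's ride starts / during the ride / after arrival —
    exactly three classes appear: shoot-the-ground-floor (1 visitor and the
    participant), trap (nobody shot), and the unchanged massacre (5 shot).
    """
    from .policies import ComplyThenAlarm, ScriptedPolicy

    scenario = scenario or build_gallery()
    if press_times is None:
        board = next(
            a.start.seconds(scenario.config.tick)
            for a in scenario.script
            if a.schema == "enter_elevator" and a.actor == scenario.metadata["gunman"]
        )
        push = max(t for t, _ in scenario.metadata["compliant_pushes"])
        arrive = (
            push
            + scenario.metadata["timing"]["start_delay"]
            + scenario.metadata["timing"]["travel_duration"]
        )
        n = int(round((arrive + 2.0 - board) / step))
        press_times = [round(board + k * step, 6) for k in range(n + 1)]

    engine = ReplayEngine(scenario)
    first = engine.record_round(ComplyThenAlarm())
    classes: dict[tuple[int, bool, bool], list[float]] = {}
    for tau in press_times:
        ctx = engine.travel_back(first)
        h2 = engine.replay_round(ctx, ScriptedPolicy([(tau, "press_alarm", {})]))
        out = round_outcome(h2, scenario)
        key = (out["visitors_shot"], out["participant_shot"], out["gunman_trapped"])
        classes.setdefault(key, []).append(tau)
    return classes
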