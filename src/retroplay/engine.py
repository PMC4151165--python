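"""The time-travel replay engine.

One round is recorded as a :class:`~retroplay.timeline.History`.  "Travel
back" builds a :class:`ReplayContext` from that history: the participant's
recorded actions are re-attributed to a fresh clone (an ordinary agent), and
all non-omitted agent-class actions become a due-action queue ordered by
virtual start time.  The next round then advances tick by tick:

1. the live participant may inject new actions — these always execute;
2. whenever the virtual clock reaches the recorded start time of a due
   action, its preconditions are checked: if they hold the action replays
   exactly as recorded; if not, the scenario's replacement rules may
   substitute a similar action (retargeting), otherwise the action is
   omitted;
3. physical objects are never replayed — they are re-simulated afresh by
   deterministic rules, so the physical world stays coherent however far
   the narrative diverges.

After each travel the previous history is discarded as a frame of
reference: the queue for travel k+1 derives solely from round k's history.
Multiple travels accumulate co-existing clones (P1, P2, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Callable, Mapping, Protocol, Sequence

from .timeline import (
    ActionInstance,
    ActionSchema,
    CausalClass,
    Entity,
    History,
    SchemaError,
    VirtualTime,
    WorldState,
    append_action,
    apply_effects,
    evaluate_preconditions,
)


class ScenarioError(ValueError):
    """A scenario definition or an intervention refers to unknown pieces."""


class FreeWillError(ValueError):
    """An injection was attempted on behalf of someone other than the live participant."""


class RangeError(ValueError):
    """Travel destination outside the recorded history."""


class EngineInvariantError(RuntimeError):
    """A replacement rule produced an action whose preconditions fail."""


# ---------------------------------------------------------------------------
# scenario plumbing

class PhysicsSim(Protocol):
    """Deterministic per-tick simulator for the physical-class entities."""

    def prime(self, history: History, destination: VirtualTime,
              schemas: Mapping[str, ActionSchema]) -> None:
        """Reconstruct runtime state for a mid-history travel destination."""

    def step(self, world: WorldState, t: VirtualTime) -> list[ActionInstance]:
        """Physical transitions occurring at tick *t* (effects not yet applied)."""


class TerminationTracker(Protocol):
    def observe(self, world: WorldState, history: History, t: VirtualTime) -> None:
        """Called at the end of every tick with the world it produced."""

    def should_terminate(self, t: VirtualTime) -> bool:
        """Called at the start of tick *t*, before any action executes;
        True ends the round at *t* (nothing else happens at that tick)."""


@dataclass(frozen=True)
class ReplacementRule:
    """Substitution for a due action whose preconditions failed.

    ``substitute`` returns an alternative ActionInstance whose preconditions
    hold in the given world, or None for omission.  Rules are consulted in
    declaration order; a schema opts in via its ``replaceable`` field.
    """

    id: str
    applies_to: str  # schema name
    substitute: Callable[
        [ActionInstance, WorldState, "ReplayContext | None"], ActionInstance | None
    ]


@dataclass
class EngineConfig:
    tick: float = 0.1
    max_time: float = 60.0
    clone_targetable: bool = False


@dataclass
class Scenario:
    """Everything the engine needs: entities, schemas, the first-round script,
    replacement rules, physics and termination factories."""

    name: str
    entities: list[Entity]
    schemas: dict[str, ActionSchema]
    script: list[ActionInstance]
    participant_id: str
    rules: list[ReplacementRule]
    make_physics: Callable[["Scenario"], PhysicsSim]
    make_termination: Callable[["Scenario"], TerminationTracker]
    config: EngineConfig = field(default_factory=EngineConfig)
    clone_prefix: str = "P"
    metadata: dict = field(default_factory=dict)

    def entity(self, entity_id: str) -> Entity:
        for e in self.entities:
            if e.id == entity_id:
                return e
        raise ScenarioError(f"undeclared entity {entity_id!r}")

    def controls(self) -> list[str]:
        """Schema names the live participant may issue."""
        return [
            s.name
            for s in self.schemas.values()
            if s.actor_class is CausalClass.PARTICIPANT
        ]


@dataclass
class CloneMap:
    """source round -> clone entity id (round k's participant becomes P_k)."""

    mapping: dict[int, str] = field(default_factory=dict)

    def clone_ids(self) -> list[str]:
        return [self.mapping[k] for k in sorted(self.mapping)]


@dataclass
class ReplayContext:
    """A travel-back session: the frame of reference and the due-action queue."""

    previous: History
    destination: VirtualTime
    queue: list[ActionInstance]  # re-attributed, ordered by start time
    clone_map: CloneMap
    rules: list[ReplacementRule]
    config: EngineConfig


class Policy(Protocol):
    """Stand-in participant: observes the world and issues control actions."""

    def reset(self, scenario: Scenario, round_index: int, rng: Any) -> None: ...

    def step(
        self,
        t: VirtualTime,
        world: WorldState,
        recent: Sequence[ActionInstance],
        scenario: Scenario,
    ) -> list[tuple[str, dict]]:
        """Control actions to inject at *t*: (schema name, params) pairs.

        *recent* holds the actions executed during the previous tick, so a
        reactive policy sees an event one tick after it happens.
        """
        ...


class _NullPolicy:
    def reset(self, scenario, round_index, rng) -> None:
        pass

    def step(self, t, world, recent, scenario):
        return []


# ---------------------------------------------------------------------------
# round runner

class RoundRunner:
    """Drives one round tick by tick; shared by recording and replay.

    In round 1 (and every Repetition-condition round) the due actions are
    the scenario script: precondition failures drop the action silently.
    In a replay round the due actions come from the previous history:
    failures go through the replacement rules and are recorded as
    retargeted or omitted.
    """

    def __init__(
        self,
        scenario: Scenario,
        round_index: int,
        due: Sequence[ActionInstance],
        *,
        ctx: ReplayContext | None = None,
        policy: Policy | None = None,
        initial_state: WorldState | None = None,
        start: VirtualTime = VirtualTime(0),
        rng: Any = None,
    ) -> None:
        self.scenario = scenario
        self.round_index = round_index
        self.ctx = ctx
        self.policy = policy or _NullPolicy()
        self.rng = rng
        self.is_replay = ctx is not None
        init = initial_state if initial_state is not None else WorldState.initial(
            scenario.entities
        )
        self.world = init
        self.history = History(round_index=round_index, initial_state=init)
        self.due = sorted(due, key=lambda a: a.start.ticks)
        self._due_pos = 0
        self.t = start
        self.physics = scenario.make_physics(scenario)
        if ctx is not None and ctx.destination.ticks > 0:
            self.physics.prime(ctx.previous, ctx.destination, scenario.schemas)
        self.termination = scenario.make_termination(scenario)
        self._last_tick_events: list[ActionInstance] = []
        self._tick_events: list[ActionInstance] = []
        self.finished = False
        self.policy.reset(scenario, round_index, rng)

    # -- execution primitives ------------------------------------------------

    def _record(self, action: ActionInstance) -> ActionInstance:
        action = replace(action, start=self.t, round_index=self.round_index)
        append_action(self.history, self.t, action)
        if action.status != "omitted":
            schema = self.scenario.schemas[action.schema]
            self.world = apply_effects(action, schema, self.world)
            self._tick_events.append(action)
        return action

    def inject(self, action: ActionInstance) -> ActionInstance:
        """Execute a live-participant action unconditionally and record it.

        The participant has free will: the engine never blocks an available
        control.  Injections are recorded so further travels replay them.
        """
        if action.actor != self.scenario.participant_id:
            raise FreeWillError(
                f"only the live participant {self.scenario.participant_id!r} may inject"
                f" actions, got {action.actor!r}"
            )
        if action.schema not in self.scenario.schemas:
            raise ScenarioError(f"unknown control {action.schema!r}")
        return self._record(replace(action, status="injected"))

    def _attempt_due(self, queued: ActionInstance) -> ActionInstance | None:
        schema = self.scenario.schemas.get(queued.schema)
        if schema is None:
            raise SchemaError(f"undeclared schema {queued.schema!r}")
        ok = evaluate_preconditions(queued, schema, self.world)
        if not self.is_replay:
            # Scripted round: failures are skipped silently, no replacement.
            if not ok:
                return None
            return self._record(replace(queued, status="scripted"))
        if ok:
            return self._record(replace(queued, status="replayed"))
        substitute = attempt_replacement(
            queued, self.world, self.ctx.rules, self.scenario, self.ctx
        )
        if substitute is None:
            return self._record(
                replace(queued, status="omitted", targets=queued.targets)
            )
        return self._record(substitute)

    # -- the tick ------------------------------------------------------------

    def tick(self) -> list[ActionInstance]:
        """Advance one tick: injections, then due agent actions, then physics.

        The tie-break at equal timestamps (participant before replayed agents
        before physical transitions) is fixed by this phase order.
        """
        if self.finished:
            return []
        # Termination is decided against the world as the previous tick left
        # it: a trial that has already met its end condition ends before any
        # same-tick action (e.g. a replayed alarm press releasing a gunman
        # trapped for exactly the full window) can undo it.
        if self.termination.should_terminate(self.t) or (
            self.t.seconds(self.scenario.config.tick) >= self.scenario.config.max_time
        ):
            self.finished = True
            self.history.end_time = self.t
            return []
        self._tick_events: list[ActionInstance] = []
        # phase 1: the live participant
        for name, params in self.policy.step(
            self.t, self.world, self._last_tick_events, self.scenario
        ):
            targets = tuple(params.pop("targets", ()))
            self.inject(
                ActionInstance(
                    schema=name,
                    actor=self.scenario.participant_id,
                    targets=targets,
                    params=params,
                )
            )
        # phase 2: due agent actions
        while (
            self._due_pos < len(self.due)
            and self.due[self._due_pos].start.ticks <= self.t.ticks
        ):
            self._attempt_due(self.due[self._due_pos])
            self._due_pos += 1
        # phase 3: physics
        for event in self.physics.step(self.world, self.t):
            schema = self.scenario.schemas[event.schema]
            if not evaluate_preconditions(event, schema, self.world):
                raise EngineInvariantError(
                    f"physics emitted {event.schema} with failing preconditions"
                )
            self._record(replace(event, status="scripted"))
        events = self._tick_events
        self._last_tick_events = events
        self.termination.observe(self.world, self.history, self.t)
        self.t = VirtualTime(self.t.ticks + 1)
        return events

    def run(self) -> History:
        while not self.finished:
            self.tick()
        return self.history


def attempt_replacement(
    action: ActionInstance,
    world: WorldState,
    rules: Sequence[ReplacementRule],
    scenario: Scenario,
    ctx: ReplayContext | None = None,
) -> ActionInstance | None:
    """Substitute a failed due action, or None for omission.

    Rules are visited in declaration order; only rules whose id matches the
    schema's ``replaceable`` tag and whose ``applies_to`` matches the schema
    name are consulted.  A substitution must satisfy its own preconditions —
    anything else is an engine invariant error.
    """
    schema = scenario.schemas[action.schema]
    for rule in rules:
        if rule.applies_to != action.schema or schema.replaceable != rule.id:
            continue
        candidate = rule.substitute(action, world, ctx)
        if candidate is None:
            continue
        cand_schema = scenario.schemas[candidate.schema]
        if not evaluate_preconditions(candidate, cand_schema, world):
            raise EngineInvariantError(
                f"rule {rule.id!r} produced invalid substitution for {action.schema}"
            )
        return candidate
    return None


# ---------------------------------------------------------------------------
# the engine

class ReplayEngine:
    """Record rounds, travel back, and replay with clones."""

    def __init__(self, scenario: Scenario) -> None:
        self.scenario = scenario

    # -- recording -----------------------------------------------------------

    def record_round(
        self,
        policy: Policy | None = None,
        round_index: int = 1,
        rng: Any = None,
    ) -> History:
        """Play the predetermined script and record participant interventions.

        Used for round 1 of both study conditions and for every round of the
        Repetition condition (the same program simply runs again).
        """
        runner = RoundRunner(
            self.scenario, round_index, self.scenario.script, policy=policy, rng=rng
        )
        return runner.run()

    # -- travelling ----------------------------------------------------------

    def travel_back(
        self,
        history: History,
        destination: VirtualTime | float = VirtualTime(0),
        clone_map: CloneMap | None = None,
    ) -> ReplayContext:
        """Build the replay context for one backward travel.

        The participant's recorded actions are re-attributed to a fresh clone
        P_k (k = the source round); all non-omitted agent-class actions with
        start >= destination form the due queue.  Physical-object transitions
        are never queued — they will be re-simulated.
        """
        if not isinstance(destination, VirtualTime):
            destination = VirtualTime.of(destination, self.scenario.config.tick)
        end = history.end_time or history.end
        if destination.ticks > end.ticks:
            raise RangeError(
                f"destination {destination} beyond history end {end}"
            )
        clone_map = CloneMap(dict(clone_map.mapping)) if clone_map else CloneMap()
        clone_id = f"{self.scenario.clone_prefix}{history.round_index}"
        if clone_id in {e.id for e in self.scenario.entities} or clone_id in set(
            clone_map.mapping.values()
        ):
            raise ScenarioError(f"clone id {clone_id!r} already in use")
        clone_map.mapping[history.round_index] = clone_id

        classes = {e.id: e.causal_class for e in self.scenario.entities}
        for cid in clone_map.clone_ids():
            classes[cid] = CausalClass.AGENT
        queue: list[ActionInstance] = []
        for action in history.actions:
            if action.status == "omitted" or action.start.ticks < destination.ticks:
                continue
            actor = action.actor
            if actor == self.scenario.participant_id:
                actor = clone_id
            if classes.get(actor) is not CausalClass.AGENT:
                continue  # physical transitions are re-simulated, never queued
            queue.append(replace(action, actor=actor))
        return ReplayContext(
            previous=history,
            destination=destination,
            queue=queue,
            clone_map=clone_map,
            rules=self.scenario.rules,
            config=self.scenario.config,
        )

    def _replay_initial_state(self, ctx: ReplayContext) -> WorldState:
        """Initial world for the replay round.

        State before the destination is immutable history: it is baked into
        the initial state rather than replayed.  The newest clone starts
        where the participant stood at the destination; the live participant
        re-enters with their declared initial state.
        """
        pid = self.scenario.participant_id
        # Bake strictly-pre-destination actions only: actions at the
        # destination itself are in the due queue and will replay.
        baked = ctx.previous.initial_state
        for action in ctx.previous.actions:
            if action.start.ticks >= ctx.destination.ticks:
                break
            if action.status == "omitted":
                continue
            baked = apply_effects(
                action, self.scenario.schemas[action.schema], baked
            )
        data = {e: dict(v) for e, v in baked.data.items()}
        newest = ctx.clone_map.mapping[ctx.previous.round_index]
        data[newest] = dict(data[pid])
        data[pid] = dict(self.scenario.entity(pid).initial_state)
        return WorldState(data)

    def start_replay(
        self, ctx: ReplayContext, policy: Policy | None = None, rng: Any = None
    ) -> RoundRunner:
        runner = RoundRunner(
            self.scenario,
            ctx.previous.round_index + 1,
            ctx.queue,
            ctx=ctx,
            policy=policy,
            initial_state=self._replay_initial_state(ctx),
            start=ctx.destination,
            rng=rng,
        )
        return runner

    def replay_round(
        self, ctx: ReplayContext, policy: Policy | None = None, rng: Any = None
    ) -> History:
        return self.start_replay(ctx, policy, rng).run()

    # -- whole sessions --------------------------------------------------

    def run_loop(
        self,
        policies: Sequence[Policy | None],
        n_rounds: int,
        mode: str = "time_travel",
        rng_factory: Callable[[int], Any] | None = None,
    ) -> list[History]:
        """Run a full session.

        ``time_travel`` chains record -> travel -> replay, each finished round
        becoming the next frame of reference (earlier rounds are discarded);
        ``repetition`` runs the identical script *n_rounds* times with no
        clones and no replay machinery.
        """
        if n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if mode not in ("time_travel", "repetition"):
            raise ScenarioError(f"unknown mode {mode!r}")
        rngs = rng_factory or (lambda k: None)
        histories: list[History] = []
        if mode == "repetition":
            for k in range(1, n_rounds + 1):
                histories.append(
                    self.record_round(_policy_for(policies, k), round_index=k, rng=rngs(k))
                )
            return histories
        current = self.record_round(_policy_for(policies, 1), round_index=1, rng=rngs(1))
        histories.append(current)
        clone_map: CloneMap | None = None
        for k in range(2, n_rounds + 1):
            ctx = self.travel_back(current, clone_map=clone_map)
            clone_map = ctx.clone_map
            current = self.replay_round(ctx, _policy_for(policies, k), rng=rngs(k))
            histories.append(current)
        return histories


def _policy_for(policies: Sequence[Policy | None], round_index: int) -> Policy | None:
    if round_index - 1 < len(policies):
        return policies[round_index - 1]
    return None
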