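"""Core domain types for recorded narrative histories.

A *history* is the engine's frame of reference for one round of an
interactive narrative: an initial world state plus an ordered sequence of
timestamped actions.  Actions are declarative — each schema names the
preconditions that must hold for the action to take place and the effects it
has on the world — so a later replay can check whether a recorded action is
still causally possible and derive the state trajectory by folding effects.

Entities fall into one of three causal classes:

* ``participant`` — the live human; their actions always execute,
* ``physical``   — deterministic objects (elevator, alarm) re-simulated
  from scratch every round,
* ``agent``      — scripted characters and past clones of the participant,
  whose recorded actions are replayed verbatim where preconditions allow.

All state variables take values from finite symbol domains and virtual time
lives on a fixed tick grid (default 0.1 s), which keeps precondition
evaluation exact and replay deterministic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping

DEFAULT_TICK = 0.1

Value = Any  # finite symbols only: str or bool


class SchemaError(ValueError):
    """An action refers to an undeclared entity, variable, or schema."""


class OrderingError(ValueError):
    """An action was appended before the end of its history."""


# ---------------------------------------------------------------------------
# time

@dataclass(frozen=True, order=True)
class VirtualTime:
    """A point on the virtual-time tick grid, stored as an integer tick count.

    Round start is tick 0.  Seconds enter and leave only at I/O boundaries
    (configs, logs) so equality comparisons between scheduled and current
    times never suffer float drift.
    """

    ticks: int

    def __post_init__(self) -> None:
        if self.ticks < 0:
            raise ValueError(f"virtual time must be non-negative, got {self.ticks} ticks")

    @staticmethod
    def of(seconds: float, tick: float = DEFAULT_TICK) -> "VirtualTime":
        return VirtualTime(round(seconds / tick))

    def seconds(self, tick: float = DEFAULT_TICK) -> float:
        return round(self.ticks * tick, 6)

    def plus(self, seconds: float, tick: float = DEFAULT_TICK) -> "VirtualTime":
        return VirtualTime(self.ticks + round(seconds / tick))

    def __repr__(self) -> str:  # pragma: no cover - debugging nicety
        return f"t{self.ticks}"


T0 = VirtualTime(0)


# ---------------------------------------------------------------------------
# entities and state

class CausalClass(str, enum.Enum):
    PARTICIPANT = "participant"
    PHYSICAL = "physical"
    AGENT = "agent"


@dataclass(frozen=True)
class Entity:
    id: str
    causal_class: CausalClass
    initial_state: Mapping[str, Value]


@dataclass(frozen=True)
class WorldState:
    """Total snapshot: every declared entity's variables and values.

    Value semantics: :meth:`with_value` returns a new world; instances are
    safe to store in trajectories.
    """

    data: Mapping[str, Mapping[str, Value]]

    def get(self, entity_id: str, variable: str) -> Value:
        try:
            ent = self.data[entity_id]
        except KeyError:
            raise SchemaError(f"undeclared entity {entity_id!r}") from None
        try:
            return ent[variable]
        except KeyError:
            raise SchemaError(f"entity {entity_id!r} has no variable {variable!r}") from None

    def with_value(self, entity_id: str, variable: str, value: Value) -> "WorldState":
        self.get(entity_id, variable)  # raises on undeclared names
        new_ent = dict(self.data[entity_id])
        new_ent[variable] = value
        new_data = dict(self.data)
        new_data[entity_id] = new_ent
        return WorldState(new_data)

    def entities(self) -> Iterable[str]:
        return self.data.keys()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WorldState):
            return NotImplemented
        return {k: dict(v) for k, v in self.data.items()} == {
            k: dict(v) for k, v in other.data.items()
        }

    def to_dict(self) -> dict:
        return {e: dict(sorted(v.items())) for e, v in sorted(self.data.items())}

    @staticmethod
    def from_dict(d: Mapping[str, Mapping[str, Value]]) -> "WorldState":
        return WorldState({e: dict(v) for e, v in d.items()})

    @staticmethod
    def initial(entities: Iterable[Entity]) -> "WorldState":
        return WorldState({e.id: dict(e.initial_state) for e in entities})


# ---------------------------------------------------------------------------
# predicates and effects

#: Predicate modes.  ``eq`` is exact symbol equality.  ``at_floor`` tests a
#: person's *effective* floor: their location equals the floor outright, or
#: they are inside the elevator while it stands stationary at that floor
#: (someone on the elevator platform at a floor is co-located with it).
PREDICATE_MODES = ("eq", "at_floor")

ELEVATOR_ID = "elevator"


@dataclass(frozen=True)
class Predicate:
    entity_id: str
    variable: str
    required_value: Value
    mode: str = "eq"

    def holds(self, world: WorldState) -> bool:
        actual = world.get(self.entity_id, self.variable)
        if self.mode == "eq":
            return actual == self.required_value
        if self.mode == "at_floor":
            return effective_floor(world, self.entity_id) == self.required_value
        raise SchemaError(f"unknown predicate mode {self.mode!r}")


def effective_floor(world: WorldState, person_id: str) -> Value | None:
    """The floor a person is effectively on, or None while in transit.

    A person inside the elevator counts as being on the floor the elevator is
    stationary at (frozen or not); between floors or mid-motion they are on
    no floor.
    """
    loc = world.get(person_id, "at")
    if loc != "elevator":
        return loc
    if (
        world.get(ELEVATOR_ID, "motion") == "stationary"
        and world.get(ELEVATOR_ID, "position") != "between"
    ):
        return world.get(ELEVATOR_ID, "position")
    return None


@dataclass(frozen=True)
class Effect:
    """A state assignment, or for ``op="toggle"`` a boolean flip.

    Toggle exists for the alarm button: replay preserves the *press*, not the
    resulting state, so the effect must be computed against the world at
    execution time.
    """

    entity_id: str
    variable: str
    new_value: Value = None
    op: str = "set"

    def apply(self, world: WorldState) -> WorldState:
        if self.op == "set":
            return world.with_value(self.entity_id, self.variable, self.new_value)
        if self.op == "toggle":
            current = world.get(self.entity_id, self.variable)
            if not isinstance(current, bool):
                raise SchemaError(
                    f"toggle on non-boolean {self.entity_id}.{self.variable}"
                )
            return world.with_value(self.entity_id, self.variable, not current)
        raise SchemaError(f"unknown effect op {self.op!r}")


# ---------------------------------------------------------------------------
# action schemas and instances

# Predicate/effect templates may reference the slots "{actor}" and "{target}",
# and required values may reference "{floor}" (bound from instance params).
_SLOT_KEYS = ("actor", "target", "floor")


def _bind(symbol: Any, bindings: Mapping[str, str]) -> Any:
    if isinstance(symbol, str) and symbol.startswith("{") and symbol.endswith("}"):
        key = symbol[1:-1]
        if key not in bindings:
            raise SchemaError(f"unbound template slot {symbol!r}")
        return bindings[key]
    return symbol


@dataclass(frozen=True)
class ActionSchema:
    name: str
    actor_class: CausalClass
    preconditions: tuple[Predicate, ...] = ()
    effects: tuple[Effect, ...] = ()
    has_target: bool = False
    replaceable: str | None = None  # id of the replacement rule, if any

    def bind_preconditions(self, action: "ActionInstance") -> list[Predicate]:
        b = action.bindings()
        return [
            replace(p, entity_id=_bind(p.entity_id, b), required_value=_bind(p.required_value, b))
            for p in self.preconditions
        ]

    def bind_effects(self, action: "ActionInstance") -> list[Effect]:
        b = action.bindings()
        return [
            replace(e, entity_id=_bind(e.entity_id, b), new_value=_bind(e.new_value, b))
            for e in self.effects
        ]


STATUSES = ("scripted", "injected", "replayed", "retargeted", "omitted")


@dataclass(frozen=True)
class ActionInstance:
    schema: str
    actor: str
    targets: tuple[str, ...] = ()
    params: Mapping[str, Value] = field(default_factory=dict)
    start: VirtualTime = T0
    round_index: int = 1
    status: str = "scripted"
    original_targets: tuple[str, ...] | None = None
    original_params: Mapping[str, Value] | None = None

    def bindings(self) -> dict[str, str]:
        b = {"actor": self.actor}
        if self.targets:
            b["target"] = self.targets[0]
        for k, v in self.params.items():
            b[k] = v
        return b

    def to_dict(self, tick: float = DEFAULT_TICK) -> dict:
        d = {
            "t": self.start.seconds(tick),
            "round": self.round_index,
            "actor": self.actor,
            "action": self.schema,
            "targets": list(self.targets),
            "status": self.status,
            "params": dict(self.params),
        }
        if self.original_targets is not None:
            d["original_targets"] = list(self.original_targets)
        if self.original_params is not None:
            d["original_params"] = dict(self.original_params)
        return d

    @staticmethod
    def from_dict(d: Mapping, tick: float = DEFAULT_TICK) -> "ActionInstance":
        return ActionInstance(
            schema=d["action"],
            actor=d["actor"],
            targets=tuple(d.get("targets", ())),
            params=dict(d.get("params", {})),
            start=VirtualTime.of(d["t"], tick),
            round_index=d["round"],
            status=d["status"],
            original_targets=(
                tuple(d["original_targets"]) if "original_targets" in d else None
            ),
            original_params=(
                dict(d["original_params"]) if "original_params" in d else None
            ),
        )


# ---------------------------------------------------------------------------
# operations

def evaluate_preconditions(
    action: ActionInstance, schema: ActionSchema, world: WorldState
) -> bool:
    """True iff every bound precondition of *action* holds in *world*.

    An empty precondition list is vacuously true.  Undeclared entities or
    variables raise :class:`SchemaError` rather than evaluating false.
    """
    return all(p.holds(world) for p in schema.bind_preconditions(action))


def apply_effects(
    action: ActionInstance, schema: ActionSchema, world: WorldState
) -> WorldState:
    """Fold the action's bound effects over *world*; the input is unchanged."""
    for eff in schema.bind_effects(action):
        world = eff.apply(world)
    return world


@dataclass
class History:
    """One round: initial world plus the ordered, timestamped action record.

    Omitted actions are kept as records (they matter for audit and attempt
    conservation) but contribute no effects to the state trajectory.
    """

    round_index: int
    initial_state: WorldState
    actions: list[ActionInstance] = field(default_factory=list)
    end_time: VirtualTime | None = None  # set when a termination rule fires

    @property
    def end(self) -> VirtualTime:
        return self.actions[-1].start if self.actions else T0


def append_action(history: History, t: VirtualTime, action: ActionInstance) -> History:
    """Append in place, enforcing non-decreasing timestamps.

    Equal timestamps are legal; ordering within a tick is the engine's
    tie-break (participant injections, then agent actions, then physics) and
    is represented by list position.
    """
    if history.actions and t < history.actions[-1].start:
        raise OrderingError(
            f"action at {t} precedes history end {history.actions[-1].start}"
        )
    if action.start != t:
        action = replace(action, start=t)
    history.actions.append(action)
    return history


def state_at(
    history: History, t: VirtualTime, schemas: Mapping[str, ActionSchema]
) -> WorldState:
    """World state at time *t*: fold of all non-omitted effects with start <= t."""
    world = history.initial_state
    for action in history.actions:
        if action.start > t:
            break
        if action.status == "omitted":
            continue
        world = apply_effects(action, schemas[action.schema], world)
    return world


@dataclass(frozen=True)
class Violation:
    index: int
    action: ActionInstance
    message: str


def validate_history(
    history: History, schemas: Mapping[str, ActionSchema]
) -> list[Violation]:
    """Check History invariants; violations are returned as data, never raised.

    Checks: non-decreasing timestamps; every non-omitted action's
    preconditions hold in the state immediately before it executes; round
    indices and statuses are mutually consistent.
    """
    violations: list[Violation] = []
    world = history.initial_state
    prev = T0
    for i, action in enumerate(history.actions):
        if action.start < prev:
            violations.append(
                Violation(i, action, f"timestamp {action.start} before {prev}")
            )
        prev = max(prev, action.start)
        if action.status not in STATUSES:
            violations.append(Violation(i, action, f"unknown status {action.status!r}"))
            continue
        if action.status in ("replayed", "retargeted", "omitted") and history.round_index < 2:
            violations.append(
                Violation(i, action, f"status {action.status} illegal in round 1")
            )
        if action.status == "omitted":
            continue
        schema = schemas.get(action.schema)
        if schema is None:
            violations.append(Violation(i, action, f"undeclared schema {action.schema!r}"))
            continue
        for pred in schema.bind_preconditions(action):
            if not pred.holds(world):
                violations.append(
                    Violation(
                        i,
                        action,
                        f"precondition {pred.entity_id}.{pred.variable}"
                        f"={pred.required_value!r} (mode={pred.mode}) fails",
                    )
                )
        world = apply_effects(action, schema, world)
    return violations
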