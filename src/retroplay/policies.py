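"""Built-in participant policies.

Policies are engine-exercising stand-ins for a human operator, not models of
participant behavior: each one is a deterministic (or seeded) rule mapping
observations to workbench controls.  A policy observes the world once per
tick and the actions executed during the *previous* tick, so reactions land
one tick (0.1 s) after the triggering event — about the fastest a human
could plausibly respond, and early enough for every maneuver the scenario
supports.
"""

from __future__ import annotations

from typing import Any, Mapping, Sequence

from .engine import Policy, Scenario, ScenarioError
from .timeline import ActionInstance, VirtualTime, WorldState


class BasePolicy:
    name = "base"

    def __init__(self) -> None:
        self._queue: list[tuple[int, str, dict]] = []  # (tick, schema, params)
        self._tick = 0.1

    def reset(self, scenario: Scenario, round_index: int, rng: Any) -> None:
        self._queue = []
        self._tick = scenario.config.tick
        self.rng = rng

    def schedule(self, t_seconds: float, schema: str, params: dict | None = None) -> None:
        self._queue.append(
            (VirtualTime.of(max(t_seconds, 0.0), self._tick).ticks, schema, params or {})
        )

    def observe(
        self, t: VirtualTime, world: WorldState,
        recent: Sequence[ActionInstance], scenario: Scenario,
    ) -> None:
        """Hook for reactive policies; default does nothing."""

    def step(self, t, world, recent, scenario):
        self.observe(t, world, recent, scenario)
        due = [(k, s, dict(p)) for (k, s, p) in self._queue if k <= t.ticks]
        self._queue = [q for q in self._queue if q[0] > t.ticks]
        return [(s, p) for (_, s, p) in sorted(due, key=lambda q: q[0])]


class DoNothing(BasePolicy):
    """Fully idle operator: the elevator never moves, nobody ascends."""

    name = "do_nothing"


class ScriptedPolicy(BasePolicy):
    """Issue an explicit timed list of (time s, control, params) actions."""

    name = "scripted"

    def __init__(self, actions: Sequence[tuple[float, str, Mapping]]) -> None:
        super().__init__()
        self._actions = [(float(t), s, dict(p)) for t, s, p in actions]

    def reset(self, scenario, round_index, rng) -> None:
        super().reset(scenario, round_index, rng)
        controls = set(scenario.schemas)
        for _, schema, _ in self._actions:
            if schema not in controls:
                raise ScenarioError(f"unknown control {schema!r} in scripted policy")
        for t, schema, params in self._actions:
            self.schedule(t, schema, params)


class _CompliantMixin(BasePolicy):
    """Push the elevator buttons on the scenario's compliant schedule."""

    def reset(self, scenario, round_index, rng) -> None:
        super().reset(scenario, round_index, rng)
        for t, button in scenario.metadata.get("compliant_pushes", ()):
            self.schedule(t, f"push_{button}")


class ComplyThenAlarm(_CompliantMixin):
    """Honor every transport request; press the alarm once the shooting starts.

    The default delay of 3.5 s from the first shot reproduces the canonical
    first round: all five recorded shots fall before the press.
    """

    name = "comply_then_alarm"

    def __init__(self, alarm_delay: float = 3.5) -> None:
        super().__init__()
        self.alarm_delay = float(alarm_delay)
        self._fired = False

    def reset(self, scenario, round_index, rng) -> None:
        super().reset(scenario, round_index, rng)
        self._fired = False

    def observe(self, t, world, recent, scenario) -> None:
        if self._fired:
            return
        for a in recent:
            if a.schema == "shoot":
                self.schedule(
                    a.start.seconds(self._tick) + self.alarm_delay, "press_alarm"
                )
                self._fired = True
                return


class DownOnShooting(_CompliantMixin):
    """Comply, then send the elevator down as soon as shots are heard —
    the classic sacrifice branch of the dilemma."""

    name = "down_on_shooting"

    def __init__(self, react_delay: float = 0.2) -> None:
        super().__init__()
        self.react_delay = float(react_delay)
        self._fired = False

    def reset(self, scenario, round_index, rng) -> None:
        super().reset(scenario, round_index, rng)
        self._fired = False

    def observe(self, t, world, recent, scenario) -> None:
        if self._fired:
            return
        for a in recent:
            if a.schema == "shoot":
                self.schedule(a.start.seconds(self._tick) + self.react_delay, "push_down")
                self._fired = True
                return


class TrapGunman(_CompliantMixin):
    """Comply, but freeze the elevator mid-ride once the gunman is aboard.

    Reacts to the start of elevator motion with the gunman inside, pressing
    the alarm ``ride_delay`` seconds into the (5 s) ride, so the elevator
    freezes between floors — the zero-casualty solution.
    """

    name = "trap_gunman"

    def __init__(self, ride_delay: float = 1.5) -> None:
        super().__init__()
        self.ride_delay = float(ride_delay)
        self._fired = False

    def reset(self, scenario, round_index, rng) -> None:
        super().reset(scenario, round_index, rng)
        self._fired = False

    def observe(self, t, world, recent, scenario) -> None:
        if self._fired:
            return
        gunman = scenario.metadata.get("gunman", "G")
        for a in recent:
            if a.schema == "elevator_start_up" and world.get(gunman, "at") == "elevator":
                self.schedule(a.start.seconds(self._tick) + self.ride_delay, "press_alarm")
                self._fired = True
                return


class FreezeAtGround(BasePolicy):
    """Press the alarm immediately after an earlier self's up-command.

    This is the move of the packaged worked narrative: the elevator freezes
    at the ground floor before it starts moving, so the gunman never
    ascends — and shoots whoever is within reach downstairs instead.  Only
    meaningful in a replay round (it reacts to another incarnation pressing
    the up button).
    """

    name = "freeze_at_ground"

    def __init__(self, react_delay: float = 0.1) -> None:
        super().__init__()
        self.react_delay = float(react_delay)
        self._fired = False

    def reset(self, scenario, round_index, rng) -> None:
        super().reset(scenario, round_index, rng)
        self._fired = False

    def observe(self, t, world, recent, scenario) -> None:
        if self._fired:
            return
        gunman = scenario.metadata.get("gunman", "G")
        for a in recent:
            if (
                a.schema == "push_up"
                and a.actor != scenario.participant_id
                and world.get(gunman, "at") == "elevator"
            ):
                self.schedule(a.start.seconds(self._tick) + self.react_delay, "press_alarm")
                self._fired = True
                return


class RandomAlarm(BasePolicy):
    """Press the alarm once, at a seeded uniform random time in a window.

    The window is given in absolute virtual seconds; with the packaged
    timings a window spanning the gunman's ride mixes the three outcome
    classes in proportion to the interval lengths, which gives a closed-form
    expectation for batch summaries.
    """

    name = "random_alarm"

    def __init__(self, window: tuple[float, float] = (31.0, 40.0)) -> None:
        super().__init__()
        self.window = (float(window[0]), float(window[1]))

    def reset(self, scenario, round_index, rng) -> None:
        super().reset(scenario, round_index, rng)
        if rng is None:
            raise ScenarioError("random_alarm requires a seeded rng")
        lo, hi = self.window
        self.schedule(float(rng.uniform(lo, hi)), "press_alarm")


POLICIES: dict[str, type] = {
    cls.name: cls
    for cls in (
        DoNothing,
        ComplyThenAlarm,
        DownOnShooting,
        TrapGunman,
        FreezeAtGround,
        RandomAlarm,
    )
}


def parse_policy(spec: str) -> Policy:
    """Parse a CLI policy spec: ``name`` or ``name:key=val,key=val``.

    ``scripted:t=<s>/<control>;t=...`` builds a :class:`ScriptedPolicy`, e.g.
    ``scripted:34.0/press_alarm;36.0/push_down``.
    """
    name, _, argstr = spec.partition(":")
    if name == "scripted":
        actions = []
        for part in filter(None, argstr.split(";")):
            t, _, control = part.partition("/")
            actions.append((float(t), control, {}))
        return ScriptedPolicy(actions)
    if name not in POLICIES:
        raise ScenarioError(
            f"unknown policy {name!r}; available: {sorted(POLICIES)} + scripted"
        )
    kwargs: dict[str, float] = {}
    for part in filter(None, argstr.split(",")):
        k, _, v = part.partition("=")
        kwargs[k] = float(v)
    return POLICIES[name](**kwargs)
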