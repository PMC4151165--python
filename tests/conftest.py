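"""Shared fixtures: the packaged gallery scenario and its reference rounds.

All fixtures are generated programmatically; session scope keeps the
canonical rounds (which every module asserts against) computed once.
Fixture histories must be treated as read-only by tests.
"""

from __future__ import annotations

import pytest

from retroplay import ReplayEngine, build_gallery
from retroplay.policies import ComplyThenAlarm, FreezeAtGround


@pytest.fixture(scope="session")
def scenario():
    return build_gallery()


@pytest.fixture(scope="session")
def engine(scenario):
    return ReplayEngine(scenario)


@pytest.fixture(scope="session")
def round1(engine):
    """Canonical first round: compliant operator, alarm after the shooting."""
    return engine.record_round(ComplyThenAlarm())


@pytest.fixture(scope="session")
def worked_example(engine, round1):
    """The reference replay: alarm injected right after the clone's
    up-command; returns (context, round-2 history)."""
    ctx = engine.travel_back(round1)
    h2 = engine.replay_round(ctx, FreezeAtGround())
    return ctx, h2


def signature(history, with_actor=True):
    """Comparable core of a history's executed actions (ignores status)."""
    return [
        (
            (a.actor,) if with_actor else ()
        ) + (a.start.ticks, a.schema, a.targets, a.params.get("floor"))
        for a in history.actions
        if a.status != "omitted"
    ]


def settled_states(history, schemas):
    """Yield (t, world) at the end of every tick that saw at least one
    executed action — the points where physical invariants must hold."""
    from retroplay import apply_effects

    world = history.initial_state
    actions = [a for a in history.actions if a.status != "omitted"]
    for i, a in enumerate(actions):
        world = apply_effects(a, schemas[a.schema], world)
        if i + 1 == len(actions) or actions[i + 1].start != a.start:
            yield a.start, world
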