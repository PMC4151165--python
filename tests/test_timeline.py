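"""Unit tests for the core domain types and history operations."""

import dataclasses
import itertools
import random

import pytest

from retroplay import (
    ActionInstance,
    ActionSchema,
    History,
    Predicate,
    VirtualTime,
    WorldState,
    append_action,
    apply_effects,
    evaluate_preconditions,
    state_at,
    validate_history,
)
from retroplay.timeline import OrderingError, SchemaError



def make_world(scenario, **overrides):
    world = WorldState.initial(scenario.entities)
    for key, value in overrides.items():
        entity, variable = key.split("__")
        world = world.with_value(entity, variable, value)
    return world


class TestVirtualTime:
    def test_quantizes_to_tick_grid(self):
        assert VirtualTime.of(32.5).ticks == 325
        assert VirtualTime.of(32.54).ticks == 325
        assert VirtualTime.of(0.0) == VirtualTime(0)

    def test_ordering_and_seconds_roundtrip(self):
        assert VirtualTime.of(1.0) < VirtualTime.of(1.1)
        for s in (0.0, 0.1, 7.0, 38.5, 47.5):
            assert VirtualTime.of(s).seconds() == s

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            VirtualTime(-1)


class TestEvaluatePreconditions:
    def shoot(self, target="V1", floor="upper"):
        return ActionInstance(
            schema="shoot", actor="G", targets=(target,), params={"floor": floor}
        )

    def test_gunman_on_wrong_floor_cannot_shoot(self, scenario):
        world = make_world(
            scenario, G__at="ground", V1__at="upper"
        )
        assert not evaluate_preconditions(
            self.shoot(), scenario.schemas["shoot"], world
        )

    def test_colocated_gunman_and_target(self, scenario):
        world = make_world(scenario, G__at="upper", V1__at="upper")
        assert evaluate_preconditions(self.shoot(), scenario.schemas["shoot"], world)

    def test_gunman_on_elevator_platform_counts_as_on_floor(self, scenario):
        world = make_world(
            scenario, G__at="elevator", V1__at="ground", elevator__position="ground"
        )
        assert evaluate_preconditions(
            self.shoot(floor="ground"), scenario.schemas["shoot"], world
        )
        # ... but not while the elevator hangs between floors
        world = world.with_value("elevator", "position", "between")
        assert not evaluate_preconditions(
            self.shoot(floor="ground"), scenario.schemas["shoot"], world
        )

    def test_empty_precondition_list_is_vacuously_true(self, scenario):
        act = ActionInstance(schema="utterance", actor="V6", params={"content": "hi"})
        assert evaluate_preconditions(
            act, scenario.schemas["utterance"], make_world(scenario)
        )

    def test_start_moving_up_enabled_states_by_enumeration(self, scenario):
        """Brute-force the elevator state space: motion may start only from
        a stationary, unfrozen car at the commanded origin floor."""
        schema = scenario.schemas["elevator_start_up"]
        act = ActionInstance(
            schema="elevator_start_up", actor="elevator", params={"from": "ground"}
        )
        enabled = set()
        for position, motion, frozen in itertools.product(
            ("ground", "upper", "between"),
            ("stationary", "moving_up", "moving_down"),
            (False, True),
        ):
            world = make_world(
                scenario,
                elevator__position=position,
                elevator__motion=motion,
                elevator__frozen=frozen,
                elevator__command="up",
            )
            if evaluate_preconditions(act, schema, world):
                enabled.add((position, motion, frozen))
        # independent oracle: direct filter over the same product
        expected = {
            (p, m, f)
            for p, m, f in itertools.product(
                ("ground", "upper", "between"),
                ("stationary", "moving_up", "moving_down"),
                (False, True),
            )
            if p == "ground" and m == "stationary" and not f
        }
        assert enabled == expected

    def test_undeclared_variable_is_schema_error(self, scenario):
        bad = ActionSchema(
            "bogus",
            scenario.schemas["shoot"].actor_class,
            preconditions=(Predicate("G", "mood", "angry"),),
        )
        act = ActionInstance(schema="bogus", actor="G")
        with pytest.raises(SchemaError):
            evaluate_preconditions(act, bad, make_world(scenario))


class TestApplyEffects:
    def test_shoot_changes_only_the_target_alive_flag(self, scenario):
        world = make_world(scenario, G__at="ground", V6__at="ground")
        act = ActionInstance(
            schema="shoot", actor="G", targets=("V6",), params={"floor": "ground"}
        )
        after = apply_effects(act, scenario.schemas["shoot"], world)
        diff = {
            (e, v)
            for e in world.entities()
            for v in world.data[e]
            if world.get(e, v) != after.get(e, v)
        }
        assert diff == {("V6", "alive")}
        assert after.get("V6", "alive") is False
        assert world.get("V6", "alive") is True  # input untouched

    def test_utterance_is_identity(self, scenario):
        world = make_world(scenario)
        act = ActionInstance(schema="utterance", actor="V6", params={"content": "?"})
        assert apply_effects(act, scenario.schemas["utterance"], world) == world

    def test_alarm_press_composes_to_identity(self, scenario):
        """The alarm button is a toggle: two presses restore the world."""
        world = make_world(scenario)
        press = ActionInstance(schema="press_alarm", actor="P")
        schema = scenario.schemas["press_alarm"]
        once = apply_effects(press, schema, world)
        assert once.get("alarm", "on") is True
        twice = apply_effects(press, schema, once)
        assert twice == world


class TestHistoryOperations:
    def test_append_rejects_earlier_timestamp(self, scenario):
        h = History(1, make_world(scenario))
        a = ActionInstance(schema="utterance", actor="V1", params={"content": "x"})
        append_action(h, VirtualTime.of(2.0), a)
        with pytest.raises(OrderingError):
            append_action(h, VirtualTime.of(1.0), a)

    def test_append_at_equal_timestamp_is_permitted(self, scenario):
        h = History(1, make_world(scenario))
        a = ActionInstance(schema="utterance", actor="V1", params={"content": "x"})
        append_action(h, VirtualTime.of(2.0), a)
        append_action(h, VirtualTime.of(2.0), a)
        assert len(h.actions) == 2

    def test_alarm_press_effect_lands_in_next_state(self, scenario, round1):
        """The canonical round records the alarm press; the derived state
        right after it has the alarm on."""
        press = next(a for a in round1.actions if a.schema == "press_alarm")
        before = state_at(round1, VirtualTime(press.start.ticks - 1), scenario.schemas)
        after = state_at(round1, press.start, scenario.schemas)
        assert before.get("alarm", "on") is False
        assert after.get("alarm", "on") is True

    def test_state_at_zero_is_initial_state(self, scenario, round1):
        assert state_at(round1, VirtualTime(0), scenario.schemas) == round1.initial_state

    def test_gunman_location_follows_script(self, scenario, round1):
        assert (
            state_at(round1, VirtualTime.of(32.0), scenario.schemas).get("G", "at")
            == "elevator"
        )

    def test_state_at_equals_brute_force_refold(self, scenario, round1):
        """Independent oracle: refold effects from scratch at random times."""
        rng = random.Random(7)
        for _ in range(25):
            t = VirtualTime(rng.randrange(0, 500))
            world = round1.initial_state
            for a in round1.actions:  # oracle: plain loop, no shared code path
                if a.start.ticks <= t.ticks and a.status != "omitted":
                    world = apply_effects(a, scenario.schemas[a.schema], world)
            assert state_at(round1, t, scenario.schemas) == world


class TestValidateHistory:
    def test_canonical_round_is_clean(self, scenario, round1):
        assert validate_history(round1, scenario.schemas) == []

    def test_worked_replay_round_is_clean(self, scenario, worked_example):
        _, h2 = worked_example
        assert validate_history(h2, scenario.schemas) == []

    def test_impossible_shot_is_reported(self, scenario):
        h = History(1, make_world(scenario, G__at="ground"))
        append_action(
            h,
            VirtualTime.of(1.0),
            ActionInstance(
                schema="shoot", actor="G", targets=("V1",), params={"floor": "upper"}
            ),
        )
        violations = validate_history(h, scenario.schemas)
        assert len(violations) >= 1
        assert any("precondition" in v.message for v in violations)

    def test_broken_time_order_is_reported(self, scenario, round1):
        """Permutation fuzz: swapping any two differently-timed actions
        breaks monotonicity and must be detected."""
        rng = random.Random(3)
        for _ in range(20):
            actions = list(round1.actions)
            i, j = sorted(rng.sample(range(len(actions)), 2))
            if actions[i].start == actions[j].start:
                continue
            actions[i], actions[j] = actions[j], actions[i]
            shuffled = History(1, round1.initial_state, actions)
            assert any(
                "timestamp" in v.message
                for v in validate_history(shuffled, scenario.schemas)
            )

    def test_randomly_generated_legal_sequences_validate(self, scenario):
        """Generator/validator agreement: sequences built by choosing only
        precondition-satisfying actions have no violations."""
        rng = random.Random(11)
        schemas = scenario.schemas
        for _ in range(100):
            world = WorldState.initial(scenario.entities)
            h = History(1, world)
            t = 0
            for _ in range(rng.randrange(5, 25)):
                candidates = _applicable_actions(scenario, world)
                if not candidates:
                    break
                act = rng.choice(candidates)
                t += rng.randrange(0, 20)
                act = dataclasses.replace(act, start=VirtualTime(t))
                append_action(h, VirtualTime(t), act)
                world = apply_effects(act, schemas[act.schema], world)
            assert validate_history(h, schemas) == []


def _applicable_actions(scenario, world):
    """Enumerate action instances whose preconditions hold in *world*."""
    out = []
    persons = ["P", "G", "V1", "V2", "V3", "V4", "V5", "V6"]
    candidates = []
    for p in persons[1:]:
        candidates.append(ActionInstance(schema="enter_gallery", actor=p))
        for floor in ("ground", "upper"):
            candidates.append(
                ActionInstance(schema="enter_elevator", actor=p, params={"floor": floor})
            )
            candidates.append(
                ActionInstance(schema="enter_floor", actor=p, params={"floor": floor})
            )
    for target in persons[2:]:
        for floor in ("ground", "upper"):
            candidates.append(
                ActionInstance(
                    schema="shoot", actor="G", targets=(target,), params={"floor": floor}
                )
            )
    for ctrl in ("push_up", "push_down", "press_alarm"):
        candidates.append(ActionInstance(schema=ctrl, actor="P"))
    for name in ("elevator_start_up", "elevator_start_down"):
        for frm in ("ground", "upper", "between"):
            candidates.append(
                ActionInstance(schema=name, actor="elevator", params={"from": frm})
            )
    for name in ("elevator_arrive_upper", "elevator_arrive_ground", "alarm_on", "alarm_off"):
        candidates.append(ActionInstance(schema=name, actor=name.split("_")[0]))
    for act in candidates:
        if evaluate_preconditions(act, scenario.schemas[act.schema], world):
            out.append(act)
    return out


class TestSerialization:
    def test_action_dict_roundtrip(self, round1, worked_example):
        _, h2 = worked_example
        for action in round1.actions + h2.actions:
            assert ActionInstance.from_dict(action.to_dict()) == action

    def test_omitted_actions_are_inert(self, scenario, worked_example):
        """Dropping the omitted records leaves the state trajectory
        unchanged at every step."""
        _, h2 = worked_example
        assert any(a.status == "omitted" for a in h2.actions)
        stripped = History(
            h2.round_index,
            h2.initial_state,
            [a for a in h2.actions if a.status != "omitted"],
        )
        for ticks in range(0, 470, 7):
            t = VirtualTime(ticks)
            assert state_at(h2, t, scenario.schemas) == state_at(
                stripped, t, scenario.schemas
            )
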