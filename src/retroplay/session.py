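"""Session I/O: event logs, batch runs, summary tables, transcripts.

Event logs are JSON Lines: one ``round_start`` record per round (carrying
the round's initial world state, so a log round-trips to an identical
:class:`~retroplay.timeline.History`) followed by one ``action`` record per
attempted action — executed, retargeted, omitted, or injected alike.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .engine import Policy, ReplayEngine, Scenario
from .gallery import VISITORS, build_gallery, count_shot, load_config
from .timeline import ActionInstance, History, VirtualTime, WorldState


class ParseError(ValueError):
    """A malformed event-log line; the message names the line number."""


# ---------------------------------------------------------------------------
# event logs

def write_event_log(histories: Sequence[History], path, tick: float = 0.1) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for h in histories:
            header = {
                "type": "round_start",
                "round": h.round_index,
                "initial_state": h.initial_state.to_dict(),
                "end_time": h.end_time.seconds(tick) if h.end_time else None,
            }
            fh.write(json.dumps(header, sort_keys=True) + "\n")
            for a in h.actions:
                rec = {"type": "action"}
                rec.update(a.to_dict(tick))
                fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_event_log(path, tick: float = 0.1) -> list[History]:
    histories: list[History] = []
    current: History | None = None
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                kind = rec["type"]
                if kind == "round_start":
                    current = History(
                        round_index=rec["round"],
                        initial_state=WorldState.from_dict(rec["initial_state"]),
                        end_time=(
                            VirtualTime.of(rec["end_time"], tick)
                            if rec.get("end_time") is not None
                            else None
                        ),
                    )
                    histories.append(current)
                elif kind == "action":
                    if current is None:
                        raise KeyError("action before any round_start")
                    current.actions.append(ActionInstance.from_dict(rec, tick))
                else:
                    raise KeyError(f"unknown record type {kind!r}")
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return histories


# ---------------------------------------------------------------------------
# summaries

@dataclass
class SessionSummary:
    """Per-round aggregates across sessions, Table-shaped: mean and standard
    error of the participant's action count and of the number of visitors
    shot.  Values are recomputable exactly from the event logs."""

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.4f")


def _se(values: list[float]) -> float:
    n = len(values)
    if n < 2:
        return 0.0
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return math.sqrt(var / n)


def summarize(
    sessions: Sequence[Sequence[History]], visitors: Iterable[str] = VISITORS
) -> SessionSummary:
    """Aggregate a batch of sessions (each a list of per-round histories)."""
    if not sessions:
        raise ValueError("empty batch")
    n_rounds = max(len(s) for s in sessions)
    rows = []
    for r in range(n_rounds):
        actions = []
        shot = []
        for s in sessions:
            if r >= len(s):
                continue
            h = s[r]
            actions.append(sum(1 for a in h.actions if a.status == "injected"))
            shot.append(count_shot(h, visitors)[0])
        rows.append(
            {
                "round": r + 1,
                "n": len(actions),
                "actions_mean": sum(actions) / len(actions),
                "actions_se": _se(actions),
                "visitors_shot_mean": sum(shot) / len(shot),
                "visitors_shot_se": _se(shot),
            }
        )
    return SessionSummary(pd.DataFrame(rows).set_index("round"))


# ---------------------------------------------------------------------------
# transcripts

_PHRASES = {
    "enter_gallery": "{actor} enters gallery",
    "utterance": "{actor} speaks ({content})",
    "enter_elevator": "{actor} enters elevator",
    "enter_floor": "{actor} exits elevator at {floor} floor",
    "push_up": "{actor} pushes elevator up",
    "push_down": "{actor} pushes elevator down",
    "press_alarm": "{actor} pushes alarm",
    "shoot": "{actor} shoots {target}",
    "elevator_start_up": "Elevator starts moving up",
    "elevator_start_down": "Elevator starts moving down",
    "elevator_arrive_upper": "Elevator arrives upper floor",
    "elevator_arrive_ground": "Elevator arrives ground floor",
    "alarm_on": "alarm on",
    "alarm_off": "alarm off",
}


def render_transcript(histories: Sequence[History], tick: float = 0.1) -> str:
    """Human-readable script of a session, one line per attempted action."""
    lines: list[str] = []
    for h in histories:
        lines.append(f"=== Round {h.round_index} ===")
        for a in h.actions:
            phrase = _PHRASES.get(a.schema, a.schema).format(
                actor=a.actor,
                target=a.targets[0] if a.targets else "",
                **{k: v for k, v in a.params.items()},
            )
            t = a.start.seconds(tick)
            marker = {
                "omitted": "  [omitted] ",
                "retargeted": "  [retargeted] ",
                "injected": "* ",
            }.get(a.status, "  ")
            extra = ""
            if a.status == "retargeted" and a.original_targets:
                extra = f" (was {','.join(a.original_targets)})"
            elif a.status == "omitted" and a.targets:
                phrase = _PHRASES.get(a.schema, a.schema).format(
                    actor=a.actor, target=a.targets[0], **dict(a.params)
                )
            lines.append(f"{t:7.1f} {marker}{phrase}{extra}")
        if h.end_time is not None:
            lines.append(f"{h.end_time.seconds(tick):7.1f}   -- round ends --")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# batch runner

def run_session(
    *,
    config_path=None,
    mode: str = "time_travel",
    rounds: int = 3,
    policies: dict[int, Policy] | None = None,
    seed: int = 0,
    out_dir=None,
    scenario: Scenario | None = None,
) -> list[History]:
    """Run one full session and (optionally) write its artifacts.

    ``policies`` maps round number (1-based) to a Policy; unmapped rounds get
    no interventions.  Writes ``events.jsonl``, ``summary.tsv`` and
    ``transcript.txt`` into *out_dir* when given.
    """
    import numpy as np

    if scenario is None:
        cfg = load_config(config_path) if config_path else None
        scenario = build_gallery(cfg)
    policies = policies or {}
    plist = [policies.get(k) for k in range(1, rounds + 1)]
    engine = ReplayEngine(scenario)
    histories = engine.run_loop(
        plist,
        rounds,
        mode=mode,
        rng_factory=lambda k: np.random.default_rng([seed % (2**31), k]),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tick = scenario.config.tick
        write_event_log(histories, out / "events.jsonl", tick)
        summarize([histories]).to_tsv(out / "summary.tsv")
        (out / "transcript.txt").write_text(render_transcript(histories, tick))
    return histories


def selftest() -> list[str]:
    """Replay the packaged worked example and diff it against the expected
    script.  Returns a list of mismatch descriptions (empty = pass)."""
    from . import fixtures
    from .policies import ComplyThenAlarm, FreezeAtGround

    scenario = build_gallery()
    engine = ReplayEngine(scenario)
    h1 = engine.record_round(ComplyThenAlarm())
    ctx = engine.travel_back(h1)
    h2 = engine.replay_round(ctx, FreezeAtGround())
    tick = scenario.config.tick

    problems: list[str] = []
    for h, expected, label in (
        (h1, fixtures.FIRST_ROUND_FROM_GUNMAN_ENTRY, "round 1"),
        (h2, fixtures.SECOND_ROUND_FROM_GUNMAN_ENTRY, "round 2"),
    ):
        got = [
            (a.start.seconds(tick), a.actor, a.schema, tuple(a.targets), a.status)
            for a in h.actions
            if a.status != "omitted"
            and a.start.seconds(tick) >= fixtures.GUNMAN_ENTRY_TIME
        ]
        if got != [tuple(e) for e in expected]:
            problems.append(f"{label}: executed actions diverge from the fixture")
            for line in (f"  expected: {expected}", f"  got:      {got}"):
                problems.append(line)
    omitted = tuple(
        a.targets[0] for a in h2.actions if a.status == "omitted" and a.schema == "shoot"
    )
    if omitted != fixtures.SECOND_ROUND_OMITTED_SHOT_TARGETS:
        problems.append(f"round 2 omitted shots {omitted} != expected")
    return problems
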