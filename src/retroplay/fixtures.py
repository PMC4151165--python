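"""Packaged worked-example fixture.

The reference narrative of the gallery scenario, used by the ``--selftest``
command and the test suite: a compliant first round ending in five deaths,
then a replay in which the participant presses the alarm immediately after
their previous clone's up-command.  The elevator freezes at the ground
floor, the ride never happens, the shootings are retargeted to the
ground-floor visitor and the participant (the remaining three are omitted),
and the clone's later alarm press now switches the alarm *off* — actions
are preserved, not outcomes.

Each expected entry is (t_seconds, actor, schema, targets, status) for the
*executed* (non-omitted) actions from the gunman's entry onward.
"""

FIRST_ROUND_FROM_GUNMAN_ENTRY = [
    (31.0, "G", "enter_gallery", (), "scripted"),
    (31.5, "G", "utterance", (), "scripted"),
    (31.5, "elevator", "elevator_arrive_ground", (), "scripted"),
    (32.0, "G", "enter_elevator", (), "scripted"),
    (32.5, "P", "push_up", (), "injected"),
    (33.0, "elevator", "elevator_start_up", (), "scripted"),
    (38.0, "elevator", "elevator_arrive_upper", (), "scripted"),
    (38.5, "G", "shoot", ("V1",), "scripted"),
    (39.0, "G", "shoot", ("V2",), "scripted"),
    (39.5, "G", "shoot", ("V3",), "scripted"),
    (40.0, "G", "shoot", ("V4",), "scripted"),
    (40.5, "G", "shoot", ("V5",), "scripted"),
    (42.0, "P", "press_alarm", (), "injected"),
    (42.0, "alarm", "alarm_on", (), "scripted"),
]

SECOND_ROUND_FROM_GUNMAN_ENTRY = [
    (31.0, "G", "enter_gallery", (), "replayed"),
    (31.5, "G", "utterance", (), "replayed"),
    (31.5, "elevator", "elevator_arrive_ground", (), "scripted"),
    (32.0, "G", "enter_elevator", (), "replayed"),
    (32.5, "P1", "push_up", (), "replayed"),
    (32.6, "P", "press_alarm", (), "injected"),
    (32.6, "alarm", "alarm_on", (), "scripted"),
    # elevator start/arrive do not occur: the elevator is frozen at ground
    (38.5, "G", "shoot", ("V6",), "retargeted"),   # was V1
    (39.0, "G", "shoot", ("P",), "retargeted"),    # was V2
    # shots at V3, V4, V5 are omitted: nobody left within reach
    (42.0, "P1", "press_alarm", (), "replayed"),
    (42.0, "alarm", "alarm_off", (), "scripted"),
]

SECOND_ROUND_OMITTED_SHOT_TARGETS = ("V3", "V4", "V5")

GUNMAN_ENTRY_TIME = 31.0
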