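"""Factorial climate-chamber design vocabulary.

Two acclimatisation temperatures crossed with three regimes give six
experimental groups; every plant is sampled (evening + morning) at the
end of each of three phases.  Group labels use an en-dash-free ASCII
form (``cold-dry``) so they can live in file paths and TSV columns.
"""

GROUPS = (
    "cold-control",
    "cold-dry",
    "cold-switch",
    "warm-control",
    "warm-dry",
    "warm-switch",
)

#: Groups that received no treatment; they anchor the percent-change matrix.
CONTROL_GROUPS = ("cold-control", "warm-control")

#: Map from a treated group to the control group sharing its acclimatisation.
CONTROL_OF = {
    "cold-dry": "cold-control",
    "cold-switch": "cold-control",
    "warm-dry": "warm-control",
    "warm-switch": "warm-control",
}

PHASES = ("acclimatisation", "treatment", "reversal")

TIMES_OF_DAY = ("evening", "morning")


def validate_group(group: str) -> str:
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    return group


def validate_phase(phase: str) -> str:
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    return phase
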