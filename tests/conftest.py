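"""Shared fixtures: the standard 40 µl pot and the low-salt lysozyme exchange."""

import pytest

from gradpot.planner import GradientSpec
from gradpot.reservoir import PotState
from gradpot.solutions import Component, Solution


@pytest.fixture
def start_solution() -> Solution:
    return Solution(
        (
            Component("NaCl", 8.0, "%w/v"),
            Component("sodium acetate", 20.0, "mM"),
        ),
        label="well solution",
    )


@pytest.fixture
def target_solution() -> Solution:
    return Solution(
        (
            Component("NaCl", 3.0, "%w/v"),
            Component("sodium acetate", 20.0, "mM"),
            Component("lysozyme", 5.0, "mg/ml"),
        ),
        label="low-salt target",
    )


@pytest.fixture
def pot40(start_solution) -> PotState:
    """Standard 40 µl pot filled with the start solution, no evaporation."""
    return PotState(volume=40.0, composition=start_solution)


@pytest.fixture
def lysozyme_spec(start_solution, target_solution, pot40) -> GradientSpec:
    """0–95% linear gradient over 40 min in the standard pot."""
    return GradientSpec(
        start=start_solution,
        target=target_solution,
        final_fraction=0.95,
        duration=40.0,
        mode="linear",
        ticks=40,
        pot=pot40,
    )


def make_spec(start, target, pot, f=0.95, duration=40.0, mode="linear", ticks=40):
    return GradientSpec(
        start=start,
        target=target,
        final_fraction=f,
        duration=duration,
        mode=mode,
        ticks=ticks,
        pot=pot,
    )
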