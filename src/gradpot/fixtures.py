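"""Reproducible random gradient problems for property testing.

:func:`generate_fixture` draws a complete, valid :class:`RunConfig` from
documented ranges covering the realistic envelope of the method: pots of
10–100 µl, gradients to 50–99% over 5–180 min with 1–500 events, one to four
components with unit-appropriate concentrations, and evaporation of 0, 1
(covered pot) or 6 µl/h (open pot).  The draw is deterministic per seed, and
every pipeline report records the seed so a run can be replayed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ComponentCfg, GradientCfg, OutputsCfg, PotCfg, PumpCfg, RunConfig, SolutionCfg

__all__ = ["FixtureProblem", "generate_fixture"]

_NAMES = (
    "NaCl",
    "glycerol",
    "PEG 8000",
    "ammonium sulfate",
    "sodium acetate",
    "KH2PO4",
    "lysozyme",
    "trehalose",
)

# plausible max concentration per unit (keeps draws lab-realistic)
_UNIT_RANGES = {
    "%w/v": 30.0,
    "%v/v": 40.0,
    "M": 3.0,
    "mM": 500.0,
    "mg/ml": 50.0,
}


@dataclass(frozen=True)
class FixtureProblem:
    """A randomly drawn but fully valid run configuration plus its seed."""

    seed: int
    config: RunConfig


def generate_fixture(seed: int) -> FixtureProblem:
    """Draw a reproducible random gradient problem.

    Ranges: V ∈ [10, 100] µl, f ∈ [0.5, 0.99], T ∈ [5, 180] min,
    n ∈ [1, 500], 1–4 components, E ∈ {0, 1, 6} µl/h.  The same seed always
    yields the same problem.
    """
    rng = np.random.default_rng(seed)
    n_comp = int(rng.integers(1, 5))
    names = rng.choice(len(_NAMES), size=n_comp, replace=False)
    units = list(_UNIT_RANGES)
    start_comps = []
    target_comps = []
    for idx in names:
        unit = units[int(rng.integers(0, len(units)))]
        hi = _UNIT_RANGES[unit]
        c_start = float(rng.uniform(0, hi))
        c_target = float(rng.uniform(0, hi))
        start_comps.append(
            ComponentCfg(name=_NAMES[idx], concentration=round(c_start, 6), unit=unit)
        )
        target_comps.append(
            ComponentCfg(name=_NAMES[idx], concentration=round(c_target, 6), unit=unit)
        )
    # guarantee start != target in at least one component
    target_comps[0] = target_comps[0].model_copy(
        update={"concentration": start_comps[0].concentration + 1.0}
    )

    cfg = RunConfig(
        schema_version=1,
        label=f"fixture-{seed}",
        start=SolutionCfg(components=start_comps, label="start"),
        target=SolutionCfg(components=target_comps, label="target"),
        pot=PotCfg(
            volume_ul=float(rng.uniform(10, 100)),
            evaporation_ul_per_h=float(rng.choice([0.0, 1.0, 6.0])),
        ),
        gradient=GradientCfg(
            final_fraction=float(rng.uniform(0.5, 0.99)),
            duration_min=float(rng.uniform(5, 180)),
            mode=("linear", "equal_volume")[int(rng.integers(0, 2))],
            ticks=int(rng.integers(1, 501)),
        ),
        pump=PumpCfg(),
        outputs=OutputsCfg(),
        seed=seed,
    )
    return FixtureProblem(seed=seed, config=cfg)
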