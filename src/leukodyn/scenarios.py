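"""Scenario presets and seeded synthetic scenario generation.

Ships the three disease-stage parameter presets of the Leslie-Gower model
(early prognosis, acute, chronic), the post-chemotherapy transplant cell
counts, and a seeded generator of clinically plausible random scenarios:
rates jittered by +-10%, initial leukocyte density drawn from the clinical
range 30-200 (in units of 1e9 cells/liter), the cancerous density a uniform
fraction of it, and a horizon of 40-80 days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hsc_game import TransplantCounts
from .leslie import LeslieParams, PopulationState

#: disease-stage presets (rates in 1/day); k and c take module defaults
STAGE_PRESETS: dict[str, dict] = {
    "early": {"r1": 0.5, "c1": 1.42e-6, "b": 0.1, "r2": 0.6, "c2": 0.5},
    "acute": {"r1": 0.7, "c1": 0.7, "b": 0.25, "r2": 0.75, "c2": 0.4},
    "chronic": {"r1": 0.6, "c1": 0.6, "b": 0.6, "r2": 0.6, "c2": 0.6},
}

#: clinical range of leukocyte counts, in model units of 1e9 cells/liter
LEU_RANGE = (30.0, 200.0)
#: observation window in days
HORIZON_RANGE = (40, 80)
#: multiplicative jitter applied to each rate by the random generator
RATE_JITTER = (0.9, 1.1)
#: initial c.leu density as a fraction of the initial leu density
CLEU_FRACTION = (0.1, 1.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """A fully specified simulation scenario."""

    stage: str
    params: LeslieParams
    initial_state: PopulationState
    seed: int | None
    horizon: float  # days

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "params": self.params.to_dict(),
            "initial_state": {"i": self.initial_state.i, "l": self.initial_state.l},
            "seed": self.seed,
            "horizon": self.horizon,
        }


def table4_scenario(stage: str) -> LeslieParams:
    """Parameter preset for a disease stage ("early", "acute", "chronic")."""
    if stage not in STAGE_PRESETS:
        raise KeyError(f"unknown stage {stage!r}; expected one of {sorted(STAGE_PRESETS)}")
    return LeslieParams(**STAGE_PRESETS[stage])


def transplant_counts() -> TransplantCounts:
    """Post-chemotherapy cell counts for the transplant scenarios."""
    return TransplantCounts()


def random_scenario(stage: str, seed: int) -> ScenarioConfig:
    """Seeded random scenario around a stage preset.

    Each rate is multiplied by an independent Uniform(0.9, 1.1) factor; the
    initial leu density is Uniform(30, 200) model units, the initial c.leu
    density a Uniform(0.1, 1.0) fraction of it, and the horizon a uniform
    integer number of days in [40, 80].  Fully determined by ``seed``.
    """
    base = table4_scenario(stage)
    rng = np.random.default_rng(seed)
    factors = rng.uniform(*RATE_JITTER, size=5)
    params = LeslieParams(
        r1=base.r1 * factors[0],
        c1=base.c1 * factors[1],
        b=base.b * factors[2],
        r2=base.r2 * factors[3],
        c2=base.c2 * factors[4],
        k=base.k,
        c=base.c,
    )
    i0 = rng.uniform(*LEU_RANGE)
    l0 = rng.uniform(*CLEU_FRACTION) * i0
    horizon = float(rng.integers(HORIZON_RANGE[0], HORIZON_RANGE[1] + 1))
    return ScenarioConfig(
        stage=stage,
        params=params,
        initial_state=PopulationState(i=i0, l=l0),
        seed=seed,
        horizon=horizon,
    )


#: coalition groupings: fixture name -> (favourable count fields, unfavourable)
GROUPINGS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "leu_vs_hsc_cleu": (
        ("leu",),
        ("cd34_infused", "cd34_number", "cleu_major", "cleu_minor"),
    ),
    "hsc_leu_vs_cleu": (
        ("leu", "cd34_infused", "cd34_number"),
        ("cleu_major", "cleu_minor"),
    ),
}


def initial_frequency_state(counts: TransplantCounts, grouping: str) -> np.ndarray:
    """Initial (favourable, unfavourable) frequencies from transplant counts.

    The coalition membership follows the grouping named by the fixture:
    ``"hsc_leu_vs_cleu"`` pools the graft with healthy leukocytes,
    ``"leu_vs_hsc_cleu"`` pools it with the cancerous ones.  The NK count is
    kept out of both pools (stored verbatim, dimensionally implausible).
    """
    if grouping not in GROUPINGS:
        raise KeyError(f"unknown grouping {grouping!r}; expected one of {sorted(GROUPINGS)}")
    fav_fields, unfav_fields = GROUPINGS[grouping]
    fav = sum(getattr(counts, f) for f in fav_fields)
    unfav = sum(getattr(counts, f) for f in unfav_fields)
    total = fav + unfav
    if total <= 0:
        raise ValueError("all grouped counts are zero; frequencies undefined")
    return np.array([fav / total, unfav / total])
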