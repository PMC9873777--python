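"""Thermal-time phenology engine.

Development is driven by accumulated thermal time (deg C day) computed from
the daily mean temperature through a broken-linear response with cardinal
temperatures. Before anthesis the response rises from ``t_base`` to a peak
of ``t_opt - t_base`` at ``t_opt`` and declines to zero at ``t_max``; after
anthesis it plateaus at the optimum and does not decline at higher
temperature. The stage sequence is::

    presow -> sown -> emerged -> pi -> flag -> anthesis -> grainfill -> mature

Stage promotion carries surplus thermal time into the next stage so no
development is lost on transition days. The thermal-time target from
emergence to panicle initiation derives from leaf numbers: four leaf
initials are already present in the seed, and leaves are initiated at a rate
(LIR) of about half the appearance rate (LAR), so the target is
``(TLN - 4) * LIR``. The panicle-initiation-to-flag-leaf duration is not an
independent target: it emerges from leaf appearance as ``TLN * LAR`` minus
the emergence-to-PI target, which keeps the parameter set self-consistent.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .errors import InvalidGenotypeError, InvalidWeatherError
from .params import CardinalTemps, GenotypeParams, StageTargets

__all__ = [
    "Stage",
    "Phase",
    "PhenoState",
    "daily_thermal_time",
    "tt_emergence_to_pi",
    "tt_emergence_to_flag",
    "advance",
]

#: Number of leaf initials already present in the seed at emergence.
SEED_LEAF_INITIALS = 4


class Stage(enum.IntEnum):
    PRESOW = 0
    SOWN = 1
    EMERGED = 2
    PI = 3
    FLAG = 4
    ANTHESIS = 5
    GRAINFILL = 6
    MATURE = 7


class Phase(enum.Enum):
    PRE_ANTHESIS = "pre_anthesis"
    POST_ANTHESIS = "post_anthesis"


@dataclass(frozen=True)
class PhenoState:
    stage: Stage = Stage.PRESOW
    tt_in_stage: float = 0.0
    tt_since_emergence: float = 0.0
    days_after_sowing: int = 0


def daily_thermal_time(
    tmax: float,
    tmin: float,
    cardinals: CardinalTemps,
    phase: Phase = Phase.PRE_ANTHESIS,
) -> float:
    """Thermal time (deg C day) contributed by one day's temperatures.

    The daily mean ``(tmax + tmin) / 2`` drives a broken-linear response:
    zero at/below ``t_base``, rising to ``t_opt - t_base`` at ``t_opt``.
    Above the optimum the pre-anthesis response declines linearly to zero at
    ``t_max``, while the post-anthesis response stays at the plateau.
    """
    if tmax < tmin:
        raise InvalidWeatherError(f"tmax {tmax} below tmin {tmin}")
    t = (tmax + tmin) / 2.0
    tb, to = cardinals.t_base, cardinals.t_opt
    peak = to - tb
    if t <= tb:
        return 0.0
    if t <= to:
        return t - tb
    if phase is Phase.POST_ANTHESIS or cardinals.t_max is None:
        return peak
    tm = cardinals.t_max
    if t >= tm:
        return 0.0
    return peak * (tm - t) / (tm - to)


def tt_emergence_to_pi(tln: float, lir: float) -> float:
    """Thermal-time target from emergence to panicle initiation.

    ``(tln - 4) * lir``: the seed already carries four leaf initials, and
    initiation of the remaining leaves at LIR deg C day each spans the
    emergence-to-PI window.
    """
    if tln <= SEED_LEAF_INITIALS:
        raise InvalidGenotypeError(
            f"total leaf number must exceed the {SEED_LEAF_INITIALS} seed initials"
        )
    if lir <= 0:
        raise InvalidGenotypeError("lir must be positive")
    return (tln - SEED_LEAF_INITIALS) * lir


def tt_emergence_to_flag(tln: float, lar: float) -> float:
    """Thermal time from emergence to full flag-leaf expansion: tln * lar."""
    if tln <= 0 or lar <= 0:
        raise InvalidGenotypeError("tln and lar must be positive")
    return tln * lar


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (reporting rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _stage_target(stage: Stage, targets: StageTargets, genotype: GenotypeParams) -> float | None:
    """Thermal-time span of the current stage; None = event/absorbing stage."""
    if stage == Stage.SOWN:
        return targets.tt_sow_to_emerg
    if stage == Stage.EMERGED:
        return targets.tt_emerg_to_pi
    if stage == Stage.PI:
        # PI -> flag emerges from leaf appearance: total emergence->flag
        # thermal time is tln*lar, of which tt_emerg_to_pi is already spent.
        return tt_emergence_to_flag(genotype.tln, genotype.lar) - targets.tt_emerg_to_pi
    if stage == Stage.FLAG:
        return targets.tt_flag_to_anthesis
    if stage == Stage.ANTHESIS:
        return targets.tt_anthesis_to_startgf
    if stage == Stage.GRAINFILL:
        return targets.tt_anthesis_to_maturity - targets.tt_anthesis_to_startgf
    return None


def advance(
    state: PhenoState,
    d_tt_pre: float,
    d_tt_post: float,
    targets: StageTargets,
    genotype: GenotypeParams,
) -> PhenoState:
    """Advance phenology by one day, promoting stages with carry-over.

    ``d_tt_pre``/``d_tt_post`` are the day's thermal time under the
    pre-anthesis and post-anthesis cardinal temperatures; the accumulator
    uses whichever matches the current stage. Surplus thermal time beyond a
    stage target spills into the next stage within the same day.
    """
    if state.stage in (Stage.PRESOW, Stage.MATURE):
        return state

    stage = state.stage
    tt_in_stage = state.tt_in_stage
    tt_emerg = state.tt_since_emergence
    remaining = d_tt_pre if stage < Stage.ANTHESIS else d_tt_post

    while remaining > 0:
        target = _stage_target(stage, targets, genotype)
        if target is None:  # mature: absorb
            break
        room = target - tt_in_stage
        if remaining < room:
            tt_in_stage += remaining
            if stage >= Stage.EMERGED:
                tt_emerg += remaining
            remaining = 0.0
        else:
            if stage >= Stage.EMERGED:
                tt_emerg += room
            remaining -= room
            stage = Stage(stage + 1)
            tt_in_stage = 0.0
            if stage == Stage.ANTHESIS and remaining > 0:
                # Re-scale the surplus into post-anthesis units for the day.
                remaining = remaining * (d_tt_post / d_tt_pre) if d_tt_pre > 0 else d_tt_post
            if stage == Stage.MATURE:
                remaining = 0.0

    return PhenoState(
        stage=stage,
        tt_in_stage=tt_in_stage,
        tt_since_emergence=tt_emerg,
        days_after_sowing=state.days_after_sowing + 1,
    )
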