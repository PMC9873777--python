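"""Daily crop carbon economy.

Biomass accumulation follows the radiation-use-efficiency paradigm: the
canopy intercepts incident shortwave radiation by Beer's law, converts it to
dry mass at the cultivar's RUE, and is scaled down by the water
supply/demand ratio when the soil cannot meet transpiration demand.
Vegetative mass is split between leaf and stem with a leaf fraction that
declines with leaf number; grain number is set at the start of grain fill
from the mean plant growth rate over the panicle-initiation-to-grain-fill
window divided by the grain number factor (g of growth per grain); grain
filling draws on current growth first and then on a limited stem reserve,
capped by kernel number x maximum kernel mass (sink limitation). Leaf area
senesces with age after anthesis and additionally under water stress.

All pools are above-ground dry mass in g m^-2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .canopy import CanopyState
from .errors import StateError
from .params import GenotypeParams  # noqa: F401  (re-export: spec'd home)
from .phenology import Stage

__all__ = [
    "GenotypeParams",
    "BiomassPools",
    "GrainState",
    "light_interception",
    "daily_growth",
    "partition_vegetative",
    "set_grain_number",
    "grain_fill",
    "senesce",
]

#: Drought senescence keys off depletion of plant-available water in the
#: rooted zone, not the instantaneous supply/demand ratio (whose coupling to
#: canopy size would let a shrinking crop stabilise itself): once the rooted
#: zone falls below SENESCENCE_FASW_THRESHOLD of its capacity, green leaf
#: area dies at up to STRESS_SENESCENCE_RATE per day (reached when the
#: profile is empty). Moderate depletion slows expansion and growth but
#: does not destroy built canopy.
STRESS_SENESCENCE_RATE = 0.2
SENESCENCE_FASW_THRESHOLD = 0.25

#: Age senescence after anthesis: fraction of anthesis green LAI lost by
#: physiological maturity in an unstressed crop (15% gone by mid-fill).
AGE_SENESCENCE_TOTAL = 0.30


@dataclass
class BiomassPools:
    leaf: float = 0.0
    stem: float = 0.0
    grain: float = 0.0
    dead_leaf: float = 0.0

    @property
    def total(self) -> float:
        return self.leaf + self.stem + self.grain + self.dead_leaf

    @property
    def harvest_index(self) -> float:
        return self.grain / self.total if self.total > 0 else 0.0


@dataclass
class GrainState:
    number: float = 0.0  # grains m^-2
    mass: float = 0.0  # g m^-2 (mirrors pools.grain)
    number_set: bool = False
    # Accumulators for the mean plant growth rate over PI -> start grain fill
    pgr_growth_sum: float = 0.0  # g m^-2 growth summed over the window
    pgr_days: int = 0
    stem_at_anthesis: float = 0.0
    stem_translocated: float = 0.0


def light_interception(lai: float, k: float) -> float:
    """Beer's-law fraction of radiation intercepted: 1 - exp(-k * LAI)."""
    if lai < 0 or k < 0:
        raise StateError("lai and k must be non-negative")
    return 1.0 - math.exp(-k * lai)


def daily_growth(radn: float, f_int: float, rue: float, sd_ratio: float) -> float:
    """Biomass increment (g m^-2): radiation x interception x RUE x stress."""
    if min(radn, f_int, rue, sd_ratio) < 0 or max(f_int, sd_ratio) > 1:
        raise StateError("inputs out of range")
    return radn * f_int * rue * sd_ratio


def partition_vegetative(
    d_biomass: float, n_leaves: float, partition_k: float, after_flag: bool = False
) -> tuple[float, float]:
    """Split a day's vegetative growth into (leaf, stem).

    The leaf fraction ``f = 1 / (1 + partition_k * n_leaves**2)`` declines as
    the canopy builds; a larger partitioning factor (taller genotypes) sends
    more growth to stem. After flag leaf expansion everything goes to stem.
    """
    if d_biomass < 0:
        raise StateError("growth must be non-negative")
    if after_flag:
        return 0.0, d_biomass
    f = 1.0 / (1.0 + partition_k * n_leaves * n_leaves)
    return f * d_biomass, (1.0 - f) * d_biomass


def set_grain_number(
    grain: GrainState, mean_pgr: float, gnf: float, density: float
) -> float:
    """Fix grain number (grains m^-2) at the start of grain fill.

    ``mean_pgr`` is the mean plant growth rate (g plant^-1 day^-1) over the
    panicle-initiation-to-grain-fill window; dividing by the grain number
    factor (g per grain) gives grains per plant.
    """
    if grain.number_set:
        raise StateError("grain number already set this season")
    if mean_pgr < 0:
        raise StateError("mean plant growth rate must be non-negative")
    grain.number = mean_pgr / gnf * density
    grain.number_set = True
    return grain.number


def grain_fill(
    d_biomass: float,
    grain: GrainState,
    pools: BiomassPools,
    d_tt: float,
    fill_tt_total: float,
    max_kernel_wt: float,
    stem_transloc_frac: float,
) -> None:
    """Allocate one grain-fill day's growth between grain and stem.

    Grain demand for the day is ``number x max_kernel_wt x d_tt /
    fill_tt_total`` (never beyond the kernel-mass cap). Demand is met from
    the day's new growth first; any shortfall is translocated from stem up
    to a cumulative cap of ``stem_transloc_frac`` of the stem mass at
    anthesis; growth beyond demand accrues to stem.
    """
    if d_biomass < 0 or d_tt < 0:
        raise StateError("negative growth or thermal time")
    cap = grain.number * max_kernel_wt
    demand = min(grain.number * max_kernel_wt * d_tt / fill_tt_total, cap - pools.grain)
    demand = max(0.0, demand)
    from_growth = min(demand, d_biomass)
    shortfall = demand - from_growth
    transloc_room = max(0.0, stem_transloc_frac * grain.stem_at_anthesis - grain.stem_translocated)
    from_stem = min(shortfall, transloc_room, pools.stem)
    pools.grain += from_growth + from_stem
    pools.stem += (d_biomass - from_growth) - from_stem
    grain.stem_translocated += from_stem
    grain.mass = pools.grain


def senesce(
    pools: BiomassPools,
    canopy: CanopyState,
    water_status: float,
    stage: Stage,
    frac_fill_elapsed: float,
    peak_lai: float,
    stress_rate: float = STRESS_SENESCENCE_RATE,
) -> None:
    """Move leaf area (and proportional leaf mass) to the senesced pools.

    Age senescence holds green LAI to a linearly declining fraction of the
    anthesis peak once grain fill progresses (``frac_fill_elapsed`` in
    [0, 1]). ``water_status`` is the rooted zone's remaining fraction of
    plant-available water: below ``SENESCENCE_FASW_THRESHOLD`` drought
    senescence removes up to ``stress_rate`` of the current green LAI per
    day, scaled by how deep the depletion runs; milder depletion senesces
    nothing. Above-ground mass is conserved: leaf mass lost moves to dead
    leaf.
    """
    if not (0 <= water_status <= 1):
        raise StateError("water_status must lie in [0, 1]")
    green0 = canopy.lai_green
    if green0 <= 0:
        return
    loss = 0.0
    if stage >= Stage.ANTHESIS and peak_lai > 0:
        target = peak_lai * (1.0 - AGE_SENESCENCE_TOTAL * min(1.0, frac_fill_elapsed))
        loss += max(0.0, green0 - target)
    severity = max(0.0, 1.0 - water_status / SENESCENCE_FASW_THRESHOLD)
    loss += stress_rate * severity * green0
    loss = min(loss, green0)
    if loss <= 0:
        return
    frac = loss / green0
    d_mass = pools.leaf * frac
    pools.leaf -= d_mass
    pools.dead_leaf += d_mass
    canopy.lai_green -= loss
    canopy.lai_senesced += loss
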