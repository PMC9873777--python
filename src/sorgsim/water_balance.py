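"""Daily layered soil-water accounting.

A cascading-bucket water balance in the APSIM tradition: curve-number
runoff partitioning of rain, top-down infiltration, fractional drainage of
water above the drained upper limit, two-stage (energy- then
supply-limited) soil evaporation from the surface layer, root-zone water
supply via per-layer extraction coefficients, and a supply/demand stress
ratio that couples the water budget to crop growth through transpiration
efficiency and vapour pressure deficit.

All water quantities are mm; layer water contents are volumetric fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidWeatherError, StateError
from .soil import SoilProfile

__all__ = [
    "WaterConfig",
    "WaterState",
    "RootZone",
    "partition_rain",
    "drain",
    "soil_evaporation",
    "vpd_estimate",
    "supply_and_demand",
    "extract_transpiration",
]


@dataclass(frozen=True)
class WaterConfig:
    """Tunable water-balance constants (defaults are field-typical)."""

    cn: float = 80.0  # USDA runoff curve number
    swcon: float = 0.3  # daily drainage fraction of water above dul
    u_evap: float = 6.0  # stage-1 soil evaporation limit, mm
    alpha_evap: float = 3.5  # stage-2 coefficient, mm day^-0.5
    te_coeff_pa: float = 9.0  # transpiration efficiency coefficient, Pa
    root_advance_cm_per_cd: float = 0.1
    vpd_floor_kpa: float = 0.1


@dataclass
class WaterState:
    """Cumulative water-budget terms and the evaporation stage trackers."""

    cum_runoff: float = 0.0
    cum_drainage: float = 0.0
    cum_soil_evap: float = 0.0
    cum_transpiration: float = 0.0
    cum_infiltration: float = 0.0
    cum_irrigation: float = 0.0
    es_since_wetting: float = 0.0  # mm evaporated since last significant wetting
    t_stage2: float = 0.0  # days into stage-2 drying


@dataclass
class RootZone:
    depth: float = 0.0  # cm
    advance_rate: float = 0.1  # cm per deg C day

    def advance(self, d_tt: float, max_depth: float) -> None:
        self.depth = min(max_depth, self.depth + self.advance_rate * d_tt)


def stored_water_mm(profile: SoilProfile) -> float:
    """Total water stored in the profile, mm (absolute, not above cll)."""
    return sum(l.sw * l.thickness_mm for l in profile.layers)


def partition_rain(
    rain: float, state: WaterState, profile: SoilProfile, cfg: WaterConfig = WaterConfig()
) -> tuple[float, float]:
    """Split rain into runoff and infiltration; fill layers top-down.

    Runoff follows the USDA curve-number relation with retention
    S = 25400/CN - 254 (mm) and initial abstraction 0.2 S. Infiltration
    fills each layer to saturation before spilling to the next; water that
    passes the bottom layer counts as drainage out of the profile.
    """
    if rain < 0:
        raise InvalidWeatherError("rain must be non-negative")
    if rain == 0:
        return 0.0, 0.0
    s = 25400.0 / cfg.cn - 254.0
    ia = 0.2 * s
    runoff = (rain - ia) ** 2 / (rain + 0.8 * s) if rain > ia else 0.0
    infil = rain - runoff
    remaining = infil
    for l in profile.layers:
        room = (l.saturation - l.sw) * l.thickness_mm
        added = min(remaining, max(0.0, room))
        l.sw += added / l.thickness_mm
        remaining -= added
        if remaining <= 0:
            break
    if remaining > 0:  # spilled below the profile
        state.cum_drainage += remaining
    state.cum_runoff += runoff
    state.cum_infiltration += infil
    # Wetting resets the surface-drying clock in proportion to the water added.
    state.es_since_wetting = max(0.0, state.es_since_wetting - infil)
    if state.es_since_wetting < cfg.u_evap:
        state.t_stage2 = 0.0
    return runoff, infil


def drain(
    state: WaterState, profile: SoilProfile, swcon: float = 0.3
) -> float:
    """Cascade water above the drained upper limit downward; return mm lost.

    Each layer sheds ``swcon`` of its water above dul per day into the layer
    below; the bottom layer drains out of the profile.
    """
    if not (0 <= swcon <= 1):
        raise StateError("swcon must lie in [0, 1]")
    carried = 0.0
    n = len(profile.layers)
    for i, l in enumerate(profile.layers):
        # Water arriving from above first tops the layer up toward saturation.
        if carried > 0:
            room = (l.saturation - l.sw) * l.thickness_mm
            added = min(carried, max(0.0, room))
            l.sw += added / l.thickness_mm
            carried -= added
        excess = max(0.0, l.sw - l.dul) * l.thickness_mm
        flux = swcon * excess
        l.sw -= flux / l.thickness_mm
        carried += flux
        if i == n - 1:
            break
    state.cum_drainage += carried
    return carried


def vpd_estimate(tmax: float, tmin: float) -> float:
    """Daytime vapour pressure deficit (kPa) from the daily extremes.

    Uses the standard convention of 75% of the saturation vapour pressure
    difference between the daily maximum and minimum temperatures.
    """
    if tmax < tmin:
        raise InvalidWeatherError("tmax below tmin")

    def svp(t: float) -> float:
        return 0.6106 * math.exp(17.27 * t / (t + 237.3))

    return 0.75 * (svp(tmax) - svp(tmin))


def _reference_evap(radn: float, tmax: float, tmin: float) -> float:
    """Hargreaves-form reference evaporative demand proxy, mm."""
    tmean = (tmax + tmin) / 2.0
    return 0.0023 * radn * (tmean + 17.8) * math.sqrt(max(0.0, tmax - tmin))


def soil_evaporation(
    state: WaterState,
    profile: SoilProfile,
    radn: float,
    tmax: float,
    tmin: float,
    cover: float,
    cfg: WaterConfig = WaterConfig(),
) -> float:
    """Two-stage soil evaporation from the top layer, mm removed today.

    Potential rate is 0.75 x a Hargreaves-form reference demand, reduced by
    canopy cover. Stage 1 (until ``u_evap`` mm has evaporated since the last
    wetting) proceeds at the potential rate; stage 2 declines with the
    square root of time. Extraction is floored at the top layer's air-dry
    content.
    """
    if not (0 <= cover <= 1):
        raise StateError("cover must lie in [0, 1]")
    top = profile.layers[0]
    potential = 0.75 * _reference_evap(radn, tmax, tmin) * (1.0 - cover)
    if state.es_since_wetting < cfg.u_evap:
        es = min(potential, cfg.u_evap - state.es_since_wetting)
    else:
        t = state.t_stage2
        es = min(potential, cfg.alpha_evap * (math.sqrt(t + 1.0) - math.sqrt(t)))
        state.t_stage2 += 1.0
    extractable = max(0.0, (top.sw - top.air_dry) * top.thickness_mm)
    es = min(es, extractable)
    top.sw -= es / top.thickness_mm
    state.cum_soil_evap += es
    state.es_since_wetting += es
    return es


def _rooted_fraction(layer_top: float, layer_bottom: float, root_depth: float) -> float:
    """Fraction of a layer's thickness the roots have penetrated."""
    if root_depth <= layer_top:
        return 0.0
    return min(1.0, (root_depth - layer_top) / (layer_bottom - layer_top))


def supply_and_demand(
    profile: SoilProfile,
    roots: RootZone,
    potential_growth: float,
    vpd: float,
    cfg: WaterConfig = WaterConfig(),
) -> tuple[float, float, float]:
    """Water supply, transpiration demand and their ratio for today.

    Supply sums ``kl * (sw - cll) * thickness`` over rooted layers (the
    bottom rooted layer pro-rated by penetration). Demand converts the
    potential (radiation-limited) growth to water through transpiration
    efficiency TE = te_coeff / vpd (g biomass per m^2 per mm, with te_coeff
    in Pa and vpd in kPa). The stress ratio is min(1, supply/demand), and 1
    when there is no demand.
    """
    if potential_growth < 0:
        raise StateError("potential growth must be non-negative")
    vpd = max(vpd, cfg.vpd_floor_kpa)
    supply = 0.0
    for l in profile.layers:
        f = _rooted_fraction(l.top_depth, l.bottom_depth, roots.depth)
        if f > 0:
            supply += l.kl * max(0.0, l.sw - l.cll) * l.thickness_mm * f
    te = cfg.te_coeff_pa / vpd  # g biomass m^-2 per mm transpired
    demand = potential_growth / te if potential_growth > 0 else 0.0
    sd_ratio = 1.0 if demand == 0 else min(1.0, supply / demand)
    return supply, demand, sd_ratio


def fraction_available_sw(profile: SoilProfile, roots: RootZone | None = None) -> float:
    """Fraction of plant-available water capacity still stored (1 = full,
    0 = at the crop lower limit throughout).

    With ``roots`` given, only the rooted zone counts (bottom layer
    pro-rated); otherwise the whole profile. The whole-profile form is the
    drought-senescence signal: a young crop with a shallow root front is not
    condemned by a dry topsoil while the subsoil reserve it is growing into
    still holds water.
    """
    stored = 0.0
    capacity = 0.0
    for l in profile.layers:
        f = 1.0 if roots is None else _rooted_fraction(l.top_depth, l.bottom_depth, roots.depth)
        if f > 0:
            stored += max(0.0, l.sw - l.cll) * l.thickness_mm * f
            capacity += (l.dul - l.cll) * l.thickness_mm * f
    # sw may sit above dul transiently after rain; cap at a full profile.
    return min(1.0, stored / capacity) if capacity > 0 else 0.0


def extract_transpiration(
    state: WaterState,
    profile: SoilProfile,
    roots: RootZone,
    amount: float,
) -> list[float]:
    """Remove ``amount`` mm from rooted layers proportionally to kl-weighted
    availability; returns per-layer extraction. Never takes a layer below
    its crop lower limit."""
    if amount < 0:
        raise StateError("extraction amount must be non-negative")
    weights = []
    for l in profile.layers:
        f = _rooted_fraction(l.top_depth, l.bottom_depth, roots.depth)
        weights.append(l.kl * max(0.0, l.sw - l.cll) * l.thickness_mm * f)
    total = sum(weights)
    if amount > total + 1e-9:
        raise StateError(f"requested {amount:.3f} mm exceeds supply {total:.3f} mm")
    taken = []
    for l, w in zip(profile.layers, weights):
        share = amount * w / total if total > 0 else 0.0
        share = min(share, max(0.0, (l.sw - l.cll) * l.thickness_mm))
        l.sw -= share / l.thickness_mm
        taken.append(share)
    # Proportional shares cannot overdraw a layer, so the residual is purely
    # floating-point; fold it into the deepest contributing layer.
    resid = amount - sum(taken)
    if abs(resid) > 1e-12:
        for i in range(len(taken) - 1, -1, -1):
            if weights[i] > 0:
                profile.layers[i].sw -= resid / profile.layers[i].thickness_mm
                taken[i] += resid
                break
    state.cum_transpiration += amount
    return taken
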