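"""Field soil characterization and layered plant-available-water arithmetic.

Implements the standard protocol used to parameterize a crop model's water
bucket from soil cores: gravimetric water content of wet/dry core samples,
bulk density from core volume, conversion to volumetric water content, and
the per-layer / whole-profile plant-available-water capacity (PAWC) sums.

Units follow field convention: layer depths in cm, volumetric water content
as a fraction (mm water per mm soil), stored water in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path


import pandas as pd

from .errors import InputError, InvalidSampleError

__all__ = [
    "SoilSample",
    "SoilLayer",
    "SoilProfile",
    "gravimetric_water_pct",
    "bulk_density",
    "volumetric_pct",
    "layer_paw",
    "profile_pawc",
    "profile_available_sw",
    "read_profile",
    "write_profile",
    "load_fixture",
    "generic_profile",
]

#: Plausible dry-soil bulk density range (g cm^-3); outside -> warning only.
_BD_PLAUSIBLE = (0.7, 1.9)

#: sw clamp bounds relative to cll/dul (air-dry = 0.5*cll, sat = dul + 0.05).
AIR_DRY_FRAC = 0.5
SAT_ABOVE_DUL = 0.05


@dataclass(frozen=True)
class SoilSample:
    """One soil core: wet and oven-dry mass (g) and core volume (cm^3)."""

    wet_weight: float
    dry_weight: float
    core_volume: float

    def __post_init__(self) -> None:
        if self.dry_weight <= 0:
            raise InvalidSampleError("dry weight must be positive")
        if self.wet_weight < self.dry_weight:
            raise InvalidSampleError("wet weight cannot be below dry weight")
        if self.core_volume <= 0:
            raise InvalidSampleError("core volume must be positive")


@dataclass
class SoilLayer:
    """One horizontal soil layer with its water-holding characteristics.

    dul/cll/sw are volumetric fractions; kl is the daily fraction of the
    water between sw and cll that roots can extract (APSIM convention).
    """

    top_depth: float  # cm
    bottom_depth: float  # cm
    bulk_density: float  # g cm^-3
    dul: float
    cll: float
    sw: float = 0.0
    kl: float = 0.05

    def __post_init__(self) -> None:
        if self.bottom_depth <= self.top_depth:
            raise InputError("layer bottom_depth must exceed top_depth")
        if not (0 <= self.cll <= self.dul < 1):
            raise InputError("require 0 <= cll <= dul < 1")
        if not (0 < self.kl <= 0.12):
            raise InputError("kl must lie in (0, 0.12]")
        # sw may legitimately start below cll (air-dry) or slightly above dul
        # after rain; clamp to the physical band rather than reject.
        self.sw = min(max(self.sw, self.air_dry), self.saturation)

    @property
    def thickness_mm(self) -> float:
        return (self.bottom_depth - self.top_depth) * 10.0

    @property
    def air_dry(self) -> float:
        return AIR_DRY_FRAC * self.cll

    @property
    def saturation(self) -> float:
        return self.dul + SAT_ABOVE_DUL


@dataclass
class SoilProfile:
    """Ordered, contiguous stack of layers starting at the surface."""

    layers: list[SoilLayer]
    site_name: str = ""

    def __post_init__(self) -> None:
        if not self.layers:
            raise InputError("profile needs at least one layer")
        if abs(self.layers[0].top_depth) > 1e-9:
            raise InputError("first layer must start at depth 0")
        for upper, lower in zip(self.layers, self.layers[1:]):
            if abs(lower.top_depth - upper.bottom_depth) > 1e-9:
                raise InputError("layers must be contiguous")

    @property
    def depth_cm(self) -> float:
        return self.layers[-1].bottom_depth

    def copy(self) -> "SoilProfile":
        return SoilProfile([replace(l) for l in self.layers], self.site_name)

    def set_sw_fraction(self, frac: float) -> None:
        """Set every layer's water to cll + frac * (dul - cll)."""
        for l in self.layers:
            l.sw = l.cll + frac * (l.dul - l.cll)


def gravimetric_water_pct(wet_weight: float, dry_weight: float) -> float:
    """Gravimetric water % = ((wet wt - dry wt) / dry wt) * 100."""
    if dry_weight <= 0:
        raise InvalidSampleError("dry weight must be positive")
    if wet_weight < dry_weight:
        raise InvalidSampleError("wet weight cannot be below dry weight")
    return (wet_weight - dry_weight) / dry_weight * 100.0


def bulk_density(dry_weight: float, core_volume: float) -> float:
    """Bulk density (g cm^-3) = dry soil weight / total core volume.

    Emits a warning (not an error) outside the plausible field range.
    """
    if core_volume <= 0 or dry_weight <= 0:
        raise InvalidSampleError("dry weight and core volume must be positive")
    bd = dry_weight / core_volume
    lo, hi = _BD_PLAUSIBLE
    if not (lo <= bd <= hi):
        warnings.warn(
            f"bulk density {bd:.2f} g/cm3 outside plausible range [{lo}, {hi}]",
            stacklevel=2,
        )
    return bd


def volumetric_pct(gravimetric_pct: float, bd: float) -> float:
    """Volumetric water % = gravimetric water % x bulk density.

    Used identically for the drained upper limit and the crop lower limit.
    """
    if gravimetric_pct < 0 or bd < 0:
        raise InvalidSampleError("inputs must be non-negative")
    return gravimetric_pct * bd


def layer_paw(layer: SoilLayer) -> float:
    """Potential plant-available water of one layer, mm: (dul-cll)*thickness."""
    return (layer.dul - layer.cll) * layer.thickness_mm


def profile_pawc(profile: SoilProfile) -> float:
    """Plant-available water capacity of the whole profile (mm)."""
    return sum(layer_paw(l) for l in profile.layers)


def profile_available_sw(profile: SoilProfile) -> float:
    """Currently stored water above the crop lower limit (mm)."""
    return sum(max(0.0, l.sw - l.cll) * l.thickness_mm for l in profile.layers)


# ---------------------------------------------------------------------------
# I/O and bundled fixtures

_CSV_COLS = ["top_cm", "bottom_cm", "bd", "dul", "cll", "sw", "kl"]


def read_profile(path: str | Path, site_name: str | None = None) -> SoilProfile:
    """Read a profile CSV with header top_cm,bottom_cm,bd,dul,cll,sw,kl."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLS if c not in df.columns]
    if missing:
        raise InputError(f"profile file missing columns: {missing}")
    layers = [
        SoilLayer(
            top_depth=r.top_cm,
            bottom_depth=r.bottom_cm,
            bulk_density=r.bd,
            dul=r.dul,
            cll=r.cll,
            sw=r.sw,
            kl=r.kl,
        )
        for r in df.itertuples()
    ]
    return SoilProfile(layers, site_name or Path(path).stem)


def write_profile(profile: SoilProfile, path: str | Path) -> None:
    rows = [
        {
            "top_cm": l.top_depth,
            "bottom_cm": l.bottom_depth,
            "bd": l.bulk_density,
            "dul": l.dul,
            "cll": l.cll,
            "sw": l.sw,
            "kl": l.kl,
        }
        for l in profile.layers
    ]
    pd.DataFrame(rows, columns=_CSV_COLS).to_csv(path, index=False)


def load_fixture(name: str) -> SoilProfile:
    """Load a bundled measured profile: ``melkassa`` or ``miesso``."""
    if name not in ("melkassa", "miesso"):
        raise InputError(f"unknown soil fixture {name!r}")
    ref = resources.files("sorgsim.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as p:
        return read_profile(p, site_name=name)


def default_kl(n_layers: int) -> list[float]:
    """Standard declining extraction profile: 0.08 top, -0.01/layer, floor 0.02."""
    return [max(0.02, 0.08 - 0.01 * i) for i in range(n_layers)]


def generic_profile(
    depth_cm: float,
    pawc_mm: float,
    *,
    dul: float = 0.35,
    n_layers: int = 5,
    bd: float = 1.2,
    site_name: str = "generic",
) -> SoilProfile:
    """Build an idealized uniform profile from a depth + PAWC summary.

    Used for long-term simulation sites characterized only by soil depth and
    plant-available water capacity; cll is back-computed so that the profile
    PAWC equals ``pawc_mm``.
    """
    if depth_cm <= 0 or pawc_mm <= 0:
        raise InputError("depth and PAWC must be positive")
    delta = pawc_mm / (depth_cm * 10.0)  # dul - cll, uniform
    if delta >= dul:
        raise InputError("requested PAWC exceeds what dul allows")
    kls = default_kl(n_layers)
    edges = [depth_cm * i / n_layers for i in range(n_layers + 1)]
    layers = [
        SoilLayer(
            top_depth=edges[i],
            bottom_depth=edges[i + 1],
            bulk_density=bd,
            dul=dul,
            cll=dul - delta,
            sw=dul - delta,
            kl=kls[i],
        )
        for i in range(n_layers)
    ]
    return SoilProfile(layers, site_name)


def characterization_table(profile: SoilProfile) -> pd.DataFrame:
    """Per-layer PAW/ASW summary plus profile totals, as printed by the CLI."""
    rows = []
    for l in profile.layers:
        rows.append(
            {
                "top_cm": l.top_depth,
                "bottom_cm": l.bottom_depth,
                "bd": l.bulk_density,
                "dul": l.dul,
                "cll": l.cll,
                "sw": l.sw,
                "paw_mm": layer_paw(l),
                "asw_mm": max(0.0, l.sw - l.cll) * l.thickness_mm,
            }
        )
    return pd.DataFrame(rows)
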