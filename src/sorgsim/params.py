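"""Genotype parameter sets.

Holds every cultivar-specific coefficient the simulator needs: cardinal
temperatures for the two developmental phases, accumulated thermal-time
targets, leaf appearance/initiation rates and total leaf number, the
individual-leaf-size regressions on total leaf number, and the growth
coefficients (leaf-stem partitioning, grain number factor, radiation use
efficiency). Bundled presets parameterize Meko (early, short improved
variety) and Jigurti (late, tall landrace).
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

from .errors import InvalidGenotypeError

__all__ = ["CardinalTemps", "StageTargets", "GenotypeParams", "load_genotype", "meko", "jigurti"]


@dataclass(frozen=True)
class CardinalTemps:
    """Base/optimum/maximum temperatures of a broken-linear development response.

    ``t_max`` is None for the post-anthesis phase, whose response plateaus at
    the optimum instead of declining at higher temperature.
    """

    t_base: float
    t_opt: float
    t_max: float | None = None

    def __post_init__(self) -> None:
        if self.t_base >= self.t_opt:
            raise InvalidGenotypeError("t_base must be below t_opt")
        if self.t_max is not None and self.t_opt >= self.t_max:
            raise InvalidGenotypeError("t_opt must be below t_max")


@dataclass(frozen=True)
class StageTargets:
    """Accumulated thermal-time targets (deg C day) between stages."""

    tt_emerg_to_pi: float
    tt_flag_to_anthesis: float
    tt_anthesis_to_maturity: float
    tt_sow_to_emerg: float = 40.0
    tt_anthesis_to_startgf: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "tt_emerg_to_pi",
            "tt_flag_to_anthesis",
            "tt_anthesis_to_maturity",
            "tt_sow_to_emerg",
            "tt_anthesis_to_startgf",
        ):
            if getattr(self, name) <= 0:
                raise InvalidGenotypeError(f"{name} must be positive")
        if self.tt_anthesis_to_startgf >= self.tt_anthesis_to_maturity:
            raise InvalidGenotypeError(
                "grain fill must start before physiological maturity"
            )


@dataclass(frozen=True)
class GenotypeParams:
    """All cultivar coefficients for phenology, canopy and growth."""

    name: str
    cardinals_veg: CardinalTemps
    cardinals_gf: CardinalTemps
    targets: StageTargets
    lar: float  # leaf appearance rate, deg C day / leaf
    lir: float  # leaf initiation rate, deg C day / leaf
    tln: float  # total leaf number driving phenology
    tln_canopy: int  # leaf number used for the leaf-size profile
    x0_slope: float
    x0_intercept: float
    y0_slope: float
    y0_intercept: float
    partition_k: float
    grain_number_factor: float
    rue: float
    extinction_k: float = 0.4
    max_kernel_wt: float = 0.028
    stem_transloc_frac: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "lar",
            "lir",
            "tln",
            "partition_k",
            "grain_number_factor",
            "rue",
            "extinction_k",
            "max_kernel_wt",
            "stem_transloc_frac",
        ):
            if getattr(self, name) <= 0:
                raise InvalidGenotypeError(f"{name} must be positive")
        # Leaf initiation runs at about half the appearance rate; a large
        # departure usually means a transcription mistake, but is legal.
        if abs(self.lir - self.lar / 2) > 0.15 * (self.lar / 2):
            warnings.warn(
                f"{self.name}: lir={self.lir} deviates >15% from lar/2={self.lar / 2}",
                stacklevel=2,
            )

    def with_overrides(self, **kwargs) -> "GenotypeParams":
        return replace(self, **kwargs)


def _from_dict(d: dict) -> GenotypeParams:
    return GenotypeParams(
        name=d["name"],
        cardinals_veg=CardinalTemps(d["t_base_veg"], d["t_opt_veg"], d["t_max_veg"]),
        cardinals_gf=CardinalTemps(d["t_base_gf"], d["t_opt_gf"], None),
        targets=StageTargets(
            tt_emerg_to_pi=d["tt_emerg_to_pi"],
            tt_flag_to_anthesis=d["tt_flag_to_anthesis"],
            tt_anthesis_to_maturity=d["tt_anthesis_to_maturity"],
            tt_sow_to_emerg=d.get("tt_sow_to_emerg", 40.0),
            tt_anthesis_to_startgf=d.get("tt_anthesis_to_startgf", 100.0),
        ),
        lar=d["lar"],
        lir=d["lir"],
        tln=d["tln"],
        tln_canopy=int(d.get("tln_canopy", round(d["tln"]))),
        x0_slope=d["x0_slope"],
        x0_intercept=d.get("x0_intercept", 0.0),
        y0_slope=d["y0_slope"],
        y0_intercept=d.get("y0_intercept", 0.0),
        partition_k=d["partition_k"],
        grain_number_factor=d["grain_number_factor"],
        rue=d["rue"],
        extinction_k=d.get("extinction_k", 0.4),
        max_kernel_wt=d.get("max_kernel_wt", 0.028),
        stem_transloc_frac=d.get("stem_transloc_frac", 0.2),
    )


def load_genotype(source: str | Path) -> GenotypeParams:
    """Load a genotype parameter file (TOML) or a bundled preset name."""
    if isinstance(source, str) and source.lower() in ("meko", "jigurti"):
        ref = resources.files("sorgsim.data").joinpath(f"{source.lower()}.toml")
        with resources.as_file(ref) as p:
            source = p
    with open(source, "rb") as fh:
        return _from_dict(tomllib.load(fh))


def meko() -> GenotypeParams:
    return load_genotype("meko")


def jigurti() -> GenotypeParams:
    return load_genotype("jigurti")
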