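"""Individual-leaf-size parameterization and daily canopy leaf-area dynamics.

The area of the leaf at position ``x`` on the culm follows a bell-shaped
profile::

    Y(x) = Y0 * exp(a * (x - X0)**2 + b * (x - X0)**3)

where ``Y0`` is the area of the largest leaf, ``X0`` its position, and
``a``/``b`` control breadth and skewness. ``X0`` and ``Y0`` are linear in
total leaf number (TLN), fitted per cultivar across plants; ``a`` and ``b``
are taken from an established maize leaf-profile study as TLN-dependent
constants rather than refitted from sparse data:

    a(TLN) = -0.0344 - 0.000186 * TLN
    b(TLN) =  0.00175 - 0.0000449 * TLN

Leaf blade area from field length x width measurements uses shape correction
factors of 0.635 for flag leaves and 0.71 for all other leaves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, InputError
from .params import GenotypeParams

__all__ = [
    "LeafSizeProfile",
    "ProfileRegression",
    "CanopyState",
    "blade_area",
    "leaf_area_at",
    "profile_from_tln",
    "profile_for_genotype",
    "fit_profile_regressions",
    "update_canopy",
    "default_a",
    "default_b",
]

FLAG_LEAF_FACTOR = 0.635
OTHER_LEAF_FACTOR = 0.71


def default_a(tln: float) -> float:
    """Breadth coefficient of the bell curve as a function of leaf number."""
    return -0.0344 - 0.000186 * tln


def default_b(tln: float) -> float:
    """Skewness coefficient of the bell curve as a function of leaf number."""
    return 0.00175 - 0.0000449 * tln


@dataclass(frozen=True)
class LeafSizeProfile:
    """Bell-curve description of fully expanded leaf area vs leaf position."""

    y0: float  # cm^2, area of the largest leaf
    x0: float  # leaf position of the largest leaf (may be fractional)
    a: float
    b: float
    tln: float

    def __post_init__(self) -> None:
        if self.y0 <= 0:
            raise InputError("y0 must be positive")
        if not (0 < self.x0 < self.tln + 1):
            raise InputError("x0 must lie within the leaf range")
        if self.a >= 0:
            raise InputError("a must be negative (bell opens downward)")

    @property
    def largest_leaf(self) -> int:
        """Largest-leaf position reported to users (round half-up)."""
        return int(math.floor(self.x0 + 0.5))

    def total_area(self) -> float:
        """Sum of all fully expanded leaf areas, cm^2 per plant."""
        return sum(leaf_area_at(x, self) for x in range(1, int(round(self.tln)) + 1))


@dataclass(frozen=True)
class ProfileRegression:
    """Linear regressions of X0 and Y0 on total leaf number."""

    x0_slope: float
    x0_intercept: float = 0.0
    y0_slope: float = 0.0
    y0_intercept: float = 0.0
    x0_r2: float | None = None
    y0_r2: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.x0_slope <= 1):
            raise InputError("x0_slope must lie in (0, 1]")


@dataclass
class CanopyState:
    appeared_leaves: float = 0.0
    expanded_leaves: int = 0
    lai_green: float = 0.0
    lai_senesced: float = 0.0


def blade_area(length: float, width: float, is_flag: bool = False) -> float:
    """Leaf blade area (cm^2) from length x width with a shape factor."""
    if length <= 0 or width <= 0:
        raise InputError("length and width must be positive")
    return length * width * (FLAG_LEAF_FACTOR if is_flag else OTHER_LEAF_FACTOR)


def leaf_area_at(x: float, profile: LeafSizeProfile) -> float:
    """Fully expanded area (cm^2) of the leaf at position ``x``."""
    if not (1 <= x <= profile.tln):
        raise InputError(f"leaf position {x} outside [1, {profile.tln}]")
    d = x - profile.x0
    return profile.y0 * math.exp(profile.a * d * d + profile.b * d * d * d)


def profile_from_tln(
    tln: float,
    reg: ProfileRegression,
    a: float | None = None,
    b: float | None = None,
) -> LeafSizeProfile:
    """Build a leaf-size profile for a plant with ``tln`` leaves."""
    if tln <= 4:
        raise InputError("tln must exceed the 4 seed leaf initials")
    x0 = reg.x0_slope * tln + reg.x0_intercept
    y0 = reg.y0_slope * tln + reg.y0_intercept
    if y0 <= 0:
        raise FitError(f"regression gives non-positive largest-leaf area ({y0:.1f})")
    return LeafSizeProfile(
        y0=y0,
        x0=x0,
        a=default_a(tln) if a is None else a,
        b=default_b(tln) if b is None else b,
        tln=tln,
    )


def profile_for_genotype(genotype: GenotypeParams) -> LeafSizeProfile:
    """Leaf-size profile implied by a genotype's bundled regressions."""
    reg = ProfileRegression(
        x0_slope=genotype.x0_slope,
        x0_intercept=genotype.x0_intercept,
        y0_slope=genotype.y0_slope,
        y0_intercept=genotype.y0_intercept,
    )
    return profile_from_tln(genotype.tln_canopy, reg)


def _fit_plant(
    tln: float, areas: dict[int, float], a: float, b: float
) -> tuple[float, float]:
    """Nonlinear least squares for one plant: only y0 and x0 free."""
    if len(areas) < 5:
        raise FitError("need at least 5 measured leaves per plant")
    xs = np.array(sorted(areas), dtype=float)
    ys = np.array([areas[int(i)] for i in xs])

    def bell(x, y0, x0):
        d = x - x0
        return y0 * np.exp(a * d**2 + b * d**3)

    p0 = (float(ys.max()), float(xs[np.argmax(ys)]))
    popt, _ = curve_fit(bell, xs, ys, p0=p0, maxfev=10_000)
    return float(popt[0]), float(popt[1])


def _ols_1d(x: np.ndarray, y: np.ndarray, through_origin: bool) -> tuple[float, float, float]:
    """Simple OLS slope/intercept/R^2, optionally constrained through zero."""
    if np.allclose(x, x[0]):
        raise FitError("singular design: all plants share the same total leaf number")
    if through_origin:
        slope = float(x @ y / (x @ x))
        intercept = 0.0
    else:
        slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
    resid = y - (slope * x + intercept)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 1.0
    return slope, intercept, r2


def fit_profile_regressions(
    plants: list[tuple[float, dict[int, float]]],
    a: float | None = None,
    b: float | None = None,
    x0_through_origin: bool = True,
) -> tuple[ProfileRegression, pd.DataFrame]:
    """Fit per-plant bell curves, then regress X0 and Y0 on total leaf number.

    ``plants`` is a list of ``(tln, {leaf_position: area_cm2})``. The bell
    breadth/skew coefficients are held fixed (supplied or the TLN-dependent
    defaults); only ``y0`` and ``x0`` are free per plant. Returns the fitted
    regression (with R^2 values) and a per-plant table of (tln, x0, y0, a, b).
    """
    if len(plants) < 2:
        raise FitError("need at least two plants to regress on leaf number")
    rows = []
    for tln, areas in plants:
        a_i = default_a(tln) if a is None else a
        b_i = default_b(tln) if b is None else b
        y0, x0 = _fit_plant(tln, areas, a_i, b_i)
        rows.append({"tln": tln, "x0": x0, "y0": y0, "a": a_i, "b": b_i})
    table = pd.DataFrame(rows)
    tlns = table["tln"].to_numpy(dtype=float)
    x0_slope, x0_int, x0_r2 = _ols_1d(tlns, table["x0"].to_numpy(), x0_through_origin)
    y0_slope, y0_int, y0_r2 = _ols_1d(tlns, table["y0"].to_numpy(), False)
    reg = ProfileRegression(
        x0_slope=x0_slope,
        x0_intercept=x0_int,
        y0_slope=y0_slope,
        y0_intercept=y0_int,
        x0_r2=x0_r2,
        y0_r2=y0_r2,
    )
    return reg, table


def update_canopy(
    state: CanopyState,
    d_tt: float,
    genotype: GenotypeParams,
    density: float,
    stress: float = 1.0,
    profile: LeafSizeProfile | None = None,
    after_anthesis: bool = False,
) -> CanopyState:
    """Advance leaf appearance and green leaf-area index by one day.

    Leaves appear at one per LAR deg C day up to the total leaf number. Each
    leaf contributes its profile area as it appears (pro-rated across days),
    converted to LAI with plant density (cm^2 -> m^2 = 1e-4) and scaled by
    the expansion stress multiplier (the water supply/demand ratio): under
    stress leaves expand less and the forgone area is never recovered.
    """
    if not (0 <= stress <= 1):
        raise InputError("stress must lie in [0, 1]")
    if profile is None:
        profile = profile_for_genotype(genotype)
    tln = profile.tln
    a0 = state.appeared_leaves
    if after_anthesis:
        a1 = a0
    else:
        a1 = min(tln, a0 + d_tt / genotype.lar)
    gain_cm2 = 0.0
    # Leaf i occupies the appearance interval (i-1, i]; add the overlapped
    # fraction of each leaf's full area.
    for i in range(int(math.floor(a0)) + 1, int(math.ceil(a1)) + 1):
        if i > int(round(tln)):
            break
        frac = min(a1, i) - max(a0, i - 1)
        if frac > 0:
            gain_cm2 += leaf_area_at(min(i, tln), profile) * frac
    return CanopyState(
        appeared_leaves=a1,
        expanded_leaves=int(math.floor(a1)),
        lai_green=state.lai_green + gain_cm2 * density * 1e-4 * stress,
        lai_senesced=state.lai_senesced,
    )
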