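"""Fermentation arithmetic: unit conversions, yields, productivities.

Shake-flask methanol cultivations are described by concentrations in
mixed conventions (%v/v, g/L, mM), molar product-per-substrate yields,
volumetric productivities, and evaporation-corrected titers.  These
helpers keep raw values exact and expose the display-rounding used in
reporting (integers for percentages, one decimal for rates) separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class UndefinedYieldError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class CompoundSpec:
    name: str
    molar_mass: float             # g/mol
    carbon_count: int
    density: float | None = None  # g/L, liquid feed compounds only

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar mass must be positive")


#: compounds of the analysis; methanol density 792 g/L is consistent with
#: the 0.5% v/v = 4 g/L and 1% = 8 g/L display equivalences
COMPOUNDS: dict[str, CompoundSpec] = {
    "methanol": CompoundSpec("methanol", 32.04, 1, density=792.0),
    "malate": CompoundSpec("malate", 134.09, 4),
    "succinate": CompoundSpec("succinate", 118.09, 4),
    "acetone": CompoundSpec("acetone", 58.08, 3),
    "isoprene": CompoundSpec("isoprene", 68.12, 5),
    "pyruvate": CompoundSpec("pyruvate", 88.06, 3),
    "fumarate": CompoundSpec("fumarate", 116.07, 4),
}

#: assumed density of the aqueous medium for evaporation correction (g/L)
MEDIUM_DENSITY = 1000.0


def display_round(value: float, decimals: int = 0) -> float:
    """Half-up rounding used for printed values (123.5 -> 124, not 124/123
    by banker's rounding)."""
    factor = 10 ** decimals
    rounded = math.floor(value * factor + 0.5) / factor
    return rounded if decimals > 0 else float(int(rounded))


def vv_percent_to_gL(percent: float, compound: CompoundSpec) -> float:
    """%v/v -> g/L via the compound's liquid density."""
    if compound.density is None:
        raise ValueError(f"{compound.name} has no liquid density")
    return percent / 100.0 * compound.density


def gL_to_mM(conc: float, compound: CompoundSpec) -> float:
    return conc / compound.molar_mass * 1000.0


def mM_to_gL(conc: float, compound: CompoundSpec) -> float:
    return conc * compound.molar_mass / 1000.0


def molar_yield(product_gL: float, substrate_consumed_gL: float,
                product: CompoundSpec, substrate: CompoundSpec) -> float:
    """mol product formed per mol substrate consumed."""
    if substrate_consumed_gL <= 0:
        raise UndefinedYieldError("no substrate consumed; yield undefined")
    return (product_gL / product.molar_mass) / \
        (substrate_consumed_gL / substrate.molar_mass)


def volumetric_productivity(titer_gL: float, elapsed_days: float) -> float:
    """g/L/d from a titer and an elapsed time."""
    if elapsed_days <= 0:
        raise ValueError("elapsed time must be positive")
    return titer_gL / elapsed_days


def ratio_percent(part: float, whole: float) -> float:
    if whole <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * part / whole


def percent_of_theoretical(yield_molmol: float, theoretical_max: float) -> float:
    """Achieved yield as a percentage of the theoretical maximum."""
    return ratio_percent(yield_molmol, theoretical_max)


def percent_remaining(residual_mM: float, initial_mM: float) -> float:
    """Residual substrate as a percentage of the initially supplied amount."""
    return ratio_percent(residual_mM, initial_mM)


# ---------------------------------------------------------------------------
# evaporation correction of shake-flask time series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimePoint:
    time_h: float
    titers: dict[str, float] = field(default_factory=dict)  # compound -> g/L
    od600: float | None = None
    flask_weight_g: float | None = None


@dataclass(frozen=True)
class CultureSeries:
    """Time-stamped titers/weights of one shake-flask culture."""

    timepoints: tuple[TimePoint, ...]
    initial_volume_mL: float

    def __post_init__(self) -> None:
        times = [tp.time_h for tp in self.timepoints]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.initial_volume_mL <= 0:
            raise ValueError("initial volume must be positive")


def evaporation_correct(series: CultureSeries,
                        medium_density: float = MEDIUM_DENSITY) -> CultureSeries:
    """Reference measured titers and OD back to the initial culture volume.

    Flask weight loss is converted to volume loss through the medium
    density; each measured concentration is multiplied by the ratio of the
    current to the initial volume.  The correction is per-timepoint and
    therefore order-independent.
    """
    if not series.timepoints:
        return series
    w0 = series.timepoints[0].flask_weight_g
    if w0 is None:
        raise ValueError("flask weights required for evaporation correction")
    density_g_per_mL = medium_density / 1000.0
    corrected = []
    for tp in series.timepoints:
        if tp.flask_weight_g is None:
            raise ValueError(f"timepoint {tp.time_h} h has no flask weight")
        volume = series.initial_volume_mL - (w0 - tp.flask_weight_g) / density_g_per_mL
        if volume <= 0:
            raise ValueError(
                f"timepoint {tp.time_h} h implies non-positive volume")
        factor = volume / series.initial_volume_mL
        corrected.append(TimePoint(
            time_h=tp.time_h,
            titers={k: v * factor for k, v in tp.titers.items()},
            od600=tp.od600 * factor if tp.od600 is not None else None,
            flask_weight_g=tp.flask_weight_g,
        ))
    return CultureSeries(timepoints=tuple(corrected),
                         initial_volume_mL=series.initial_volume_mL)
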