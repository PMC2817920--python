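"""Polarity classification on the solvent D/V ladder, polarity-adaptivity
ranges, and hydration increments.

The dipole-to-volume ratio (debye/A^3) places a complex on a ladder of
common solvents running from water (0.090) down to hexane (0.00).  Band
boundaries (0.005, 0.02, 0.06 by default) interpolate the verbal anchors
of the reference protocol: ~0.005 low-polarity/octanol, 0.04-0.045
alcohol-like, 0.090 water.  An ensemble whose minimum and maximum D/V fall
in different bands is called *polarity adaptive* — this two-band criterion
is this package's operationalization of the term.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import ASFResult, GroupSummary, SolventReference
from .io import load_fixture

#: Band boundaries (D/V, ascending) and the names of the four bands.
DEFAULT_BAND_BOUNDS = (0.005, 0.02, 0.06)
BAND_NAMES = ("nonpolar", "low-polarity", "alcohol-range", "water-like")

#: Surface area / volume of a single water molecule used to express
#: hydration increments in "water equivalents".
WATER_AREA_A2 = 36.4
WATER_VOLUME_A3 = 19.4


def default_ladder() -> list[SolventReference]:
    """The packaged eight-solvent reference ladder."""
    return load_fixture("table1")


def band_label(dv_ratio: float, bounds: tuple[float, ...] = DEFAULT_BAND_BOUNDS) -> str:
    if dv_ratio < 0:
        raise ValueError("D/V ratio must be >= 0")
    if len(bounds) + 1 != len(BAND_NAMES):
        raise ValueError("expected one boundary fewer than bands")
    for bound, name in zip(bounds, BAND_NAMES):
        if dv_ratio < bound:
            return name
    return BAND_NAMES[-1]


def classify_polarity(
    dv_ratio: float,
    ladder: list[SolventReference] | None = None,
    bounds: tuple[float, ...] = DEFAULT_BAND_BOUNDS,
) -> tuple[SolventReference, str]:
    """Nearest reference solvent and polarity band for a D/V ratio.

    Nearest by |dv - dv_ratio|; ties resolve to the more polar (higher
    D/V) solvent.
    """
    if dv_ratio < 0:
        raise ValueError("D/V ratio must be >= 0")
    ladder = ladder if ladder is not None else default_ladder()
    if not ladder:
        raise ValueError("empty solvent ladder")
    nearest = min(ladder, key=lambda s: (abs(s.dv_ratio - dv_ratio), -s.dv_ratio))
    return nearest, band_label(dv_ratio, bounds)


@dataclass(frozen=True)
class PolarityRange:
    min_dv: float
    max_dv: float
    span: float
    adaptive: bool


def polarity_range(
    results: list[ASFResult] | list[float],
    bounds: tuple[float, ...] = DEFAULT_BAND_BOUNDS,
) -> PolarityRange:
    """D/V spread of a complex ensemble; ``adaptive`` when the extremes
    fall in different polarity bands."""
    values = [r.dv_ratio if isinstance(r, ASFResult) else float(r) for r in results]
    if len(values) < 2:
        raise ValueError("polarity_range needs at least 2 complexes")
    lo, hi = min(values), max(values)
    return PolarityRange(
        min_dv=lo,
        max_dv=hi,
        span=hi - lo,
        adaptive=band_label(lo, bounds) != band_label(hi, bounds),
    )


@dataclass(frozen=True)
class HydrationIncrement:
    """Componentwise change on moving a water into the inner sphere."""

    d_area: float
    d_volume: float
    d_dipole: float
    d_energy: float
    area_water_equivalents: float
    volume_water_equivalents: float


def hydration_increment(
    summary_dry: GroupSummary,
    summary_wet: GroupSummary,
    water_area: float = WATER_AREA_A2,
    water_volume: float = WATER_VOLUME_A3,
) -> HydrationIncrement:
    """Wet minus dry ensemble means, plus area/volume deltas expressed as
    multiples of a single water molecule."""
    d_area = summary_wet.mean_area - summary_dry.mean_area
    d_volume = summary_wet.mean_volume - summary_dry.mean_volume
    return HydrationIncrement(
        d_area=d_area,
        d_volume=d_volume,
        d_dipole=summary_wet.mean_dipole - summary_dry.mean_dipole,
        d_energy=summary_wet.mean_energy - summary_dry.mean_energy,
        area_water_equivalents=d_area / water_area,
        volume_water_equivalents=d_volume / water_volume,
    )
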