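"""The scoring core: aqueous stability factor, covalency filters, ranking
and group summaries.

The aqueous stability factor of a complex is

    ASF = E * L / (D * Z)        [J.m/debye]

with E the complex energy (source-scale joules), L the mean coordination
bond length converted from angstroms to meters, D the dipole moment in
debye and Z the signed integer charge (+1 for every complex in the
reference data).  Smaller — and in particular negative — ASF marks a more
stable, more water-compatible complex, so ranking is ascending by signed
value by default; ranking by |ASF| is available as an alternative policy.
"""

from __future__ import annotations

from statistics import fmean

from .core import (
    ANGSTROM_TO_METER,
    ASFResult,
    ComplexDescriptor,
    FilterConfig,
    GroupSummary,
)

#: Filter-rule identifiers recorded in ``ASFResult.filter_reasons``.
REASON_ABL = "abl_gt_max"
REASON_BOND = "bond_gt_max"

RANK_POLICIES = ("signed", "magnitude")


def average_bond_length(bond_distances) -> float:
    """Arithmetic mean of the coordination bond distances (A)."""
    distances = list(bond_distances)
    if not distances:
        raise ValueError("average_bond_length of an empty distance list")
    return fmean(distances)


def compute_asf(energy: float, abl: float, dipole: float, charge: int) -> float:
    """ASF = E * (abl in meters) / (D * Z)."""
    if abl <= 0:
        raise ValueError(f"average bond length must be > 0, got {abl}")
    if dipole <= 0:
        raise ZeroDivisionError(
            f"dipole moment must be > 0 to compute ASF, got {dipole}"
        )
    if charge == 0:
        raise ValueError("charge must be nonzero to compute ASF")
    return energy * (abl * ANGSTROM_TO_METER) / (dipole * charge)


def compute_dv(dipole: float, volume: float) -> float:
    """Dipole-to-volume ratio D/V (debye per A^3), the polarity proxy."""
    if volume <= 0:
        raise ValueError(f"volume must be > 0, got {volume}")
    return dipole / volume


def apply_filters(
    descriptor: ComplexDescriptor,
    config: FilterConfig | None = None,
) -> tuple[bool, tuple[str, ...]]:
    """Covalency screen: mean bond length and single longest bond.

    Returns ``(passed, reasons)``; both rules may fail at once.  Thresholds
    are strict inequalities (a bond of exactly 2.9 A still passes).
    """
    config = config or FilterConfig()
    # relative epsilon keeps exact-boundary inputs (e.g. six 2.7 A bonds)
    # on the passing side despite binary rounding of the mean
    eps = 1e-12
    reasons = []
    if config.enforce_average:
        abl = average_bond_length(descriptor.bond_distances)
        if abl > config.max_average_bond_length * (1 + eps):
            reasons.append(REASON_ABL)
    if config.enforce_single:
        if any(d > config.max_single_bond_length * (1 + eps)
               for d in descriptor.bond_distances):
            reasons.append(REASON_BOND)
    return (not reasons), tuple(reasons)


def score_complexes(
    descriptors: list[ComplexDescriptor],
    filter_config: FilterConfig | None = None,
) -> list[ASFResult]:
    """Score every complex, recording the filter verdict separately.

    The ASF is computed even for complexes that fail the covalency screen
    (the reference tables themselves contain rule-violating rows); the
    verdict only controls later ranking.
    """
    filter_config = filter_config or FilterConfig()
    results = []
    for d in descriptors:
        abl = average_bond_length(d.bond_distances)
        try:
            asf = compute_asf(d.energy, abl, d.dipole_moment, d.charge)
        except (ValueError, ZeroDivisionError) as exc:
            raise type(exc)(f"{d.complex_id}: {exc}") from None
        passed, reasons = apply_filters(d, filter_config)
        results.append(
            ASFResult(
                complex_id=d.complex_id,
                asf=asf,
                average_bond_length=abl,
                dv_ratio=compute_dv(d.dipole_moment, d.volume),
                passed_filters=passed,
                filter_reasons=reasons,
                donors=d.donor_order,
            )
        )
    return results


def rank_complexes(
    results: list[ASFResult],
    k: int | None = None,
    policy: str = "signed",
    include_filtered: bool = False,
) -> list[ASFResult]:
    """Return the top-k most stable complexes.

    ``signed`` (default) sorts ascending by signed ASF, so negative scores
    rank first; ``magnitude`` sorts ascending by |ASF|.  Ties break
    lexicographically on complex_id.  Complexes failing the covalency
    screen are excluded unless ``include_filtered``.  Assigns 1-based
    ``rank`` on the returned (copied-order) results.
    """
    if policy not in RANK_POLICIES:
        raise ValueError(f"unknown ranking policy {policy!r}; use one of {RANK_POLICIES}")
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    pool = results if include_filtered else [r for r in results if r.passed_filters]
    key = (lambda r: (r.asf, r.complex_id)) if policy == "signed" else \
          (lambda r: (abs(r.asf), r.complex_id))
    ranked = sorted(pool, key=key)
    if k is not None:
        ranked = ranked[:k]
    for i, r in enumerate(ranked, start=1):
        r.rank = i
    return ranked


def summarize_group(descriptors: list[ComplexDescriptor], label: str) -> GroupSummary:
    """Ensemble means (area, volume, dipole, D/V, ABL, energy) plus the
    best — minimum signed — and mean ASF over one species' complexes."""
    if not descriptors:
        raise ValueError(f"cannot summarize empty group {label!r}")
    results = score_complexes(descriptors)
    asfs = [r.asf for r in results]
    return GroupSummary(
        label=label,
        n=len(descriptors),
        mean_area=fmean(d.surface_area for d in descriptors),
        mean_volume=fmean(d.volume for d in descriptors),
        mean_dipole=fmean(d.dipole_moment for d in descriptors),
        mean_dv=fmean(r.dv_ratio for r in results),
        mean_abl=fmean(r.average_bond_length for r in results),
        mean_energy=fmean(d.energy for d in descriptors),
        best_asf=min(asfs),
        mean_asf=fmean(asfs),
    )
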