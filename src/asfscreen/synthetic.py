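"""Stand-ins for the semi-empirical descriptor stage.

Two back-ends let the full enumerate -> score -> rank pipeline run with no
quantum-chemistry software:

* :func:`generate_descriptors` — a seeded stochastic generator whose
  marginal ranges and hydrated-vs-dry dipole shift emulate the reference
  descriptor tables (only marginals; no joint correlations).
* :func:`mock_descriptors` — a deterministic geometric mock mapping an
  enumerated shell plus 3D donor positions to pseudo-descriptors.  Its
  functional forms are non-physical test plumbing: they exist so ranking
  and filtering have structured, reproducible inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import AQUA_LABEL, ComplexDescriptor, CoordinationShell
from .shells import GeometryError

#: Donor-label pool the stochastic generator samples shells from.
_LABEL_POOL = tuple(f"O{i}" for i in range(1, 9)) + ("N1",)


@dataclass
class SyntheticConfig:
    """Marginal distributions of the stochastic descriptor generator.

    Ranges mirror the spreads of the reference descriptor tables: bond
    lengths 1.85-2.80 A, dipoles 7-37 D, energies ~N(1.2e6, 6e5) J
    truncated at zero, volumes/areas spanning the small (discodermolide)
    to large (kahalalide F) complexes.  ``aqua_dipole_shift`` (default
    +4.97 D) reproduces the mean dipole increase on moving a water into
    the inner sphere (ensemble means 13.36 vs 8.39 D).
    """

    seed: int
    n_complexes: int = 100
    bond_length_range: tuple[float, float] = (1.85, 2.80)
    dipole_range: tuple[float, float] = (7.0, 37.0)
    energy_mean: float = 1.2e6
    energy_sd: float = 6e5
    volume_range: tuple[float, float] = (640.0, 1600.0)
    area_range: tuple[float, float] = (650.0, 1590.0)
    molar_mass_range: tuple[float, float] = (640.0, 1540.0)
    aqua_fraction: float = 0.5
    aqua_dipole_shift: float = 4.97
    negative_energy_fraction: float = 0.0
    charge: int = 1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("bond_length_range", "dipole_range", "volume_range",
                     "area_range", "molar_mass_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be ordered low < high, got ({lo}, {hi})")
        if not 0.0 <= self.aqua_fraction <= 1.0:
            raise ValueError("aqua_fraction must be in [0, 1]")
        if not 0.0 <= self.negative_energy_fraction <= 1.0:
            raise ValueError("negative_energy_fraction must be in [0, 1]")
        if self.n_complexes < 1:
            raise ValueError("n_complexes must be >= 1")


def generate_descriptors(config: SyntheticConfig) -> list[ComplexDescriptor]:
    """Draw ``n_complexes`` reproducible synthetic descriptor records.

    Bond lengths are i.i.d. uniform in range; the dipole is uniform in
    range plus ``aqua_dipole_shift`` for aqua-containing records; energy
    is normal truncated at zero (a ``negative_energy_fraction`` of records
    is then sign-flipped); charge is ``config.charge`` throughout.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ComplexDescriptor] = []
    for i in range(config.n_complexes):
        has_aqua = bool(rng.random() < config.aqua_fraction)
        n_donors = 5 if has_aqua else 6
        labels = sorted(rng.choice(_LABEL_POOL, size=n_donors, replace=False))
        shell = CoordinationShell(donor_labels=frozenset(labels), has_aqua=has_aqua)

        distances = tuple(rng.uniform(*config.bond_length_range, size=6).round(3))
        dipole = rng.uniform(*config.dipole_range)
        if has_aqua:
            dipole += config.aqua_dipole_shift
        energy = rng.normal(config.energy_mean, config.energy_sd)
        while energy <= 0:  # truncate at zero
            energy = rng.normal(config.energy_mean, config.energy_sd)
        if rng.random() < config.negative_energy_fraction:
            energy = -energy

        order = tuple(labels) + ((AQUA_LABEL,) if has_aqua else ())
        records.append(
            ComplexDescriptor(
                complex_id=f"syn-{i:04d}",
                shell=shell,
                dipole_moment=float(dipole),
                bond_distances=distances,
                surface_area=float(rng.uniform(*config.area_range)),
                volume=float(rng.uniform(*config.volume_range)),
                molar_mass=float(rng.uniform(*config.molar_mass_range)),
                energy=float(energy),
                charge=config.charge,
                donor_order=order,
            )
        )
    return records


# deterministic mock: geometry -> pseudo-descriptor constants
_CLIP_LOW, _CLIP_HIGH = 1.85, 3.2     # A, recorded bond-length window
_REF_BOND = 2.1                       # A, strain-free reference distance
_DIPOLE_SCALE = 5.0                   # D per unit of vector asymmetry
_ENERGY_SCALE = 1e6                   # J per A^2 of mean squared strain
_SPHERE_PAD = 3.0                     # A added to the bounding-sphere radius

_ATOM_MASS = {"O": 16.0, "N": 14.0}


def mock_descriptors(
    shell: CoordinationShell,
    structure_positions: dict[str, tuple[float, float, float]],
    complex_id: str | None = None,
) -> ComplexDescriptor:
    """Deterministic pseudo-descriptors for one shell from 3D geometry.

    A pseudo-iron sits at the donor centroid.  Bond distances are the
    donor-centroid distances clipped to [1.85, 3.2] A (an aqua ligand
    contributes a fixed 2.1 A bond); the dipole is the magnitude of the
    resultant of unit centroid->donor vectors times 5 D; the energy is
    1e6 times the mean squared deviation of the recorded distances from
    2.1 A; area and volume come from a padded bounding sphere.  Identical
    inputs give identical outputs.
    """
    labels = sorted(shell.donor_labels)
    missing = [lab for lab in labels if lab not in structure_positions]
    if missing:
        raise GeometryError(f"no coordinates for donor(s): {', '.join(missing)}")
    pts = np.asarray([structure_positions[lab] for lab in labels], dtype=float)
    centroid = pts.mean(axis=0)
    vectors = pts - centroid
    raw = np.sqrt((vectors ** 2).sum(axis=1))
    if (raw == 0).any():
        raise GeometryError("a donor coincides with the centroid")

    distances = list(np.clip(raw, _CLIP_LOW, _CLIP_HIGH))
    units = vectors / raw[:, None]
    if shell.has_aqua:
        distances.append(_REF_BOND)
        resultant = units.sum(axis=0)
        norm = float(np.sqrt((resultant ** 2).sum()))
        # the aqua ligand sits opposite the net donor direction (or +z)
        aqua_unit = -resultant / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        units = np.vstack([units, aqua_unit])

    dipole = float(np.sqrt((units.sum(axis=0) ** 2).sum())) * _DIPOLE_SCALE
    distances_arr = np.asarray(distances)
    energy = float(_ENERGY_SCALE * ((distances_arr - _REF_BOND) ** 2).mean())

    radius = float(raw.max()) + _SPHERE_PAD
    volume = 4.0 / 3.0 * math.pi * radius ** 3
    area = 4.0 * math.pi * radius ** 2

    mass = sum(_ATOM_MASS.get(lab[0], 12.0) + 14.0 for lab in labels)
    if shell.has_aqua:
        mass += 18.0

    order = tuple(labels) + ((AQUA_LABEL,) if shell.has_aqua else ())
    return ComplexDescriptor(
        complex_id=complex_id or "mock-" + ".".join(order),
        shell=shell,
        dipole_moment=round(dipole, 6),
        bond_distances=tuple(round(d, 6) for d in distances),
        surface_area=round(area, 4),
        volume=round(volume, 4),
        molar_mass=round(mass, 3),
        energy=round(energy, 4),
        charge=1,
    )
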