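"""Domain types and unit conventions.

The screening pipeline works on per-complex physical descriptors of an
octahedral iron(II/III) centre bound to five or six oxygen/nitrogen donors of
a natural-product ligand (plus, optionally, one aqua ligand).  Conventions:

* bond distances and average bond length (ABL) in angstroms,
* dipole moment in debye,
* surface area in A^2, volume in A^3,
* energy on the scale printed by the semi-empirical (PM3) source tables;
  it is treated as an opaque "joules" quantity and never converted,
* charge as a signed integer (``+1`` throughout the reference data),
* ASF (aqueous stability factor) in J.m/debye, with the angstrom -> meter
  conversion of the bond length hard-coded into the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Conversion applied to the average bond length inside the ASF score.
ANGSTROM_TO_METER = 1e-10

#: Reserved donor label for the aqua (water) ligand occupying one
#: coordination site.
AQUA_LABEL = "H2O"


class SchemaError(ValueError):
    """A table is missing a mandatory column or has an unusable header."""


class RecordError(ValueError):
    """A single table row could not be turned into a valid record."""


class FixtureLookupError(KeyError):
    """An unknown packaged fixture table was requested."""


@dataclass(frozen=True)
class DonorAtom:
    """One candidate O or N donor atom of the ligand.

    ``label`` follows the convention of numbering oxygens and nitrogens
    separately in file atom order ("O1", "O2", ..., "N1", ...).
    """

    atom_index: int
    element: str
    label: str
    position: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.element not in ("O", "N"):
            raise ValueError(f"donor element must be O or N, got {self.element!r}")


@dataclass(frozen=True)
class CoordinationShell:
    """Which ligand donors (plus an optional aqua ligand) bind the iron.

    ``donor_labels`` holds only the ligand donors; with ``has_aqua`` the
    sixth octahedral site is a water molecule, so exactly five ligand
    donors are allowed.
    """

    donor_labels: frozenset[str]
    has_aqua: bool = False

    def __post_init__(self) -> None:
        n = len(self.donor_labels) + (1 if self.has_aqua else 0)
        if n != 6:
            raise ValueError(
                f"shell must occupy 6 octahedral sites, got {n} "
                f"({len(self.donor_labels)} donors, has_aqua={self.has_aqua})"
            )
        if AQUA_LABEL in self.donor_labels:
            raise ValueError(f"{AQUA_LABEL!r} is reserved for the aqua ligand")

    @classmethod
    def from_labels(cls, labels: list[str] | tuple[str, ...]) -> "CoordinationShell":
        """Build a shell from a raw label list, recognising the H2O label."""
        labels = [lab.strip() for lab in labels]
        has_aqua = AQUA_LABEL in labels
        donors = [lab for lab in labels if lab != AQUA_LABEL]
        if len(donors) != len(set(donors)):
            raise ValueError(f"duplicate donor labels in {labels}")
        return cls(donor_labels=frozenset(donors), has_aqua=has_aqua)

    @property
    def sorted_labels(self) -> tuple[str, ...]:
        """Donor labels in lexicographic order, aqua label last if present."""
        labels = tuple(sorted(self.donor_labels))
        return labels + ((AQUA_LABEL,) if self.has_aqua else ())


@dataclass
class ComplexDescriptor:
    """Physical descriptors of one candidate iron complex.

    ``bond_distances`` are the six Fe-O / Fe-N / Fe-OH2 distances; a lenient
    reader may retain records with only five (flagged ``incomplete_distances``).
    ``donor_order`` preserves the donor labels verbatim in table order.
    ``printed`` carries derived columns (abl/dv/asf) exactly as printed in a
    source table, for replication checks; ``flags`` marks documented
    inconsistencies of such rows.
    """

    complex_id: str
    shell: CoordinationShell
    dipole_moment: float
    bond_distances: tuple[float, ...]
    surface_area: float
    volume: float
    molar_mass: float
    energy: float
    charge: int
    donor_order: tuple[str, ...] = ()
    printed: dict[str, float] = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.donor_order:
            self.donor_order = self.shell.sorted_labels
        if self.dipole_moment < 0:
            raise ValueError(f"{self.complex_id}: dipole moment must be >= 0")
        if self.volume <= 0 or self.surface_area <= 0:
            raise ValueError(f"{self.complex_id}: volume and area must be > 0")
        if any(d <= 0 for d in self.bond_distances):
            raise ValueError(f"{self.complex_id}: bond distances must be > 0")
        if not 5 <= len(self.bond_distances) <= 6:
            raise ValueError(
                f"{self.complex_id}: expected 5 or 6 bond distances, "
                f"got {len(self.bond_distances)}"
            )

    @property
    def is_complete(self) -> bool:
        return len(self.bond_distances) == 6


@dataclass
class ASFResult:
    """Score card for one complex: ASF, ABL, D/V and the filter verdict."""

    complex_id: str
    asf: float
    average_bond_length: float
    dv_ratio: float
    passed_filters: bool
    filter_reasons: tuple[str, ...] = ()
    rank: int | None = None
    donors: tuple[str, ...] = ()


@dataclass(frozen=True)
class SolventReference:
    """One rung of the solvent polarity ladder (dipole/volume ratio)."""

    name: str
    dipole_moment: float
    molecular_volume: float
    dv_ratio: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ActivityRecord:
    """A growth-inhibition measurement (GI50) for one cell line / sample."""

    sample_id: str
    gi50: float

    def __post_init__(self) -> None:
        if self.gi50 <= 0:
            raise ValueError(f"{self.sample_id}: gi50 must be > 0")


@dataclass
class GroupSummary:
    """Ensemble means over one species' complexes (Table-8 shape).

    ``abl``, ``best_asf`` and ``mean_asf`` are ``None`` for uncomplexed
    (iron-free) molecules, for which those columns do not exist.
    """

    label: str
    n: int
    mean_area: float
    mean_volume: float
    mean_dipole: float
    mean_dv: float
    mean_abl: float | None
    mean_energy: float
    best_asf: float | None
    mean_asf: float | None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group summary requires n > 0")


@dataclass
class FilterConfig:
    """Covalency screens applied before ranking.

    Complexes whose mean coordination bond length exceeds
    ``max_average_bond_length`` (default 2.7 A), or with any single bond
    longer than ``max_single_bond_length`` (default 2.9 A), are judged to
    lack covalent character and are excluded from ranking.  The two rules
    are independent and individually switchable.
    """

    max_average_bond_length: float = 2.7
    max_single_bond_length: float = 2.9
    enforce_average: bool = True
    enforce_single: bool = True

    def __post_init__(self) -> None:
        if self.max_average_bond_length <= 0 or self.max_single_bond_length <= 0:
            raise ValueError("filter thresholds must be > 0")


@dataclass
class RegressionFit:
    """A fitted trend family with its coefficients and R^2.

    Coefficients are ordered as in spreadsheet trendline captions:
    polynomial families highest degree first; exponential ``(a, b)`` for
    y = a*exp(b*x); power ``(a, b)`` for y = a*x**b; logarithmic ``(a, b)``
    for y = a*ln(x) + b.
    """

    family: str
    coefficients: tuple[float, ...]
    r_squared: float
    n: int

    _ARITY = {"linear": 2, "quadratic": 3, "exponential": 2,
              "power": 2, "logarithmic": 2}

    def __post_init__(self) -> None:
        arity = self._ARITY.get(self.family)
        if arity is None:
            raise ValueError(f"unknown fit family {self.family!r}")
        if len(self.coefficients) != arity:
            raise ValueError(
                f"{self.family} fit needs {arity} coefficients, "
                f"got {len(self.coefficients)}"
            )
        if self.n < arity:
            raise ValueError("fewer points than coefficients")
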