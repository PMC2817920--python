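"""Donor-atom identification and combinatorial enumeration of octahedral
coordination shells.

A ligand with n O/N donors offers C(n,6) six-donor shells, plus C(n,5)
five-donor shells completed by an aqua ligand.  The number of candidates
grows quickly; ``cap_shells`` makes the practical cap (~50 per mode in the
reference protocol) an explicit, reproducible selection rule.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import numpy as np

from .core import CoordinationShell, DonorAtom


class StructureFormatError(ValueError):
    """The molecular structure file could not be parsed."""


class GeometryError(ValueError):
    """Missing or unusable 3D coordinates."""


def _load_mol(structure):
    from rdkit import Chem

    if isinstance(structure, (str, Path)):
        path = Path(structure)
        if not path.exists():
            raise StructureFormatError(f"no such structure file: {path}")
        if path.suffix.lower() == ".pdb":
            mol = Chem.MolFromPDBFile(str(path), removeHs=False, sanitize=False)
        else:  # SDF / MOL V2000
            mol = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=False)
        if mol is None:
            raise StructureFormatError(f"could not parse structure file {path}")
        return mol
    return structure  # assume an rdkit Mol


def identify_donors(structure, label_map: dict[int, str] | None = None) -> list[DonorAtom]:
    """Every O and N atom of the structure, as candidate iron donors.

    Labels number oxygens and nitrogens separately in file atom order
    ("O1", "O2", ..., "N1", ...); ``label_map`` (atom index -> label) can
    override individual labels to match an external numbering scheme.
    Deterministic for a fixed input file.
    """
    mol = _load_mol(structure)
    conf = mol.GetConformer() if mol.GetNumConformers() else None
    label_map = label_map or {}

    donors: list[DonorAtom] = []
    counts = {"O": 0, "N": 0}
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        if symbol not in counts:
            continue
        counts[symbol] += 1
        idx = atom.GetIdx()
        label = label_map.get(idx, f"{symbol}{counts[symbol]}")
        position = None
        if conf is not None:
            p = conf.GetAtomPosition(idx)
            position = (p.x, p.y, p.z)
        donors.append(DonorAtom(atom_index=idx, element=symbol, label=label,
                                position=position))
    labels = [d.label for d in donors]
    if len(labels) != len(set(labels)):
        raise ValueError("donor labels are not unique (check the label map)")
    return donors


def _span_ok(group: tuple[DonorAtom, ...], max_span: float) -> bool:
    positions = []
    for d in group:
        if d.position is None:
            raise GeometryError(f"donor {d.label} has no 3D coordinates")
        positions.append(d.position)
    pts = np.asarray(positions)
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max()) <= max_span


def enumerate_shells(
    donors: list[DonorAtom],
    include_aqua: bool = False,
    geometry_max_span: float | None = None,
) -> list[CoordinationShell]:
    """All candidate octahedral shells over the given donors.

    Emits every 6-donor subset; with ``include_aqua`` additionally every
    5-donor subset completed by an aqua ligand.  Order is deterministic:
    six-donor shells first, each mode lexicographic by sorted donor labels.
    ``geometry_max_span`` (A) drops subsets whose maximum pairwise
    donor-donor distance exceeds the bound (requires 3D coordinates).
    """
    needed = 5 if include_aqua else 6
    if len(donors) < needed:
        raise ValueError(
            f"need at least {needed} donors "
            f"({'aqua' if include_aqua else 'six-donor'} mode), got {len(donors)}"
        )
    ordered = sorted(donors, key=lambda d: d.label)

    shells: list[CoordinationShell] = []
    for size, aqua in ((6, False),) + (((5, True),) if include_aqua else ()):
        if len(ordered) < size:
            continue
        for group in combinations(ordered, size):
            if geometry_max_span is not None and not _span_ok(group, geometry_max_span):
                continue
            shells.append(
                CoordinationShell(
                    donor_labels=frozenset(d.label for d in group),
                    has_aqua=aqua,
                )
            )
    return shells


def count_conformers(n_rotatable_bonds: int) -> int:
    """3**n staggered-rotamer conformer bound (exact integer arithmetic)."""
    if not isinstance(n_rotatable_bonds, (int, np.integer)) or isinstance(n_rotatable_bonds, bool):
        raise ValueError("n_rotatable_bonds must be an integer")
    if n_rotatable_bonds < 0:
        raise ValueError("n_rotatable_bonds must be >= 0")
    return 3 ** int(n_rotatable_bonds)


def cap_shells(
    shells: list[CoordinationShell],
    max_count: int,
    selection_rule: str = "first-lexicographic",
    seed: int | None = None,
) -> list[CoordinationShell]:
    """Cap the candidate list at ``max_count`` shells per mode.

    ``first-lexicographic`` keeps the first shells in enumeration order;
    ``random-with-seed`` draws a reproducible random subset per mode
    (``seed`` mandatory).  Within each mode the output preserves
    enumeration order.
    """
    if max_count < 1:
        raise ValueError("max_count must be >= 1")
    if selection_rule not in ("first-lexicographic", "random-with-seed"):
        raise ValueError(f"unknown selection rule {selection_rule!r}")
    if selection_rule == "random-with-seed" and seed is None:
        raise ValueError("random-with-seed selection requires a seed")

    capped: list[CoordinationShell] = []
    rng = np.random.default_rng(seed) if seed is not None else None
    for aqua in (False, True):
        mode = [s for s in shells if s.has_aqua is aqua]
        if len(mode) <= max_count:
            capped.extend(mode)
        elif selection_rule == "first-lexicographic":
            capped.extend(mode[:max_count])
        else:
            keep = sorted(rng.choice(len(mode), size=max_count, replace=False))
            capped.extend(mode[i] for i in keep)
    return capped
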