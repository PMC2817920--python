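"""Readers and writers for descriptor, activity, solvent and result tables,
plus the packaged reference tables (``table1`` ... ``table8``).

All tables are plain CSV (UTF-8, "." decimal separator); TSV is accepted via
``dialect="tsv"``.  Numeric cells that do not parse raise :class:`RecordError`
with the offending row — they are never silently zeroed.
"""

from __future__ import annotations

import csv
import math
from importlib import resources
from pathlib import Path
from typing import IO, Iterable

from .core import (
    AQUA_LABEL,
    ASFResult,
    ActivityRecord,
    ComplexDescriptor,
    CoordinationShell,
    FixtureLookupError,
    GroupSummary,
    RecordError,
    SchemaError,
    SolventReference,
)

DESCRIPTOR_COLUMNS = [
    "complex_id", "donors", "dipole_debye",
    "d1", "d2", "d3", "d4", "d5", "d6",
    "area_A2", "volume_A3", "molar_mass", "energy_J", "charge",
]
PRINTED_COLUMNS = ["abl_printed", "dv_printed", "asf_printed"]
RESULT_COLUMNS = [
    "complex_id", "donors", "asf_Jm_per_D", "abl_A", "dv_D_per_A3",
    "passed", "filter_reasons", "rank",
]

FIXTURE_NAMES = tuple(f"table{i}" for i in range(1, 9))


def _rows(source: str | Path | IO[str], dialect: str) -> tuple[list[str], list[list[str]]]:
    delim = {"csv": ",", "tsv": "\t"}.get(dialect)
    if delim is None:
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")

    def parse(fh: Iterable[str]) -> tuple[list[str], list[list[str]]]:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("table has no header row") from None
        return [c.strip() for c in header], [row for row in reader if any(c.strip() for c in row)]

    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return parse(fh)
    return parse(source)


def _float(cell: str, column: str, row_idx: int) -> float:
    try:
        value = float(cell)
    except ValueError:
        raise RecordError(
            f"row {row_idx}: cannot parse {column}={cell!r} as a number"
        ) from None
    if math.isnan(value):
        raise RecordError(f"row {row_idx}: {column} is not a number")
    return value


def _require(header: list[str], columns: list[str]) -> None:
    missing = [c for c in columns if c not in header]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")


def read_descriptor_table(
    source: str | Path | IO[str],
    dialect: str = "csv",
    strict: bool = True,
) -> list[ComplexDescriptor]:
    """Read per-complex descriptors from a CSV/TSV table.

    In strict mode a row must provide all six bond distances; in lenient
    mode (``strict=False``) a row with only five is retained and flagged
    ``incomplete_distances``.  Extra ``abl_printed``/``dv_printed``/
    ``asf_printed``/``flags`` columns, when present, are preserved on the
    record for replication work.
    """
    header, rows = _rows(source, dialect)
    _require(header, DESCRIPTOR_COLUMNS)
    idx = {c: header.index(c) for c in header}

    records: list[ComplexDescriptor] = []
    for i, row in enumerate(rows, start=1):
        if len(row) < len(header):
            row = row + [""] * (len(header) - len(row))
        cell = lambda c: row[idx[c]].strip()  # noqa: E731

        distances = tuple(
            _float(cell(c), c, i)
            for c in ("d1", "d2", "d3", "d4", "d5", "d6")
            if cell(c) != ""
        )
        if len(distances) < 5:
            raise RecordError(
                f"row {i}: found {len(distances)} bond distances, need at least 5"
            )
        flags = tuple(f for f in cell("flags").split(";") if f) if "flags" in idx else ()
        if len(distances) == 5:
            if strict:
                raise RecordError(
                    f"row {i}: 5 bond distances in strict mode (6 required)"
                )
            if "incomplete_distances" not in flags:
                flags = flags + ("incomplete_distances",)

        printed = {}
        for col in PRINTED_COLUMNS:
            if col in idx and cell(col) != "":
                printed[col.removesuffix("_printed")] = _float(cell(col), col, i)

        donor_labels = tuple(lab.strip() for lab in cell("donors").split(",") if lab.strip())
        try:
            shell = CoordinationShell.from_labels(list(donor_labels))
        except ValueError as exc:
            raise RecordError(f"row {i}: {exc}") from None

        charge_cell = cell("charge")
        try:
            charge = int(charge_cell)
        except ValueError:
            raise RecordError(
                f"row {i}: cannot parse charge={charge_cell!r} as an integer"
            ) from None

        records.append(
            ComplexDescriptor(
                complex_id=cell("complex_id"),
                shell=shell,
                dipole_moment=_float(cell("dipole_debye"), "dipole_debye", i),
                bond_distances=distances,
                surface_area=_float(cell("area_A2"), "area_A2", i),
                volume=_float(cell("volume_A3"), "volume_A3", i),
                molar_mass=_float(cell("molar_mass"), "molar_mass", i),
                energy=_float(cell("energy_J"), "energy_J", i),
                charge=charge,
                donor_order=donor_labels,
                printed=printed,
                flags=flags,
            )
        )
    return records


def write_descriptor_table(
    records: list[ComplexDescriptor],
    destination: str | Path | IO[str],
    dialect: str = "csv",
) -> None:
    """Write descriptors in the canonical CSV schema (round-trips with
    :func:`read_descriptor_table`)."""
    delim = "," if dialect == "csv" else "\t"
    with_extras = any(r.printed or r.flags for r in records)
    header = DESCRIPTOR_COLUMNS + (PRINTED_COLUMNS + ["flags"] if with_extras else [])

    def emit(fh: IO[str]) -> None:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(header)
        for r in records:
            dists = [repr(d) for d in r.bond_distances]
            dists += [""] * (6 - len(dists))
            row = [
                r.complex_id, ",".join(r.donor_order), repr(r.dipole_moment),
                *dists, repr(r.surface_area), repr(r.volume),
                repr(r.molar_mass), repr(r.energy), str(r.charge),
            ]
            if with_extras:
                row += [
                    "" if "abl" not in r.printed else repr(r.printed["abl"]),
                    "" if "dv" not in r.printed else repr(r.printed["dv"]),
                    "" if "asf" not in r.printed else repr(r.printed["asf"]),
                    ";".join(r.flags),
                ]
            writer.writerow(row)

    if isinstance(destination, (str, Path)):
        with open(destination, "w", newline="", encoding="utf-8") as fh:
            emit(fh)
    else:
        emit(destination)


def read_activity_table(source: str | Path | IO[str], dialect: str = "csv") -> list[ActivityRecord]:
    """Read (sample_id, gi50) activity records."""
    header, rows = _rows(source, dialect)
    _require(header, ["sample_id", "gi50"])
    sid, gid = header.index("sample_id"), header.index("gi50")
    records = []
    for i, row in enumerate(rows, start=1):
        gi50 = _float(row[gid].strip(), "gi50", i)
        try:
            records.append(ActivityRecord(sample_id=row[sid].strip(), gi50=gi50))
        except ValueError as exc:
            raise RecordError(f"row {i}: {exc}") from None
    return records


def write_activity_table(records: list[ActivityRecord], destination: str | Path) -> None:
    with open(destination, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "gi50"])
        for r in records:
            writer.writerow([r.sample_id, repr(r.gi50)])


def read_solvent_table(source: str | Path | IO[str], dialect: str = "csv") -> list[SolventReference]:
    """Read a solvent polarity ladder (name, dipole, volume, D/V)."""
    header, rows = _rows(source, dialect)
    _require(header, ["name", "dipole_debye", "volume_A3", "dv"])
    idx = {c: header.index(c) for c in header}
    out = []
    for i, row in enumerate(rows, start=1):
        flags_cell = row[idx["flags"]].strip() if "flags" in idx and len(row) > idx["flags"] else ""
        out.append(
            SolventReference(
                name=row[idx["name"]].strip(),
                dipole_moment=_float(row[idx["dipole_debye"]], "dipole_debye", i),
                molecular_volume=_float(row[idx["volume_A3"]], "volume_A3", i),
                dv_ratio=_float(row[idx["dv"]], "dv", i),
                flags=tuple(f for f in flags_cell.split(";") if f),
            )
        )
    return out


def read_group_table(source: str | Path | IO[str], dialect: str = "csv") -> list[GroupSummary]:
    """Read per-species ensemble summaries (Table-8 shape)."""
    header, rows = _rows(source, dialect)
    cols = ["species", "area_A2", "volume_A3", "dipole_debye", "dv",
            "abl_A", "energy_J", "asf_best", "asf_mean", "n"]
    _require(header, cols)
    idx = {c: header.index(c) for c in header}
    out = []
    for i, row in enumerate(rows, start=1):
        opt = lambda c: (None if row[idx[c]].strip() == ""  # noqa: E731
                         else _float(row[idx[c]], c, i))
        out.append(
            GroupSummary(
                label=row[idx["species"]].strip(),
                n=int(row[idx["n"]]),
                mean_area=_float(row[idx["area_A2"]], "area_A2", i),
                mean_volume=_float(row[idx["volume_A3"]], "volume_A3", i),
                mean_dipole=_float(row[idx["dipole_debye"]], "dipole_debye", i),
                mean_dv=_float(row[idx["dv"]], "dv", i),
                mean_abl=opt("abl_A"),
                mean_energy=_float(row[idx["energy_J"]], "energy_J", i),
                best_asf=opt("asf_best"),
                mean_asf=opt("asf_mean"),
            )
        )
    return out


def write_group_table(groups: list[GroupSummary], destination: str | Path) -> None:
    with open(destination, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "area_A2", "volume_A3", "dipole_debye", "dv",
                         "abl_A", "energy_J", "asf_best", "asf_mean", "n"])
        for g in groups:
            fmt = lambda v: "" if v is None else repr(v)  # noqa: E731
            writer.writerow([g.label, repr(g.mean_area), repr(g.mean_volume),
                             repr(g.mean_dipole), repr(g.mean_dv), fmt(g.mean_abl),
                             repr(g.mean_energy), fmt(g.best_asf), fmt(g.mean_asf), g.n])


def read_results_table(source: str | Path | IO[str], dialect: str = "csv") -> list[ASFResult]:
    """Read a score-card table written by :func:`write_results_table`."""
    header, rows = _rows(source, dialect)
    _require(header, RESULT_COLUMNS)
    idx = {c: header.index(c) for c in header}
    out = []
    for i, row in enumerate(rows, start=1):
        rank_cell = row[idx["rank"]].strip()
        reasons = tuple(f for f in row[idx["filter_reasons"]].split(";") if f)
        out.append(
            ASFResult(
                complex_id=row[idx["complex_id"]].strip(),
                asf=_float(row[idx["asf_Jm_per_D"]], "asf_Jm_per_D", i),
                average_bond_length=_float(row[idx["abl_A"]], "abl_A", i),
                dv_ratio=_float(row[idx["dv_D_per_A3"]], "dv_D_per_A3", i),
                passed_filters=row[idx["passed"]].strip().lower() == "true",
                filter_reasons=reasons,
                rank=None if rank_cell == "" else int(rank_cell),
                donors=tuple(lab.strip() for lab in row[idx["donors"]].split(",") if lab.strip()),
            )
        )
    return out


def write_results_table(results: list[ASFResult], destination: str | Path | IO[str]) -> None:
    def emit(fh: IO[str]) -> None:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for r in results:
            writer.writerow([
                r.complex_id, ",".join(r.donors), repr(r.asf),
                repr(r.average_bond_length), repr(r.dv_ratio),
                str(r.passed_filters).lower(), ";".join(r.filter_reasons),
                "" if r.rank is None else r.rank,
            ])

    if isinstance(destination, (str, Path)):
        with open(destination, "w", newline="", encoding="utf-8") as fh:
            emit(fh)
    else:
        emit(destination)


def fixture_path(table_name: str) -> Path:
    """Filesystem path of a packaged reference table."""
    if table_name not in FIXTURE_NAMES:
        raise FixtureLookupError(
            f"unknown fixture {table_name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        )
    return Path(str(resources.files("asfscreen.data") / f"{table_name}.csv"))


def load_fixture(table_name: str):
    """Load a packaged reference table by name.

    ``table1`` -> solvent ladder (:class:`SolventReference` rows),
    ``table2`` ... ``table7`` -> complex descriptors with the printed
    ABL/D-V/ASF columns attached, ``table8`` -> per-species summaries.
    """
    path = fixture_path(table_name)
    if table_name == "table1":
        return read_solvent_table(path)
    if table_name == "table8":
        return read_group_table(path)
    return read_descriptor_table(path, strict=False)


def toy_structure_path() -> Path:
    """Path of the packaged toy 3D structure (8 O + 1 N donors)."""
    return Path(str(resources.files("asfscreen.data") / "toy_donors.sdf"))
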