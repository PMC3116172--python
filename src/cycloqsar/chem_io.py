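"""Reading and writing compound structures and activity tables.

The atomic unit of the dataset is a :class:`CompoundRecord`: one molecule
plus its measured IC50 (µg/mL) against each assayed cell line.  Record
order is preserved everywhere because the diversity-based dataset division
is seeded from the first record of the file.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Cell lines assayed in the cyclopamine-derivative study, in canonical order.
CELL_LINES: tuple[str, ...] = ("BxPC-3", "NCI-H446", "SW1990", "NCI-H157")

#: IC50 (µg/mL) of the positive control (cyclopamine) per cell line; used as
#: the activity cut-off when binarizing continuous IC50 data.
CYCLOPAMINE_IC50: dict[str, float] = {
    "BxPC-3": 38.11,
    "NCI-H446": 9.13,
    "SW1990": 61.05,
    "NCI-H157": 58.33,
}


class EmptyLibraryError(ValueError):
    """Raised when an input yields zero usable compounds."""


@dataclass
class Molecule:
    """A compound structure with a stable identifier.

    The molecular graph is held as an RDKit Mol; ``smiles`` caches the
    canonical SMILES for hashing and round-tripping.
    """

    id: str
    mol: Chem.Mol

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    @property
    def num_atoms(self) -> int:
        return self.mol.GetNumAtoms()


@dataclass
class ParseFailure:
    """A structure record that could not be parsed."""

    index: int
    reason: str
    raw: str = ""


@dataclass
class CompoundRecord:
    molecule: Molecule
    #: cell line -> IC50 in µg/mL; ``None`` marks a missing measurement.
    activities: dict[str, Optional[float]]

    def ic50(self, cell_line: str) -> Optional[float]:
        return self.activities.get(cell_line)


@dataclass
class CompoundLibrary:
    records: list[CompoundRecord]
    cell_lines: tuple[str, ...] = CELL_LINES
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.molecule.id for r in self.records]

    @property
    def molecules(self) -> list[Molecule]:
        return [r.molecule for r in self.records]

    def summary_csv(self, path: str | Path) -> None:
        """Write a per-compound summary (id, SMILES, IC50 per cell line)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "smiles", *self.cell_lines])
            for rec in self.records:
                row = [rec.molecule.id, rec.molecule.smiles]
                for cl in self.cell_lines:
                    v = rec.activities.get(cl)
                    row.append("" if v is None else repr(v))
                w.writerow(row)

    def write_smiles(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(f"{rec.molecule.smiles}\t{rec.molecule.id}\n")

    def write_activities(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", *self.cell_lines])
            for rec in self.records:
                row = [rec.molecule.id]
                for cl in self.cell_lines:
                    v = rec.activities.get(cl)
                    row.append("" if v is None else repr(v))
                w.writerow(row)


def read_structures(
    path: str | Path, fmt: str = "smiles"
) -> tuple[list[Molecule], list[ParseFailure]]:
    """Read molecules from a SMILES (one per line, optional id) or SDF file.

    Invalid records are reported in the failure list, never silently
    dropped.  Raises :class:`EmptyLibraryError` if no record parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mols: list[Molecule] = []
    failures: list[ParseFailure] = []
    if fmt == "smiles":
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                smi = parts[0]
                mid = parts[1] if len(parts) > 1 else f"M{len(mols) + 1}"
                m = Chem.MolFromSmiles(smi)
                if m is None:
                    failures.append(ParseFailure(i, "unparsable SMILES", line))
                else:
                    mols.append(Molecule(mid, m))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, m in enumerate(supplier):
            if m is None:
                failures.append(ParseFailure(i, "unparsable SDF record"))
                continue
            mid = m.GetProp("_Name") if m.HasProp("_Name") and m.GetProp("_Name") else f"M{len(mols) + 1}"
            mols.append(Molecule(mid, m))
    else:
        raise ValueError(f"unknown structure format: {fmt!r}")
    if not mols:
        raise EmptyLibraryError(f"no valid molecules in {path}")
    return mols, failures


def read_activity_table(
    path: str | Path, id_column: str = "id"
) -> dict[str, dict[str, Optional[float]]]:
    """Read a CSV activity table: id column plus one IC50 column per cell line.

    Blank cells become missing values (``None``).  Duplicate ids or
    non-numeric non-blank cells raise ``ValueError`` naming the offender.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, dict[str, Optional[float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or id_column not in reader.fieldnames:
            raise ValueError(f"activity table must have a header with an {id_column!r} column")
        cell_cols = [c for c in reader.fieldnames if c != id_column]
        for rownum, row in enumerate(reader, start=2):
            cid = row[id_column]
            if cid in out:
                raise ValueError(f"duplicate compound id {cid!r} at row {rownum}")
            acts: dict[str, Optional[float]] = {}
            for col in cell_cols:
                cell = (row[col] or "").strip()
                if cell == "":
                    acts[col] = None
                    continue
                try:
                    acts[col] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric IC50 {cell!r} at row {rownum}, column {col!r}"
                    ) from None
            out[cid] = acts
    return out


def join_library(
    molecules: Sequence[Molecule],
    activity_map: Mapping[str, Mapping[str, Optional[float]]],
    cell_lines: Iterable[str] = CELL_LINES,
    strict: bool = True,
) -> CompoundLibrary:
    """Join structures with their activity rows, preserving molecule order.

    In strict mode every molecule must have an activity row.  In permissive
    mode unmatched molecules are kept with all-missing activities and
    recorded in the library warnings.
    """
    cell_lines = tuple(cell_lines)
    seen = set()
    for m in molecules:
        if m.id in seen:
            raise ValueError(f"duplicate molecule id {m.id!r}")
        seen.add(m.id)
    matched = [m for m in molecules if m.id in activity_map]
    if not matched:
        raise EmptyLibraryError("no molecule id matches any activity row")
    records: list[CompoundRecord] = []
    warnings: list[str] = []
    for m in molecules:
        if m.id in activity_map:
            acts = {cl: activity_map[m.id].get(cl) for cl in cell_lines}
            for cl, v in acts.items():
                if v is not None and v <= 0:
                    raise ValueError(f"non-positive IC50 {v} for {m.id!r}/{cl}")
        else:
            if strict:
                raise ValueError(f"molecule {m.id!r} has no activity row")
            acts = {cl: None for cl in cell_lines}
            warnings.append(f"no activity row for molecule {m.id!r}")
        records.append(CompoundRecord(m, acts))
    return CompoundLibrary(records, cell_lines, warnings)
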