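"""Molecule ingestion, standardization, and result-table output.

Structures are read from SMILES, SDF (V2000) or CSV files into
:class:`MoleculeRecord` objects, pushed through a fixed standardization
pipeline (salt removal -> charge neutralization -> tautomer canonicalization
-> canonical SMILES), and screening/novelty results are written back out as
TSV/CSV tables.

Records that fail to parse or sanitize are carried along flagged
``valid=False`` with a reason; they are never silently dropped, and the
screening layers exclude (and count) them explicitly.
"""

from __future__ import annotations

import csv as _csv
import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger("fpscreen.chem_io")

# RDKit logs every sanitization complaint to stderr; invalid records are
# reported through MoleculeRecord.reason instead.
RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "InputError",
    "read_molecules",
    "standardize",
    "standardize_smiles",
    "write_table",
]


class InputError(ValueError):
    """Raised for unreadable, malformed, or inconsistent input files."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One library/query/actives entry.

    Attributes
    ----------
    id : str
        Non-empty identifier, unique within a collection.
    smiles_input : str
        The structure text exactly as read.
    smiles_canonical : str or None
        Canonical standardized SMILES; ``None`` until :func:`standardize`
        has been applied.
    source : str
        Provenance string, ``"<file>:<record index>"``.
    valid : bool
        False when parsing or standardization failed.
    reason : str or None
        Failure explanation; set exactly when ``valid`` is False.
    """

    id: str
    smiles_input: str
    smiles_canonical: str | None = None
    source: str = ""
    valid: bool = True
    reason: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("MoleculeRecord.id must be non-empty")
        if not self.valid and not self.reason:
            raise ValueError("invalid records must carry a reason")


# Standardization helpers are module-level singletons: construction of the
# tautomer canonicalizer is expensive.
_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMERIZER = rdMolStandardize.TautomerEnumerator()


def standardize_smiles(smiles: str) -> str:
    """Standardize one SMILES string and return the canonical form.

    Pipeline order is fixed: (1) keep the largest organic fragment (salt
    removal), (2) neutralize charges where chemically valid, (3)
    canonicalize the tautomer, (4) emit canonical SMILES.  The operation is
    idempotent: feeding the output back in returns it unchanged.

    Raises
    ------
    ValueError
        If the SMILES does not parse or fails sanitization.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES does not parse/sanitize: {smiles!r}")
    mol = _FRAGMENT_CHOOSER.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    mol = _TAUTOMERIZER.Canonicalize(mol)
    return Chem.MolToSmiles(mol)


def standardize(record: MoleculeRecord) -> MoleculeRecord:
    """Return a copy of *record* with ``smiles_canonical`` set.

    Records that fail any pipeline stage come back flagged ``valid=False``
    with the failure reason; already-invalid records pass through unchanged.
    """
    if not record.valid:
        return record
    try:
        canonical = standardize_smiles(record.smiles_input)
    except Exception as exc:  # rdkit raises several exception types
        return replace(record, valid=False, reason=f"standardization failed: {exc}")
    return replace(record, smiles_canonical=canonical)


def _check_unique_ids(records: Sequence[MoleculeRecord]) -> None:
    seen: dict[str, int] = {}
    dups: list[str] = []
    for rec in records:
        if rec.id in seen:
            dups.append(rec.id)
        seen[rec.id] = seen.get(rec.id, 0) + 1
    if dups:
        raise InputError(f"duplicate ids in input: {sorted(set(dups))}")


def _read_smiles_file(path: Path) -> list[MoleculeRecord]:
    records: list[MoleculeRecord] = []
    with path.open() as fh:
        idx = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol{idx + 1}"
            records.append(_parse_entry(mol_id, smiles, f"{path}:{lineno}"))
            idx += 1
    return records


def _parse_entry(mol_id: str, smiles: str, source: str) -> MoleculeRecord:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        logger.warning("record %s (%s): unparseable SMILES %r", mol_id, source, smiles)
        return MoleculeRecord(
            id=mol_id,
            smiles_input=smiles,
            source=source,
            valid=False,
            reason=f"SMILES does not parse/sanitize: {smiles!r}",
        )
    return MoleculeRecord(id=mol_id, smiles_input=smiles, source=source)


def _read_sdf_file(path: Path) -> list[MoleculeRecord]:
    records: list[MoleculeRecord] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for idx, mol in enumerate(supplier):
        source = f"{path}:{idx}"
        if mol is None:
            logger.warning("record %d (%s): unreadable SDF block", idx, source)
            records.append(
                MoleculeRecord(
                    id=f"sdf{idx + 1}",
                    smiles_input="",
                    source=source,
                    valid=False,
                    reason="SDF record failed to parse/sanitize",
                )
            )
            continue
        name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        mol_id = name or f"sdf{idx + 1}"
        records.append(
            MoleculeRecord(id=mol_id, smiles_input=Chem.MolToSmiles(mol), source=source)
        )
    return records


def _read_csv_file(
    path: Path, id_column: str | None, smiles_column: str | None
) -> list[MoleculeRecord]:
    if id_column is None or smiles_column is None:
        raise InputError("csv input requires id_column and smiles_column")
    with path.open(newline="") as fh:
        reader = _csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in (id_column, smiles_column) if c not in header]
        if missing:
            raise InputError(f"csv {path} lacks declared column(s) {missing}; has {header}")
        records = [
            _parse_entry(
                str(row[id_column]).strip(),
                str(row[smiles_column]).strip(),
                f"{path}:{lineno}",
            )
            for lineno, row in enumerate(reader, start=2)
        ]
    return records


def read_molecules(
    path: str | Path,
    format: str | None = None,
    *,
    id_column: str | None = None,
    smiles_column: str | None = None,
) -> list[MoleculeRecord]:
    """Read molecules from *path* into an ordered list of records.

    Parameters
    ----------
    path : path-like
        Input file.
    format : {"smiles", "sdf", "csv"}, optional
        Inferred from the file suffix (.smi/.smiles, .sdf, .csv) when omitted.
    id_column, smiles_column : str, optional
        Column mapping; required for CSV input.

    Input order is preserved; unparseable entries come back ``valid=False``
    with a reason.  Duplicate ids are a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format is None:
        format = {
            ".smi": "smiles",
            ".smiles": "smiles",
            ".txt": "smiles",
            ".sdf": "sdf",
            ".csv": "csv",
        }.get(path.suffix.lower())
        if format is None:
            raise InputError(f"cannot infer format from suffix of {path}")
    if format == "smiles":
        records = _read_smiles_file(path)
    elif format == "sdf":
        records = _read_sdf_file(path)
    elif format == "csv":
        records = _read_csv_file(path, id_column, smiles_column)
    else:
        raise InputError(f"unknown format {format!r}; expected smiles|sdf|csv")
    _check_unique_ids(records)
    n_bad = sum(not r.valid for r in records)
    logger.info("read %d records from %s (%d invalid)", len(records), path, n_bad)
    return records


def round_half_away(value: float, decimals: int) -> str:
    """Render *value* with ties rounded away from zero at *decimals* places.

    Plain float formatting rounds ties to even; result tables instead use
    the convention that e.g. -3.0135 at 3 decimals becomes "-3.014".
    """
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def write_table(
    rows: Sequence,
    path: str | Path,
    format: str = "tsv",
    *,
    columns: Sequence[str] | None = None,
) -> None:
    """Write ScreenRow or NoveltyRow objects as a delimited table.

    Distances, normalized scores and consensus values are rendered with 3
    decimals, Tanimoto similarities with 4; full precision is retained on
    the row objects themselves.  An empty collection produces a header-only
    file; pass *columns* to name the header in that case (it is otherwise
    taken from the rows).
    """
    if format not in ("tsv", "csv"):
        raise InputError(f"unknown table format {format!r}; expected tsv|csv")
    sep = "\t" if format == "tsv" else ","
    path = Path(path)
    kinds = {type(r).__name__ for r in rows}
    if len(kinds) > 1:
        raise InputError(f"heterogeneous row collection: {sorted(kinds)}")
    lines: list[str] = []
    if rows:
        header, render = rows[0]._table_spec()
        lines.append(sep.join(header))
        lines.extend(sep.join(render(r)) for r in rows)
    elif columns is not None:
        lines.append(sep.join(columns))
    try:
        path.write_text("".join(line + "\n" for line in lines))
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc
    logger.info("wrote %d rows to %s", len(rows), path)
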