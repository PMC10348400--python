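"""Reading, validation and curation of molecule tables and target annotations.

Raw species tables (CSV / SDF / SMILES files) are curated into
:class:`MoleculeRecord` objects: SMILES are canonicalized with RDKit,
duplicate structures and duplicate CAS registry numbers are collapsed
(first occurrence wins), and rows with missing or corrupted SMILES are
dropped and counted in a :class:`CurationReport`.

Molecule -> protein-target annotations (gene symbol, UniProt accession,
assay id, activity) are read from CSV and referentially checked against the
curated molecule set.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .errors import DataError, SchemaError, SmilesParseError

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "MoleculeRecord",
    "TargetAnnotation",
    "CurationReport",
    "parse_and_canonicalize",
    "element_inventory",
    "clean_species_table",
    "read_molecule_table",
    "read_structure_file",
    "read_target_annotations",
]


@dataclass
class MoleculeRecord:
    """One curated chemical species.

    ``elements`` always includes hydrogen when the molecular formula does
    (implicit hydrogens are counted). ``is_single_element`` marks monoatomic
    / elemental species (e.g. ``[Pb]``), which downstream are routed to the
    separate descriptor/quantum element spaces.
    """

    mol_id: str
    name: str
    smiles_input: str
    smiles_canonical: str
    cas: str | None = None
    inchikey: str | None = None
    formula: str | None = None
    elements: set[str] = field(default_factory=set)
    is_single_element: bool = False
    is_multifragment: bool = False

    @property
    def mol(self) -> Chem.Mol:
        """Parsed RDKit structure handle (re-parsed from the canonical SMILES)."""
        mol = Chem.MolFromSmiles(self.smiles_canonical)
        if mol is None:  # pragma: no cover - canonical SMILES always parse
            raise SmilesParseError(self.smiles_canonical)
        return mol


@dataclass(frozen=True)
class TargetAnnotation:
    """A molecule -> protein-target link derived from bioassay data."""

    mol_id: str
    gene_symbol: str
    uniprot: str | None = None
    assay_id: str | None = None
    activity_name: str | None = None
    activity_value_um: float | None = None


@dataclass
class CurationReport:
    n_input: int = 0
    n_kept: int = 0
    n_dropped_duplicate: int = 0
    n_dropped_bad_smiles: int = 0
    dropped_ids: list[str] = field(default_factory=list)

    def check(self) -> None:
        """Assert the count identity n_input = kept + duplicate + bad."""
        if self.n_input != self.n_kept + self.n_dropped_duplicate + self.n_dropped_bad_smiles:
            raise ValueError("CurationReport counts do not reconcile")


def parse_and_canonicalize(smiles: str) -> tuple[Chem.Mol, str]:
    """Parse a SMILES string and return ``(mol, canonical_smiles)``.

    Canonicalization is idempotent: feeding the canonical form back returns
    the same string.

    Raises
    ------
    SmilesParseError
        If the string is empty or RDKit cannot parse it.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles, "empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol, Chem.MolToSmiles(mol)


def element_inventory(mol: Chem.Mol) -> set[str]:
    """Unique element symbols in a molecule, implicit hydrogens included."""
    symbols = {atom.GetSymbol() for atom in mol.GetAtoms()}
    if any(atom.GetTotalNumHs() > 0 for atom in mol.GetAtoms()) or any(
        atom.GetSymbol() == "H" for atom in mol.GetAtoms()
    ):
        symbols.add("H")
    return symbols


def _make_record(mol_id: str, name: str, cas: str | None, smiles: str) -> MoleculeRecord:
    mol, canonical = parse_and_canonicalize(smiles)
    elements = element_inventory(mol)
    try:
        inchikey = Chem.MolToInchiKey(mol) or None
    except Exception:
        inchikey = None
    formula = Chem.rdMolDescriptors.CalcMolFormula(mol)
    return MoleculeRecord(
        mol_id=mol_id,
        name=name,
        cas=cas or None,
        smiles_input=smiles,
        smiles_canonical=canonical,
        inchikey=inchikey,
        formula=formula,
        elements=elements,
        is_single_element=len(elements) == 1,
        is_multifragment="." in canonical,
    )


def clean_species_table(
    rows: Sequence[Mapping[str, object]],
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Curate raw molecule rows into unique, parseable records.

    Each row needs at least ``name`` and ``smiles``; ``mol_id`` and ``cas``
    are optional (a missing mol_id is synthesized from the row position).
    One record is kept per unique canonical structure; on duplicate CAS or
    duplicate canonical SMILES the first occurrence wins. Rows whose SMILES
    is empty or unparseable are dropped and counted.
    """
    if not rows:
        raise DataError("no molecules")
    for col in ("name", "smiles"):
        if col not in rows[0]:
            raise SchemaError(f"missing required column: {col!r}")

    records: list[MoleculeRecord] = []
    report = CurationReport(n_input=len(rows))
    seen_cas: set[str] = set()
    seen_canonical: set[str] = set()
    seen_ids: set[str] = set()
    for i, row in enumerate(rows):
        mol_id = str(row.get("mol_id") or f"M{i + 1:06d}")
        name = str(row.get("name") or "")
        cas = str(row.get("cas") or "") or None
        smiles = str(row.get("smiles") or "")
        try:
            record = _make_record(mol_id, name, cas, smiles)
        except SmilesParseError:
            report.n_dropped_bad_smiles += 1
            report.dropped_ids.append(mol_id)
            continue
        if (
            (cas is not None and cas in seen_cas)
            or record.smiles_canonical in seen_canonical
            or mol_id in seen_ids
        ):
            report.n_dropped_duplicate += 1
            report.dropped_ids.append(mol_id)
            continue
        if cas is not None:
            seen_cas.add(cas)
        seen_canonical.add(record.smiles_canonical)
        seen_ids.add(mol_id)
        records.append(record)
    report.n_kept = len(records)
    report.check()
    return records, report


def read_molecule_table(path: str | Path) -> list[dict[str, str]]:
    """Read a molecule CSV (columns mol_id,name,cas,smiles; header required)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header required")
        missing = {"name", "smiles"} - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing required column: {sorted(missing)[0]!r}")
        return [dict(row) for row in reader]


def read_structure_file(path: str | Path) -> list[dict[str, str]]:
    """Read molecules from an SDF or one-SMILES-per-line file into raw rows."""
    path = Path(path)
    rows: list[dict[str, str]] = []
    if path.suffix.lower() == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                rows.append({"mol_id": f"SDF{i + 1:06d}", "name": "", "smiles": ""})
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            rows.append(
                {
                    "mol_id": name or f"SDF{i + 1:06d}",
                    "name": name,
                    "smiles": Chem.MolToSmiles(mol),
                }
            )
    else:
        for i, line in enumerate(path.read_text(encoding="utf-8").splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else ""
            rows.append({"mol_id": name or f"SMI{i + 1:06d}", "name": name, "smiles": smiles})
    return rows


def read_target_annotations(
    path: str | Path,
    known_mol_ids: Iterable[str] | None = None,
) -> list[TargetAnnotation]:
    """Read molecule->target annotations from CSV.

    Rows are deduplicated on ``(mol_id, gene_symbol, assay_id)``. When
    ``known_mol_ids`` is given, annotations for unknown molecules are kept
    out and reported with a warning, never an error.
    """
    path = Path(path)
    known = set(known_mol_ids) if known_mol_ids is not None else None
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header required")
        missing = {"mol_id", "gene_symbol"} - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing required column: {sorted(missing)[0]!r}")
        annotations: list[TargetAnnotation] = []
        seen: set[tuple[str, str, str | None]] = set()
        n_unknown = 0
        for row in reader:
            mol_id = (row.get("mol_id") or "").strip()
            gene = (row.get("gene_symbol") or "").strip()
            if not mol_id or not gene:
                continue
            if known is not None and mol_id not in known:
                n_unknown += 1
                continue
            assay = (row.get("assay_id") or "").strip() or None
            key = (mol_id, gene, assay)
            if key in seen:
                continue
            seen.add(key)
            value = (row.get("activity_value_um") or "").strip()
            annotations.append(
                TargetAnnotation(
                    mol_id=mol_id,
                    gene_symbol=gene,
                    uniprot=(row.get("uniprot") or "").strip() or None,
                    assay_id=assay,
                    activity_name=(row.get("activity_name") or "").strip() or None,
                    activity_value_um=float(value) if value else None,
                )
            )
    if n_unknown:
        warnings.warn(f"{n_unknown} annotation rows refer to unknown mol_ids and were skipped")
    return annotations
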