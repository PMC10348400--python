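"""Feature matrices feeding the four chemical spaces.

Fingerprint families computed with RDKit:

``maccs``
    166 MACCS structural keys (binary only).
``estate``
    79 electrotopological (E-state) atom types of Kier and Hall, as
    presence/absence or occurrence counts.
``path_hashed``
    Hashed fingerprint over bond paths up to length 8 folded into 1024 bits
    (binary).
``atom_pairs``
    Atom pairs at their topological distances; columns are the vocabulary
    of pair codes observed in the input set (binary or counts).
``smarts_set``
    Presence or count of an arbitrary SMARTS pattern list (binary or
    counts); a builtin functional-group set is used when none is supplied.

Continuous molecular-descriptor / quantum-property tables are ingested from
CSV (they come from external descriptor software, not computed here) into
``FeatureBlock`` objects with an explicit missing-value mask. Single-element
(monoatomic) species are split from descriptor/quantum blocks into separate
element blocks, since their descriptor profiles are not comparable with
polyatomic molecules.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys
from rdkit.Chem.AtomPairs import Pairs
from rdkit.Chem.EState import Fingerprinter as EStateFingerprinter

from .chem_io import MoleculeRecord
from .errors import DataError, SchemaError, ValidationError
from .smarts_sets import BUILTIN_SMARTS

__all__ = [
    "FeatureBlock",
    "FINGERPRINT_FAMILIES",
    "compute_fingerprint_block",
    "smarts_pattern_fingerprint",
    "load_descriptor_block",
    "read_smarts_file",
    "filter_single_elements",
]

COUNT_CAP = 2**15 - 1

DISCRETE_LABELS = ("fingerprint_bits", "fingerprint_counts")
CONTINUOUS_LABELS = ("descriptors", "quantum", "descriptors_elements", "quantum_elements")
SPACE_LABELS = DISCRETE_LABELS + CONTINUOUS_LABELS

FINGERPRINT_FAMILIES: dict[str, tuple[str, ...]] = {
    "maccs": ("binary",),
    "path_hashed": ("binary",),
    "estate": ("binary", "count"),
    "atom_pairs": ("binary", "count"),
    "smarts_set": ("binary", "count"),
}


@dataclass
class FeatureBlock:
    """A molecules x features matrix with a declared kind.

    Binary blocks contain only {0,1}; count blocks non-negative integers;
    continuous blocks carry a same-shape ``missing_mask``.
    """

    space_label: str
    mol_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    kind: str
    missing_mask: np.ndarray | None = None
    zero_rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.mol_ids), len(self.feature_names)):
            raise ValidationError("values shape does not match mol_ids x feature_names")
        if len(set(self.mol_ids)) != len(self.mol_ids):
            raise ValidationError("mol_ids must be unique")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("feature_names must be unique")
        if self.kind == "binary" and not np.isin(self.values, (0, 1)).all():
            raise ValidationError("binary block contains values outside {0,1}")
        if self.kind == "count":
            if (self.values < 0).any() or not np.issubdtype(self.values.dtype, np.integer):
                raise ValidationError("count block must hold non-negative integers")
        if self.kind == "continuous" and self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)

    @property
    def n_molecules(self) -> int:
        return len(self.mol_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.mol_ids, columns=self.feature_names)


def _maccs_vector(mol: Chem.Mol) -> np.ndarray:
    # RDKit emits 167 bits with bit 0 always unset; keys are 1..166
    bits = np.array(MACCSkeys.GenMACCSKeys(mol), dtype=np.int64)
    return bits[1:]


def _estate_counts(mol: Chem.Mol) -> np.ndarray:
    counts, _sums = EStateFingerprinter.FingerprintMol(mol)
    return np.asarray(counts, dtype=np.int64)


def _path_hashed_vector(mol: Chem.Mol, n_bits: int = 1024, max_path: int = 8) -> np.ndarray:
    fp = Chem.RDKFingerprint(mol, maxPath=max_path, fpSize=n_bits)
    return np.array(fp, dtype=np.int64)


def compute_fingerprint_block(
    molecules: Sequence[MoleculeRecord],
    family: str,
    mode: str = "binary",
    patterns: Sequence[str] | None = None,
    space_label: str | None = None,
) -> FeatureBlock:
    """Compute one fingerprint family over a molecule list.

    Rows align with the input order. A molecule for which the fingerprint
    computation fails yields a zero row plus a warning (inorganics stay in
    the bit spaces; zero rows are excluded later from cosine similarity).
    """
    if family not in FINGERPRINT_FAMILIES:
        raise ValidationError(f"unknown fingerprint family: {family!r}")
    if mode not in FINGERPRINT_FAMILIES[family]:
        raise ValidationError(f"family {family!r} does not support mode {mode!r}")
    if family == "smarts_set":
        return smarts_pattern_fingerprint(
            molecules, patterns if patterns is not None else BUILTIN_SMARTS, mode, space_label
        )

    label = space_label or ("fingerprint_counts" if mode == "count" else "fingerprint_bits")

    if family == "atom_pairs":
        per_mol: list[dict[int, int]] = []
        zero_rows: list[str] = []
        for rec in molecules:
            try:
                nz = Pairs.GetAtomPairFingerprint(rec.mol).GetNonzeroElements()
            except Exception:
                warnings.warn(f"atom_pairs failed for {rec.mol_id}; zero row emitted")
                nz = {}
            if not nz:
                zero_rows.append(rec.mol_id)
            per_mol.append(dict(nz))
        vocab = sorted(set().union(*per_mol)) if per_mol else []
        values = np.zeros((len(molecules), len(vocab)), dtype=np.int64)
        index = {code: j for j, code in enumerate(vocab)}
        for i, nz in enumerate(per_mol):
            for code, count in nz.items():
                values[i, index[code]] = min(count, COUNT_CAP)
        names = [f"ap_{code}" for code in vocab]
        if mode == "binary":
            values = (values > 0).astype(np.int64)
        return FeatureBlock(label, [r.mol_id for r in molecules], names, values,
                            mode, zero_rows=zero_rows)

    compute = {
        "maccs": _maccs_vector,
        "estate": _estate_counts,
        "path_hashed": _path_hashed_vector,
    }[family]
    width = {"maccs": 166, "estate": 79, "path_hashed": 1024}[family]
    prefix = {"maccs": "maccs_", "estate": "estate_", "path_hashed": "path_"}[family]
    rows = []
    zero_rows = []
    for rec in molecules:
        try:
            vec = compute(rec.mol)
        except Exception:
            warnings.warn(f"{family} failed for {rec.mol_id}; zero row emitted")
            vec = np.zeros(width, dtype=np.int64)
        if not vec.any():
            zero_rows.append(rec.mol_id)
        rows.append(np.minimum(vec, COUNT_CAP))
    values = np.vstack(rows) if rows else np.zeros((0, width), dtype=np.int64)
    if mode == "binary":
        values = (values > 0).astype(np.int64)
    names = [f"{prefix}{k + 1}" for k in range(width)]
    return FeatureBlock(label, [r.mol_id for r in molecules], names, values,
                        mode, zero_rows=zero_rows)


def smarts_pattern_fingerprint(
    molecules: Sequence[MoleculeRecord],
    patterns: Sequence[str],
    mode: str = "binary",
    space_label: str | None = None,
) -> FeatureBlock:
    """Presence (binary) or number of distinct matches (count) per SMARTS pattern.

    Column order follows the pattern order. An invalid SMARTS raises an
    error naming the pattern index.
    """
    if mode not in ("binary", "count"):
        raise ValidationError(f"unsupported mode: {mode!r}")
    compiled = []
    for idx, pattern in enumerate(patterns):
        query = Chem.MolFromSmarts(pattern)
        if query is None:
            raise ValidationError(f"invalid SMARTS at index {idx}: {pattern!r}")
        compiled.append(query)
    values = np.zeros((len(molecules), len(compiled)), dtype=np.int64)
    zero_rows = []
    for i, rec in enumerate(molecules):
        mol = rec.mol
        for j, query in enumerate(compiled):
            n = len(mol.GetSubstructMatches(query, uniquify=True))
            values[i, j] = min(n, COUNT_CAP)
        if not values[i].any():
            zero_rows.append(rec.mol_id)
    if mode == "binary":
        values = (values > 0).astype(np.int64)
    label = space_label or ("fingerprint_counts" if mode == "count" else "fingerprint_bits")
    names = [f"smarts_{j}" for j in range(len(compiled))]
    return FeatureBlock(label, [r.mol_id for r in molecules], names, values,
                        mode, zero_rows=zero_rows)


def read_smarts_file(path: str | Path) -> list[str]:
    """Read SMARTS patterns, one per line; '#' starts a comment."""
    patterns = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            patterns.append(line)
    return patterns


def load_descriptor_block(path: str | Path, space_label: str) -> FeatureBlock:
    """Ingest a continuous descriptor / quantum-property CSV.

    First column must be ``mol_id``; remaining columns numeric with blanks
    allowed (recorded in the missing mask). Constant (zero-variance)
    columns are dropped with a warning.
    """
    if space_label not in CONTINUOUS_LABELS:
        raise ValidationError(f"space_label must be continuous, got {space_label!r}")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        if not header or header[0] != "mol_id":
            raise SchemaError(f"{path}: first column must be 'mol_id'")
        feature_names = header[1:]
        mol_ids: list[str] = []
        data: list[list[float]] = []
        mask: list[list[bool]] = []
        for r, row in enumerate(reader, start=2):
            mol_ids.append(row[0])
            vals, miss = [], []
            for c, cell in enumerate(row[1:], start=1):
                cell = cell.strip()
                if cell == "":
                    vals.append(np.nan)
                    miss.append(True)
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise SchemaError(
                        f"{path}: non-numeric cell at row {r}, column {header[c]!r}: {cell!r}"
                    ) from None
                miss.append(False)
            data.append(vals)
            mask.append(miss)
    if not mol_ids:
        raise DataError(f"{path}: no data rows")
    values = np.asarray(data, dtype=float)
    missing = np.asarray(mask, dtype=bool)
    all_missing_rows = missing.all(axis=1)
    if all_missing_rows.any():
        bad = [mol_ids[i] for i in np.flatnonzero(all_missing_rows)]
        raise DataError(f"{path}: all-missing rows for {bad}")
    return _drop_constant_columns(
        FeatureBlock(space_label, mol_ids, list(feature_names), values, "continuous", missing)
    )


def _drop_constant_columns(block: FeatureBlock) -> FeatureBlock:
    values, missing = block.values, block.missing_mask
    keep = []
    for j in range(values.shape[1]):
        observed = values[~missing[:, j], j]
        if observed.size and np.ptp(observed) > 0:
            keep.append(j)
    dropped = [block.feature_names[j] for j in range(values.shape[1]) if j not in set(keep)]
    if dropped:
        warnings.warn(f"dropping constant columns: {dropped}")
    return FeatureBlock(
        block.space_label,
        block.mol_ids,
        [block.feature_names[j] for j in keep],
        values[:, keep],
        "continuous",
        missing[:, keep],
    )


def filter_single_elements(
    records: Sequence[MoleculeRecord], block: FeatureBlock
) -> tuple[FeatureBlock, FeatureBlock]:
    """Split single-element species out of a descriptor/quantum block.

    Returns ``(main, elements)``; the elements block carries the
    ``_elements`` suffixed space label. The row partition is exact.
    """
    if block.space_label not in ("descriptors", "quantum"):
        raise ValidationError(
            "single-element filtering applies only to descriptor/quantum blocks"
        )
    single = {r.mol_id for r in records if r.is_single_element}
    main_idx = [i for i, m in enumerate(block.mol_ids) if m not in single]
    elem_idx = [i for i, m in enumerate(block.mol_ids) if m in single]

    def _subset(indices: list[int], label: str) -> FeatureBlock:
        return FeatureBlock(
            label,
            [block.mol_ids[i] for i in indices],
            list(block.feature_names),
            block.values[indices],
            block.kind,
            None if block.missing_mask is None else block.missing_mask[indices],
            zero_rows=[m for m in block.zero_rows if m in {block.mol_ids[i] for i in indices}],
        )

    return (
        _subset(main_idx, block.space_label),
        _subset(elem_idx, block.space_label + "_elements"),
    )
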