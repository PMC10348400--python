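"""Synthetic datasets with known structure, plus the builtin case-study set.

``generate_planted_blocks`` emulates the three real input kinds the engine
consumes — binary/count fingerprint blocks, continuous descriptor and
quantum-property tables with missing cells, and molecule->target
annotations — while planting a known community structure: each community
has a prototype bit pattern, count profile and continuous centroid, and
members are noisy copies. Co-members preferentially share gene-symbol
targets. Everything is reproducible from one seed, so every pipeline stage
is testable offline with a known ground truth.

``builtin_case_set`` returns twelve inorganic and organic air-pollutant
molecules (queries and their reported nearest neighbors) keyed by PubChem
CID, with structures encoded here as SMILES constants.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem_io import MoleculeRecord, TargetAnnotation, clean_species_table
from .errors import ValidationError
from .features import FeatureBlock

__all__ = [
    "PlantedDataset",
    "generate_planted_blocks",
    "builtin_case_set",
    "write_dataset",
]


@dataclass
class PlantedDataset:
    """Synthetic molecules, feature blocks, community labels and annotations."""

    records: list[MoleculeRecord]
    blocks: dict[str, FeatureBlock]
    true_labels: dict[str, int]
    annotations: list[TargetAnnotation]
    seed: int
    params: dict = field(default_factory=dict)


def _synthetic_records(n: int) -> list[MoleculeRecord]:
    # distinct linear alcohols CH3(CH2)kOH: trivially valid, unique structures
    rows = [
        {"mol_id": f"SYN{i + 1:04d}", "name": f"synthetic-{i + 1}", "smiles": "C" * (i + 1) + "O"}
        for i in range(n)
    ]
    records, report = clean_species_table(rows)
    assert report.n_kept == n
    return records


def generate_planted_blocks(
    n_molecules: int = 60,
    n_communities: int = 3,
    n_binary_features: int = 200,
    n_count_features: int = 120,
    n_continuous_features: int = 80,
    within_noise: float = 0.02,
    missing_rate: float = 0.02,
    seed: int = 0,
    n_quantum_features: int = 20,
    p_target_within: float = 0.6,
    p_target_between: float = 0.1,
    individual_fraction: float = 0.4,
) -> PlantedDataset:
    """Generate a planted-community dataset covering all four chemical spaces.

    Each feature block mixes two feature groups. Community features carry
    the planted structure: a prototype bit pattern (bits flipped at
    ``within_noise`` in members), a prototype count profile (entries
    re-drawn from a Poisson at rate ``within_noise``) and continuous
    centroids Gaussian-perturbed with sd ``within_noise`` relative to unit
    centroid spread. The remaining ``individual_fraction`` of features is
    molecule-specific (stable idiosyncratic substructures / descriptor
    values, not noise), mirroring real chemical feature tables where
    molecules of one structural family still differ in many features; this
    keeps the reduced spaces at realistic rank instead of collapsing to one
    component per community. The quantum block is deliberately narrow
    (default 20 features) so the 90%-variance PCA branch is exercised.
    Unordered molecule pairs share a fresh gene-symbol target with
    probability ``p_target_within`` inside a community and
    ``p_target_between`` across communities.
    """
    if n_communities < 2:
        raise ValidationError("need at least 2 communities")
    if n_molecules < 2 * n_communities:
        raise ValidationError("need at least 2 molecules per community")
    for name, rate in (("within_noise", within_noise), ("missing_rate", missing_rate)):
        if not 0 <= rate < 1:
            raise ValidationError(f"{name} must be in [0,1)")

    if not 0 <= individual_fraction < 1:
        raise ValidationError("individual_fraction must be in [0,1)")

    rng = np.random.default_rng(seed)
    records = _synthetic_records(n_molecules)
    mol_ids = [r.mol_id for r in records]
    labels = np.arange(n_molecules) % n_communities
    true_labels = {m: int(c) for m, c in zip(mol_ids, labels)}

    def split(n_features: int) -> tuple[int, int]:
        n_ind = int(round(individual_fraction * n_features))
        return n_features - n_ind, n_ind

    # --- binary fingerprint block: prototype bits + flips, then individual bits
    n_comm, n_ind = split(n_binary_features)
    prototypes_bin = rng.integers(0, 2, size=(n_communities, n_comm))
    flips = rng.random((n_molecules, n_comm)) < within_noise
    community_bits = np.abs(prototypes_bin[labels] - flips.astype(np.int64))
    individual_bits = (rng.random((n_molecules, n_ind)) < 0.3).astype(np.int64)
    binary = np.hstack([community_bits, individual_bits])
    binary[binary.sum(axis=1) == 0, 0] = 1  # no all-zero rows
    block_bits = FeatureBlock(
        "fingerprint_bits", mol_ids, [f"bit_{j}" for j in range(n_binary_features)],
        binary.astype(np.int64), "binary",
    )

    # --- count block: sparse prototype profile (entries re-drawn Poisson at
    # the noise rate) plus sparse individual counts
    n_comm, n_ind = split(n_count_features)
    prototypes_cnt = (
        rng.poisson(3.0, size=(n_communities, n_comm))
        * (rng.random((n_communities, n_comm)) < 0.4)
    ).astype(np.int64)
    counts = prototypes_cnt[labels].copy()
    redraw = rng.random(counts.shape) < within_noise
    jitter = rng.poisson(np.maximum(prototypes_cnt[labels], 1))
    counts[redraw] = jitter[redraw]
    individual_cnt = (
        rng.poisson(3.0, size=(n_molecules, n_ind))
        * (rng.random((n_molecules, n_ind)) < 0.3)
    ).astype(np.int64)
    counts = np.hstack([counts, individual_cnt])
    counts[counts.sum(axis=1) == 0, 0] = 1
    block_counts = FeatureBlock(
        "fingerprint_counts", mol_ids, [f"cnt_{j}" for j in range(n_count_features)],
        counts, "count",
    )

    # --- continuous blocks: unit-spread centroids with sd=within_noise members
    # on community features; standard-normal molecule-specific values on the rest
    def continuous_block(label: str, n_features: int) -> FeatureBlock:
        n_comm, n_ind = split(n_features)
        centroids = rng.normal(0.0, 1.0, size=(n_communities, n_comm))
        community_vals = centroids[labels] + rng.normal(
            0.0, max(within_noise, 1e-9), size=(n_molecules, n_comm)
        )
        individual_vals = rng.normal(0.0, 1.0, size=(n_molecules, n_ind))
        values = np.hstack([community_vals, individual_vals])
        missing = rng.random(values.shape) < missing_rate
        # keep at least one observed cell per row and per column
        for i in np.flatnonzero(missing.all(axis=1)):
            missing[i, 0] = False
        for j in np.flatnonzero(missing.all(axis=0)):
            missing[0, j] = False
        values = values.copy()
        values[missing] = np.nan
        return FeatureBlock(
            label, mol_ids, [f"{label[:4]}_{j}" for j in range(n_features)],
            values, "continuous", missing,
        )

    block_desc = continuous_block("descriptors", n_continuous_features)
    block_quantum = continuous_block("quantum", n_quantum_features)

    annotations = _planted_annotations(
        mol_ids, labels, p_target_within, p_target_between, rng
    )

    return PlantedDataset(
        records=records,
        blocks={
            "fingerprint_bits": block_bits,
            "fingerprint_counts": block_counts,
            "descriptors": block_desc,
            "quantum": block_quantum,
        },
        true_labels=true_labels,
        annotations=annotations,
        seed=seed,
        params={
            "n_molecules": n_molecules,
            "n_communities": n_communities,
            "within_noise": within_noise,
            "missing_rate": missing_rate,
            "p_target_within": p_target_within,
            "p_target_between": p_target_between,
        },
    )


def _planted_annotations(
    mol_ids: Sequence[str],
    labels: np.ndarray,
    p_within: float,
    p_between: float,
    rng: np.random.Generator,
) -> list[TargetAnnotation]:
    """Pairwise construction: each sharing pair gets its own fresh gene.

    Realized within/between sharing rates therefore match the requested
    probabilities up to binomial noise. Every molecule additionally carries
    one private gene so all molecules are annotated.
    """
    genes: dict[str, set[str]] = {m: {f"PRIV_{m}"} for m in mol_ids}
    counter = 0
    n = len(mol_ids)
    for i in range(n):
        for j in range(i + 1, n):
            p = p_within if labels[i] == labels[j] else p_between
            if rng.random() < p:
                gene = f"SHARED{counter:06d}"
                counter += 1
                genes[mol_ids[i]].add(gene)
                genes[mol_ids[j]].add(gene)
    return [
        TargetAnnotation(mol_id=m, gene_symbol=g)
        for m in mol_ids
        for g in sorted(genes[m])
    ]


# Case-study air pollutants: four query molecules and their reported nearest
# neighbors, keyed by PubChem CID. SMILES encoded from the standard
# structures (the source tables print names and CIDs only).
CASE_SET: tuple[tuple[str, str, str], ...] = (
    ("32881", "2-(2-hydroxypropoxy)propan-1-ol", "CC(O)COC(C)CO"),
    ("_1m4nn", "1-methyl-4-nitronaphthalene", "Cc1ccc([N+](=O)[O-])c2ccccc12"),
    (
        "_hap",
        "hydroxyapatite",
        "[Ca+2].[Ca+2].[Ca+2].[Ca+2].[Ca+2].[OH-]."
        "[O-]P(=O)([O-])[O-].[O-]P(=O)([O-])[O-].[O-]P(=O)([O-])[O-]",
    ),
    ("_phosgene", "phosgene", "O=C(Cl)Cl"),
    ("10039", "carbonyl sulphide", "O=C=S"),
    ("59430", "carbon tetrachloride", "ClC(Cl)(Cl)Cl"),
    (
        "25477",
        "chrysotile",
        "[OH-].[OH-].[OH-].[OH-].[Mg+2].[Mg+2].[Mg+2].[O-][Si](=O)O[Si](=O)[O-]",
    ),
    ("9989226", "aluminium oxide", "O=[Al]O[Al]=O"),
    ("8087", "1,1'-oxydi-2-propanol", "CC(O)COCC(C)O"),
    ("15287", "1-ethoxy-2-propanol", "CCOCC(C)O"),
    ("93496", "1-methyl-5-nitronaphthalene", "Cc1cccc2c([N+](=O)[O-])cccc12"),
    ("86258", "1-methyl-6-nitronaphthalene", "Cc1cccc2cc([N+](=O)[O-])ccc12"),
)


def builtin_case_set() -> list[MoleculeRecord]:
    """The 12 case-study molecules (queries plus reported neighbors)."""
    rows = [{"mol_id": cid, "name": name, "smiles": smi} for cid, name, smi in CASE_SET]
    records, report = clean_species_table(rows)
    if report.n_kept != len(CASE_SET):  # pragma: no cover - static data
        raise RuntimeError(f"case set failed curation: {report}")
    return records


def write_dataset(dataset: PlantedDataset, out_dir: str | Path) -> Path:
    """Write the full CSV suite: molecules, blocks, annotations, true labels."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with (out / "molecules.csv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mol_id", "name", "cas", "smiles"])
        for rec in dataset.records:
            writer.writerow([rec.mol_id, rec.name, rec.cas or "", rec.smiles_input])
    for label, block in dataset.blocks.items():
        with (out / f"block_{label}.csv").open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["mol_id", *block.feature_names])
            for i, mol_id in enumerate(block.mol_ids):
                row = []
                for j, v in enumerate(block.values[i]):
                    missing = (
                        block.missing_mask is not None and bool(block.missing_mask[i, j])
                    ) or (isinstance(v, float) and np.isnan(v))
                    row.append("" if missing else (f"{v:.10g}" if block.kind == "continuous" else int(v)))
                writer.writerow([mol_id, *row])
    with (out / "annotations.csv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mol_id", "gene_symbol", "uniprot", "assay_id",
                         "activity_name", "activity_value_um"])
        for ann in dataset.annotations:
            writer.writerow([ann.mol_id, ann.gene_symbol, ann.uniprot or "",
                             ann.assay_id or "", ann.activity_name or "",
                             "" if ann.activity_value_um is None else ann.activity_value_um])
    with (out / "true_labels.csv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mol_id", "community"])
        for mol_id, community in dataset.true_labels.items():
            writer.writerow([mol_id, community])
    return out
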