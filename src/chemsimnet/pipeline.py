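"""End-to-end orchestration: curate -> features -> spaces -> simnet -> embed.

Each stage writes re-loadable artifacts into a stage subdirectory of the
output directory, and a ``manifest.json`` records per-stage row/edge counts,
variance retained and seeds, so a rerun with the identical config reproduces
an identical manifest. One global seed fans out to per-stage seeds as
``seed + stage ordinal`` so stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

from .chem_io import clean_species_table, read_molecule_table, read_target_annotations
from .embedding import EmbeddingModel, TrainConfig, WalkConfig, embed_space, save_model
from .errors import DataError
from .features import (
    FeatureBlock,
    compute_fingerprint_block,
    filter_single_elements,
    load_descriptor_block,
    read_smarts_file,
)
from .simnet import SimilarityNetwork, build_network, compute_similarity
from .spaces import ChemicalSpace, SpaceConfig, build_space, save_space

logger = logging.getLogger("chemsimnet")

__all__ = ["PipelineConfig", "run_pipeline", "build_all_spaces",
           "networks_from_spaces", "embed_networks", "STAGE_ORDER"]

STAGE_ORDER = ("curate", "features", "spaces", "simnet", "embed")


@dataclass
class PipelineConfig:
    """Single document driving a full pipeline run (JSON or YAML)."""

    molecules: str = ""
    descriptors: str | None = None
    quantum: str | None = None
    annotations: str | None = None
    smarts_file: str | None = None
    bit_families: tuple[str, ...] = ("maccs", "estate", "path_hashed", "smarts_set")
    count_families: tuple[str, ...] = ("estate", "atom_pairs", "smarts_set")
    feature_cutoff: int = 50
    n_permutations: int = 1000
    alpha: float = 0.05
    walk: WalkConfig = field(default_factory=WalkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    query_threshold: float = 0.95
    query_floor: float = 0.75
    query_step: float = 0.01
    hi: float = 0.96
    lo: float = 0.46
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        walk = WalkConfig(**data.pop("walk", {}))
        train = TrainConfig(**data.pop("train", {}))
        for key in ("bit_families", "count_families"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(walk=walk, train=train, **data)

    def stage_seed(self, stage: str) -> int:
        return self.seed + STAGE_ORDER.index(stage)


def _concat_blocks(blocks: list[FeatureBlock], label: str, kind: str) -> FeatureBlock:
    import numpy as np

    mol_ids = blocks[0].mol_ids
    names: list[str] = []
    for fam_idx, block in enumerate(blocks):
        names.extend(f"f{fam_idx}_{name}" for name in block.feature_names)
    values = np.hstack([b.values for b in blocks])
    zero = sorted(set.intersection(*(set(b.zero_rows) for b in blocks))) if blocks else []
    return FeatureBlock(label, list(mol_ids), names, values, kind, zero_rows=zero)


def compute_feature_blocks(records, config: PipelineConfig) -> dict[str, FeatureBlock]:
    """Fingerprint blocks (computed) plus descriptor/quantum blocks (ingested)."""
    patterns = read_smarts_file(config.smarts_file) if config.smarts_file else None
    bit_blocks = [
        compute_fingerprint_block(records, fam, "binary", patterns=patterns)
        for fam in config.bit_families
    ]
    count_blocks = [
        compute_fingerprint_block(records, fam, "count", patterns=patterns)
        for fam in config.count_families
    ]
    blocks = {
        "fingerprint_bits": _concat_blocks(bit_blocks, "fingerprint_bits", "binary"),
        "fingerprint_counts": _concat_blocks(count_blocks, "fingerprint_counts", "count"),
    }
    for label, path in (("descriptors", config.descriptors), ("quantum", config.quantum)):
        if path:
            block = load_descriptor_block(path, label)
            main, elements = filter_single_elements(records, block)
            if main.n_molecules:
                blocks[label] = main
            if elements.n_molecules:
                blocks[label + "_elements"] = elements
    return blocks


def build_all_spaces(
    blocks: dict[str, FeatureBlock], space_config: SpaceConfig | None = None
) -> dict[str, ChemicalSpace]:
    space_config = space_config or SpaceConfig()
    spaces = {}
    for label, block in blocks.items():
        if block.n_molecules < 2:
            logger.warning("skipping space %s: fewer than 2 molecules", label)
            continue
        spaces[label] = build_space(block, space_config)
    return spaces


def networks_from_spaces(
    spaces: dict[str, ChemicalSpace],
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, tuple[Any, SimilarityNetwork]]:
    """Similarity + permutation test + network per space.

    Each space gets a distinct sub-seed derived from ``seed`` so the nulls
    are independent across spaces yet reproducible.
    """
    out = {}
    for ordinal, label in enumerate(sorted(spaces)):
        space = spaces[label]
        result = compute_similarity(
            space.mol_ids, space.reduced,
            n_permutations=n_permutations, seed=seed + 1000 * ordinal,
        )
        out[label] = (result, build_network(result, alpha=alpha))
    return out


def embed_networks(
    networks: dict[str, tuple[Any, SimilarityNetwork]],
    walk: WalkConfig | None = None,
    train: TrainConfig | None = None,
    seed: int = 0,
) -> dict[str, EmbeddingModel]:
    models = {}
    for ordinal, label in enumerate(sorted(networks)):
        _result, network = networks[label]
        if not network.edges:
            logger.warning("space %s has no significant edges; skipping embedding", label)
            continue
        stage_seed = seed + 1000 * ordinal
        walk_cfg = WalkConfig(**{**(walk or WalkConfig()).__dict__, "seed": stage_seed})
        models[label] = embed_space(
            network, label, walk_cfg, train or TrainConfig(), seed=stage_seed
        )
    return models


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages, write artifacts, return the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config_hash": config.config_hash(), "stages": {},
                                "timings": {}}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                info = fn()
            except FileNotFoundError as exc:
                raise DataError(f"stage {name}: INPUT_NOT_FOUND: {exc}") from exc
            except Exception as exc:
                raise type(exc)(f"stage {name}: {exc}") from exc
            # timings live outside the hashed manifest: reruns with the same
            # config must reproduce an identical manifest hash
            manifest["timings"][name] = round(time.perf_counter() - t0, 3)
            manifest["stages"][name] = info
            logger.info("stage %s done: %s", name, info)
            return info

        return wrap

    if not Path(config.molecules).exists():
        raise DataError(f"stage curate: INPUT_NOT_FOUND: {config.molecules}")

    records_box = {}

    @stage("curate")
    def _curate():
        rows = read_molecule_table(config.molecules)
        records, report = clean_species_table(rows)
        records_box["records"] = records
        with (out / "curated_molecules.csv").open("w", encoding="utf-8") as fh:
            fh.write("mol_id,name,cas,smiles\n")
            for r in records:
                fh.write(f"{r.mol_id},{r.name},{r.cas or ''},{r.smiles_canonical}\n")
        return {
            "n_input": report.n_input, "n_kept": report.n_kept,
            "n_dropped_duplicate": report.n_dropped_duplicate,
            "n_dropped_bad_smiles": report.n_dropped_bad_smiles,
        }

    blocks_box = {}

    @stage("features")
    def _features():
        blocks = compute_feature_blocks(records_box["records"], config)
        blocks_box["blocks"] = blocks
        return {label: [b.n_molecules, b.n_features] for label, b in blocks.items()}

    spaces_box = {}

    @stage("spaces")
    def _spaces():
        spaces = build_all_spaces(
            blocks_box["blocks"], SpaceConfig(feature_cutoff=config.feature_cutoff)
        )
        spaces_box["spaces"] = spaces
        for label, space in spaces.items():
            save_space(space, out / "spaces" / label)
        return {
            label: {"k": s.n_components, "variance_retained": round(s.variance_retained, 6)}
            for label, s in spaces.items()
        }

    networks_box = {}

    @stage("simnet")
    def _simnet():
        networks = networks_from_spaces(
            spaces_box["spaces"], config.n_permutations, config.alpha,
            seed=config.stage_seed("simnet"),
        )
        networks_box["networks"] = networks
        (out / "networks").mkdir(exist_ok=True)
        for label, (_res, net) in networks.items():
            net.write_edgelist(out / "networks" / f"{label}.tsv")
        return {
            label: {"n_nodes": len(net.nodes), "n_edges": len(net.edges),
                    "n_isolated": len(net.isolated_nodes)}
            for label, (_r, net) in networks.items()
        }

    @stage("embed")
    def _embed():
        models = embed_networks(
            networks_box["networks"], config.walk, config.train,
            seed=config.stage_seed("embed"),
        )
        for label, model in models.items():
            save_model(model, out / "models" / label)
        return {
            label: {"dims": m.dims, "n_embedded": len(m.vectors),
                    "n_isolated": len(m.isolated_nodes)}
            for label, m in models.items()
        }

    if config.annotations:
        known = {r.mol_id for r in records_box["records"]}
        annotations = read_target_annotations(config.annotations, known)
        manifest["n_annotations"] = len(annotations)

    manifest["seed"] = config.seed
    hashable = {k: v for k, v in manifest.items() if k != "timings"}
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(hashable, sort_keys=True).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
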