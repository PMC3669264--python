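"""End-to-end orchestration: featurize -> discretize -> encode -> refine ->
balance -> train -> combine, plus prediction and evaluation entry points.

Every run writes a JSON manifest carrying the configuration hash, all seeds,
and the instance/protein counts after each filtering stage, so any artifact
on disk can be regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import dataset_builder, discretization, evaluation, pair_encoding, sequence_features
from . import tree_learner
from .dataset_builder import BalancedDatasetSet, InstanceTable
from .discretization import BinningModel, BinnedProfile
from .pair_encoding import AttributeSchema, SchemaTag
from .sequence_features import GroupingTable, ProteinRecord
from .tree_learner import CombinedModel, Prediction, TreeParams

logger = logging.getLogger("seqppi")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a training / prediction / evaluation run."""

    fasta: str
    pairs: str
    out_dir: str
    schema_tag: SchemaTag = "Fp"
    seed: int = 0
    n_bags: int = 10
    tree_params: TreeParams = field(default_factory=TreeParams)
    grouping_table: Optional[str] = None  # None -> packaged default
    validation_policy: str = "strict"
    shuffle_labels: bool = False  # train on the label-shuffled control instead
    cv_folds: int = 10

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _needs(schema_tag: SchemaTag) -> tuple[bool, bool]:
    return (
        schema_tag in ("F", "Fp", "FC", "FpCp"),
        schema_tag in ("C", "Cp", "FC", "FpCp"),
    )


def compute_profiles(
    proteome: Sequence[ProteinRecord],
    schema_tag: SchemaTag,
    binning: dict[str, BinningModel],
    table: Optional[GroupingTable] = None,
) -> dict[str, BinnedProfile]:
    """Discretize every protein with the frozen binning model(s) a schema needs."""
    need_f, need_c = _needs(schema_tag)
    if need_c and table is None:
        table = sequence_features.load_grouping_table()
    profiles: dict[str, BinnedProfile] = {}
    for rec in proteome:
        parts = []
        if need_f:
            vec = sequence_features.aa_frequency(rec)
            parts.append(discretization.bin_profile(vec, binning["frequency"]))
        if need_c:
            vec = sequence_features.ctd_composition(rec, table)
            parts.append(discretization.bin_profile(vec, binning["composition"]))
        profiles[rec.id] = (
            parts[0] if len(parts) == 1 else discretization.merge_profiles(*parts)
        )
    return profiles


def build_schema_for(schema_tag: SchemaTag, table: Optional[GroupingTable] = None) -> AttributeSchema:
    need_f, need_c = _needs(schema_tag)
    comp_names = None
    if need_c:
        table = table or sequence_features.load_grouping_table()
        comp_names = table.descriptor_names()
    freq_names = sequence_features.frequency_descriptor_names() if need_f else None
    return pair_encoding.build_schema(schema_tag, freq_names, comp_names)


def refine_instances(
    vectors_by_protein: dict[str, tuple],
    table: InstanceTable,
) -> tuple[InstanceTable, dict[str, int]]:
    """Apply the three refinement rules; returns the table plus attrition counts."""
    counts = {"input": len(table)}
    table = dataset_builder.dedupe_pairs(table)
    counts["after_dedupe"] = len(table)
    table = dataset_builder.remove_conflicts(table)
    counts["after_conflicts"] = len(table)
    dataset_builder.assert_refined(table)
    return table, counts


def run_train(config: RunConfig) -> tuple[CombinedModel, dict]:
    """Train a combined model per the configured schema; persist all artifacts.

    Stages: parse/validate sequences -> descriptor vectors -> identical-feature
    exclusion -> pair refinement -> fit bins (frozen thereafter) -> encode ->
    balance -> optional label shuffle -> per-dataset bagging -> combination.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "config_hash": config.config_hash(),
                      "stage_counts": {}}

    proteome = sequence_features.read_fasta(config.fasta)
    manifest["stage_counts"]["proteins_parsed"] = len(proteome)
    proteome = sequence_features.validate_proteome(proteome, config.validation_policy)
    manifest["stage_counts"]["proteins_valid"] = len(proteome)

    table = dataset_builder.read_pair_tsv(config.pairs)
    known = {r.id for r in proteome}
    mask = table.data["id1"].isin(known) & table.data["id2"].isin(known)
    dropped = int((~mask).sum())
    if dropped:
        logger.warning("dropping %d pairs referencing unknown/rejected proteins", dropped)
        table = InstanceTable(data=table.data.loc[mask].reset_index(drop=True),
                              provenance=table.provenance)

    need_f, need_c = _needs(config.schema_tag)
    grouping = (
        sequence_features.load_grouping_table(config.grouping_table) if need_c else None
    )
    # Identical-feature exclusion operates on the concatenated descriptor sets
    # the schema uses.
    vectors = {}
    for rec in proteome:
        parts = []
        if need_f:
            parts.extend(sequence_features.aa_frequency(rec).values)
        if need_c:
            parts.extend(sequence_features.ctd_composition(rec, grouping).values)
        vectors[rec.id] = tuple(parts)
    from types import SimpleNamespace

    pseudo = [SimpleNamespace(protein_id=pid, values=v) for pid, v in vectors.items()]
    kept_vectors, table = dataset_builder.drop_identical_feature_proteins(pseudo, table)
    kept_ids = {v.protein_id for v in kept_vectors}
    proteome = [r for r in proteome if r.id in kept_ids]
    manifest["stage_counts"]["proteins_after_identical_filter"] = len(proteome)

    table, attrition = refine_instances(vectors, table)
    manifest["stage_counts"].update(attrition)

    # Fit and freeze discretization on the training proteins.
    binning: dict[str, BinningModel] = {}
    if need_f:
        fvecs = [sequence_features.aa_frequency(r) for r in proteome]
        binning["frequency"] = discretization.fit_bins(fvecs)
        binning["frequency"].to_json(out / "binning_frequency.json")
    if need_c:
        cvecs = [sequence_features.ctd_composition(r, grouping) for r in proteome]
        binning["composition"] = discretization.fit_bins(cvecs)
        binning["composition"].to_json(out / "binning_composition.json")

    schema = build_schema_for(config.schema_tag, grouping)
    profiles = compute_profiles(proteome, config.schema_tag, binning, grouping)
    encoded = pair_encoding.encode_table(table.data, profiles, schema)
    manifest["stage_counts"]["encoded_instances"] = len(encoded)

    balanced = dataset_builder.balance(
        InstanceTable(data=encoded, provenance="train"), seed=config.seed
    )
    if config.shuffle_labels:
        balanced = dataset_builder.shuffle_labels(balanced, seed=config.seed + 1)
    manifest["balanced"] = {
        "kind": balanced.kind,
        "n_datasets": len(balanced.datasets),
        "n_full": balanced.n_full,
        "remainder": balanced.remainder,
        "sizes": list(balanced.sizes),
        "seed": balanced.seed,
    }

    models = [
        tree_learner.bag_train(
            ds.data, schema, config.tree_params, n_bags=config.n_bags,
            seed=config.seed * 100 + i,
        )
        for i, ds in enumerate(balanced.datasets)
    ]
    model = tree_learner.combine(models)
    tree_learner.save_combined_model(model, out / "combined_model.json")
    manifest["model"] = {"n_models": len(models), "n_bags": config.n_bags,
                         "schema_tag": config.schema_tag}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return model, manifest


def run_predict(
    config: RunConfig,
    model_path: str | Path,
    pairs_path: str | Path,
    out_path: Optional[str | Path] = None,
) -> tuple[list[Prediction], list[dict]]:
    """Score unlabeled pairs with a persisted model and its frozen binning.

    Pairs referencing unknown proteins produce per-row error records and the
    run continues. Returns (predictions, error records).
    """
    model_dir = Path(model_path).parent
    model = tree_learner.load_combined_model(model_path)
    need_f, need_c = _needs(config.schema_tag)
    binning = {}
    if need_f:
        binning["frequency"] = BinningModel.from_json(model_dir / "binning_frequency.json")
    if need_c:
        binning["composition"] = BinningModel.from_json(model_dir / "binning_composition.json")
    grouping = (
        sequence_features.load_grouping_table(config.grouping_table) if need_c else None
    )
    proteome = sequence_features.validate_proteome(
        sequence_features.read_fasta(config.fasta), config.validation_policy
    )
    profiles = compute_profiles(proteome, config.schema_tag, binning, grouping)
    schema = build_schema_for(config.schema_tag, grouping)

    pairs = dataset_builder.read_pair_tsv(pairs_path)
    errors: list[dict] = []
    ok_rows = []
    for _, row in pairs.data.iterrows():
        unknown = [p for p in (row["id1"], row["id2"]) if p not in profiles]
        if unknown:
            errors.append({"id1": row["id1"], "id2": row["id2"],
                           "error": f"unknown protein id(s): {', '.join(unknown)}"})
        else:
            ok_rows.append(row)
    predictions: list[Prediction] = []
    if ok_rows:
        ok = pd.DataFrame(ok_rows).reset_index(drop=True)
        encoded = pair_encoding.encode_table(ok, profiles, schema)
        predictions = tree_learner.classify(model, encoded, schema)
    if out_path is not None:
        tree_learner.write_predictions_tsv(predictions, out_path)
        if errors:
            Path(str(out_path) + ".errors.json").write_text(json.dumps(errors, indent=1))
    return predictions, errors


def run_evaluate(
    balanced: BalancedDatasetSet,
    schema: AttributeSchema,
    params: TreeParams = TreeParams(),
    k: int = 10,
    n_bags: int = 10,
    seed: int = 0,
) -> list[evaluation.PerformanceReport]:
    """10-fold cross-validate a bagged model on every balanced dataset."""
    reports = []
    for i, ds in enumerate(balanced.datasets):
        reports.append(
            evaluation.cross_validate(
                ds.data, schema, params, k=k, n_bags=n_bags,
                seed=seed * 100 + i, dataset_id=f"{balanced.kind}-{i:02d}",
            )
        )
    return reports
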