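"""Instance refinement, train/test splitting, class balancing and label-shuffle controls.

The raw labeled pair collection is refined before any learning:

1. redundant pairs collapse to one instance (``ab`` equals ``ba``);
2. pairs recorded with both labels are removed entirely;
3. proteins sharing an identical descriptor vector are removed along with
   every pair that references them.

Because interacting pairs vastly outnumber experimentally supported
non-interacting pairs, training uses *balanced* datasets: with P positives
and N negatives (P >= N), the shuffled positives are cut into
``k = floor(P / N)`` blocks of N, each paired with the full negative set
(dataset size 2N), plus — if ``r = P - k*N > 0`` — one remainder dataset of
the r leftover positives paired with r sampled negatives (size 2r). Every
positive is used exactly once. Label-shuffled ("random") copies of the
balanced datasets serve as negative controls: class counts are preserved but
labels are permuted across instances, so any residual signal is spurious.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Hashable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .pair_encoding import LABEL_NO_PPI, LABEL_PPI
from .sequence_features import DescriptorVector


@dataclass(frozen=True)
class InstanceTable:
    """A table of labeled (or unlabeled) protein pairs, possibly encoded.

    ``data`` must carry columns id1, id2, label; encoded tables add one
    column per attribute. The refinement invariants (no duplicate unordered
    pair, no pair with both labels) are checked by :func:`assert_refined`
    after the refinement steps, not on construction.
    """

    data: pd.DataFrame
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for col in ("id1", "id2", "label"):
            if col not in self.data.columns:
                raise ValueError(f"instance table lacks required column {col!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def label_counts(self) -> dict[str, int]:
        return self.data["label"].value_counts().to_dict()


@dataclass(frozen=True)
class BalancedDatasetSet:
    """Ordered balanced datasets plus the bookkeeping to regenerate them."""

    datasets: tuple[InstanceTable, ...]
    seed: int
    kind: Literal["normal", "random"]
    n_full: int  # number of full datasets (size 2N)
    remainder: int  # r; 0 when P divides by N exactly

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(d) for d in self.datasets)


def _pair_key(df: pd.DataFrame) -> pd.Series:
    """Unordered pair identity as a sortable string key."""
    a = df["id1"].astype(str)
    b = df["id2"].astype(str)
    lo = a.where(a <= b, b)
    hi = b.where(a <= b, a)
    return lo + "\x1f" + hi


def dedupe_pairs(table: InstanceTable) -> InstanceTable:
    """Collapse records identical under unordered comparison; first occurrence kept.

    Redundancy is judged on the (unordered pair, label) combination, so a
    pair recorded with both labels survives dedup and is handled by
    :func:`remove_conflicts`. A self-pair (a, a) is a legal instance and is
    retained once.
    """
    key = _pair_key(table.data) + "\x1f" + table.data["label"].astype(str)
    keep = ~key.duplicated(keep="first")
    return replace(table, data=table.data.loc[keep].reset_index(drop=True))


def remove_conflicts(table: InstanceTable) -> InstanceTable:
    """Drop every record of any unordered pair labeled both PPI and no-PPI."""
    keys = _pair_key(table.data)
    n_labels = table.data.groupby(keys.values)["label"].transform("nunique")
    keep = n_labels <= 1
    return replace(table, data=table.data.loc[keep.values].reset_index(drop=True))


def assert_refined(table: InstanceTable) -> None:
    """Invariant check after refinement: unique unordered pairs, one label each."""
    keys = _pair_key(table.data)
    if keys.duplicated().any():
        raise AssertionError("refined table still contains duplicate unordered pairs")


def drop_identical_feature_proteins(
    vectors: Sequence[DescriptorVector], table: InstanceTable
) -> tuple[list[DescriptorVector], InstanceTable]:
    """Remove all proteins whose descriptor vector duplicates another protein's.

    Every member of an identical-feature group is removed (not keep-one),
    together with every instance referencing any removed protein.
    """
    by_values: dict[tuple[float, ...], list[str]] = {}
    for v in vectors:
        by_values.setdefault(tuple(val for _, val in v.values), []).append(v.protein_id)
    doomed = {pid for group in by_values.values() if len(group) > 1 for pid in group}
    kept_vectors = [v for v in vectors if v.protein_id not in doomed]
    mask = ~(table.data["id1"].isin(doomed) | table.data["id2"].isin(doomed))
    kept_table = replace(table, data=table.data.loc[mask].reset_index(drop=True))
    return kept_vectors, kept_table


def split_train_test(
    table: InstanceTable,
    positive_fraction: float,
    seed: int,
    group_key: Optional[Sequence[Hashable]] = None,
    negatives_to_train: bool = True,
) -> tuple[InstanceTable, InstanceTable]:
    """Split positives per group into train/test; route negatives by policy.

    Within each group, ``round(positive_fraction * positives)`` positive
    instances are sampled (without replacement, seeded) into the training
    split; the rest go to test. Negatives go wholly to train when
    ``negatives_to_train`` (the default, mirroring a design in which all
    species-specific experimentally supported negatives train the model), or
    are split with the same per-group fraction otherwise.
    """
    if not 0.0 < positive_fraction < 1.0:
        raise ValueError("positive_fraction must lie strictly between 0 and 1")
    df = table.data
    groups = pd.Series(group_key, index=df.index) if group_key is not None else pd.Series(
        0, index=df.index
    )
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for _, idx in df.groupby(groups.values).groups.items():
        idx = pd.Index(idx)
        pos = idx[df.loc[idx, "label"] == LABEL_PPI]
        neg = idx[df.loc[idx, "label"] != LABEL_PPI]
        n_train = round(positive_fraction * len(pos))
        chosen = rng.choice(len(pos), size=n_train, replace=False) if len(pos) else []
        chosen_set = set(pos[list(chosen)])
        train_idx.extend(p for p in pos if p in chosen_set)
        test_idx.extend(p for p in pos if p not in chosen_set)
        if negatives_to_train:
            train_idx.extend(neg)
        else:
            n_neg_train = round(positive_fraction * len(neg))
            chosen_n = rng.choice(len(neg), size=n_neg_train, replace=False) if len(neg) else []
            chosen_neg = set(neg[list(chosen_n)])
            train_idx.extend(n for n in neg if n in chosen_neg)
            test_idx.extend(n for n in neg if n not in chosen_neg)
    train = df.loc[sorted(train_idx)].reset_index(drop=True)
    test = df.loc[sorted(test_idx)].reset_index(drop=True)
    return (
        replace(table, data=train, provenance=f"{table.provenance}/train"),
        replace(table, data=test, provenance=f"{table.provenance}/test"),
    )


def balance(table: InstanceTable, seed: int) -> BalancedDatasetSet:
    """Partition positives into balanced datasets against the full negative set.

    With P positives and N negatives (P >= N >= 1): positives are shuffled
    (seeded) and cut into ``k = P // N`` blocks of N plus a remainder of
    ``r = P - k*N``. Each full block joins all N negatives (size 2N); a
    non-empty remainder joins r negatives sampled without replacement
    (size 2r). Each positive appears in exactly one dataset.
    """
    df = table.data
    pos = df.index[df["label"] == LABEL_PPI]
    neg = df.index[df["label"] == LABEL_NO_PPI]
    P, N = len(pos), len(neg)
    if N < 1:
        raise ValueError("need at least one negative instance")
    if P < N:
        raise ValueError(f"balancing scheme requires P >= N, got P={P}, N={N}")
    rng = np.random.default_rng(seed)
    pos_order = pos[rng.permutation(P)]
    k, r = divmod(P, N)
    datasets = []
    for i in range(k):
        block = pos_order[i * N : (i + 1) * N]
        data = pd.concat([df.loc[block], df.loc[neg]], ignore_index=True)
        datasets.append(InstanceTable(data=data, provenance=f"{table.provenance}/balanced{i:02d}"))
    if r > 0:
        block = pos_order[k * N :]
        neg_sample = neg[rng.choice(N, size=r, replace=False)]
        data = pd.concat([df.loc[block], df.loc[neg_sample]], ignore_index=True)
        datasets.append(
            InstanceTable(data=data, provenance=f"{table.provenance}/balanced{k:02d}")
        )
    return BalancedDatasetSet(
        datasets=tuple(datasets), seed=seed, kind="normal", n_full=k, remainder=r
    )


def shuffle_labels(dataset_set: BalancedDatasetSet, seed: int) -> BalancedDatasetSet:
    """Permute each dataset's label multiset over its instances (features untouched).

    Produces the "random" negative-control counterpart of a normal balanced
    set: class counts are preserved exactly, association with features is
    destroyed.
    """
    rng = np.random.default_rng(seed)
    shuffled = []
    for table in dataset_set.datasets:
        data = table.data.copy()
        perm = rng.permutation(len(data))
        data["label"] = data["label"].to_numpy()[perm]
        shuffled.append(replace(table, data=data, provenance=f"{table.provenance}/random"))
    return replace(dataset_set, datasets=tuple(shuffled), kind="random", seed=seed)


# -- I/O --------------------------------------------------------------------

def read_pair_tsv(path: str | Path, provenance: str | None = None) -> InstanceTable:
    """Read a pair table TSV with columns id1, id2[, label]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "label" not in df.columns:
        df["label"] = "unlabeled"
    return InstanceTable(data=df, provenance=provenance or str(path))


def write_pair_tsv(table: InstanceTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def write_balanced_set(dataset_set: BalancedDatasetSet, out_dir: str | Path) -> Path:
    """Write numbered dataset TSVs plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, table in enumerate(dataset_set.datasets):
        name = f"dataset_{i:02d}.tsv"
        table.data.to_csv(out / name, sep="\t", index=False)
        entries.append({"file": name, "n_instances": len(table), "labels": table.label_counts})
    manifest = {
        "kind": dataset_set.kind,
        "seed": dataset_set.seed,
        "n_datasets": len(dataset_set.datasets),
        "n_full": dataset_set.n_full,
        "remainder": dataset_set.remainder,
        "datasets": entries,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
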