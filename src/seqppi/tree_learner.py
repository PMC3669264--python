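"""C4.5-style categorical decision trees, bagging, and the combined pair scorer.

Trees split multiway on nominal pair attributes, choosing at each node the
attribute with the highest *gain ratio* — information gain divided by split
information — among attributes whose gain is at least the average gain of
the candidates (the classic C4.5 eligibility heuristic, which guards the
ratio against attributes with many sparse values). Growth stops on class
purity, attribute exhaustion, or when no split leaves at least two branches
with the minimum leaf size. Optional pessimistic pruning replaces a subtree
by a leaf when the leaf's upper-confidence error bound does not exceed the
subtree's.

Each balanced training dataset yields one bagged model (bootstrap resamples,
one tree per resample, probabilities averaged over trees); the combined
model averages the bagged models' P(interaction) into the final score. A
pair is called interacting when its (rounded) score exceeds 0.5,
non-interacting below 0.5, and left unclassified at exactly 0.50.
"""

from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .pair_encoding import LABEL_NO_PPI, LABEL_PPI, AttributeSchema, EncodedInstance

# Class index convention throughout this module: 0 = no-PPI, 1 = PPI.
_CLASS_LABELS = (LABEL_NO_PPI, LABEL_PPI)
_EPS = 1e-12


@dataclass(frozen=True)
class TreeParams:
    """Learning knobs mirroring the usual C4.5 defaults."""

    confidence: float = 0.25  # pessimistic-pruning confidence factor
    min_leaf: int = 2  # minimum instances per retained branch
    prune: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence <= 0.5:
            raise ValueError("confidence must lie in (0, 0.5]")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


class Node:
    """Tree node. ``attr`` is an attribute index; None marks a leaf.

    ``counts`` are the training class counts (no-PPI, PPI) reaching the node;
    children are indexed by attribute-value index, one per domain value, so
    values absent from the training partition route to a child leaf carrying
    the parent's class distribution (the C4.5-style fallback).
    """

    __slots__ = ("attr", "children", "counts", "fallback_proba")

    def __init__(self, counts: np.ndarray, attr: Optional[int] = None,
                 children: Optional[list["Node"]] = None,
                 fallback_proba: Optional[float] = None):
        self.counts = counts
        self.attr = attr
        self.children = children or []
        # P(PPI) to emit when no training instance reached this node (an
        # attribute value unseen in the local partition): the parent's
        # training distribution.
        self.fallback_proba = fallback_proba

    @property
    def is_leaf(self) -> bool:
        return self.attr is None

    @property
    def proba_ppi(self) -> float:
        total = self.counts.sum()
        if total == 0:
            return 0.5 if self.fallback_proba is None else self.fallback_proba
        return float(self.counts[1]) / float(total)

    def n_nodes(self) -> int:
        return 1 + sum(c.n_nodes() for c in self.children)


# -- entropy / gain ratio ----------------------------------------------------

def class_entropy(counts: Sequence[float]) -> float:
    """Shannon entropy in bits of a class-count vector, with 0*log0 = 0."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    p = arr[arr > 0] / total
    return float(-(p * np.log2(p)).sum())


def _split_scores(values: np.ndarray, y: np.ndarray, domain_size: int,
                  min_leaf: int) -> tuple[float, float, bool]:
    """(gain, gain_ratio, admissible) for one attribute at one node.

    ``admissible`` requires positive gain and split information plus the
    C4.5 minimum-instances rule: at least two branches of size >= min_leaf.
    """
    n = len(y)
    joint = np.bincount(values * 2 + y, minlength=domain_size * 2).reshape(domain_size, 2)
    branch_tot = joint.sum(axis=1)
    parent = class_entropy(joint.sum(axis=0))
    nz = branch_tot > 0
    bt = branch_tot[nz].astype(float)
    jm = joint[nz].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = jm / bt[:, None]
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    branch_H = -(p * logp).sum(axis=1)
    cond = float((bt / n * branch_H).sum())
    gain = parent - cond
    frac = bt / n
    split_info = float(-(frac * np.log2(frac)).sum())
    ok = (
        gain > _EPS
        and split_info > _EPS
        and int((branch_tot >= min_leaf).sum()) >= 2
    )
    ratio = gain / split_info if split_info > _EPS else 0.0
    return gain, ratio, ok


def gain_ratio(attribute_values: Sequence, labels: Sequence) -> float:
    """Gain ratio of splitting ``labels`` on a nominal attribute.

    Returns 0 for attributes with zero gain or zero split information
    (e.g. a constant attribute), which are never eligible split candidates.
    """
    vals = list(attribute_values)
    labs = list(labels)
    if len(vals) != len(labs) or not vals:
        raise ValueError("need equal-length, non-empty values and labels")
    vmap = {v: i for i, v in enumerate(dict.fromkeys(vals))}
    lmap = {l: i for i, l in enumerate(dict.fromkeys(labs))}
    if len(lmap) > 2:
        raise ValueError("binary class expected")
    v = np.array([vmap[x] for x in vals], dtype=np.int64)
    y = np.array([lmap[x] for x in labs], dtype=np.int64)
    gain, ratio, _ = _split_scores(v, y, len(vmap), min_leaf=1)
    if gain <= _EPS:
        return 0.0
    return ratio


# -- pessimistic error pruning ----------------------------------------------

@functools.lru_cache(maxsize=None)
def _z_quantile(cf: float) -> float:
    return float(norm.ppf(1.0 - cf))


def _added_errors(n: float, e: float, cf: float) -> float:
    """Upper-confidence extra errors for a leaf with n instances, e mistakes.

    The standard pessimistic-error bound used by C4.5-family pruners: exact
    binomial tail for small e, normal approximation otherwise.
    """
    if e < 1.0:
        base = n * (1.0 - cf ** (1.0 / n))
        if e == 0.0:
            return base
        return base + e * (_added_errors(n, 1.0, cf) - base)
    if e + 0.5 >= n:
        return max(n - e, 0.0)
    z = _z_quantile(cf)
    f = (e + 0.5) / n
    r = (f + z * z / (2 * n) + z * math.sqrt(f / n - f * f / n + z * z / (4 * n * n))) / (
        1 + z * z / n
    )
    return r * n - e


def _leaf_errors(counts: np.ndarray, cf: float) -> float:
    n = float(counts.sum())
    if n == 0:
        return 0.0
    e = n - float(counts.max())
    return e + _added_errors(n, e, cf)


def _subtree_errors(node: Node, cf: float) -> float:
    if node.is_leaf:
        return _leaf_errors(node.counts, cf)
    return sum(_subtree_errors(c, cf) for c in node.children if c.counts.sum() > 0)


def _prune(node: Node, cf: float) -> float:
    """Bottom-up subtree replacement; returns the subtree's post-prune errors."""
    leaf_err = _leaf_errors(node.counts, cf)
    if node.is_leaf:
        return leaf_err
    tree_err = sum(_prune(c, cf) for c in node.children if c.counts.sum() > 0)
    if leaf_err <= tree_err + 0.1:
        node.attr = None
        node.children = []
        return leaf_err
    return tree_err


def _score_candidates(
    X: np.ndarray, y: np.ndarray, idx: np.ndarray, avail_idx: np.ndarray,
    domain_sizes: Sequence[int], min_leaf: int,
) -> list[tuple[int, float, float]]:
    """(attr, gain, gain_ratio) for every admissible attribute at one node.

    All candidate attributes are tallied with a single flattened bincount so
    per-node cost is one pass over the instance-by-attribute submatrix.
    """
    n = len(idx)
    sizes = np.asarray([domain_sizes[a] for a in avail_idx], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(sizes[:-1])])
    cols = X[np.ix_(idx, avail_idx)]
    ysub = y[idx]
    flat = (cols + offsets[None, :]) * 2 + ysub[:, None]
    total = int(sizes.sum())
    joint = np.bincount(flat.ravel(), minlength=total * 2).reshape(total, 2)
    parent_H = class_entropy(np.bincount(ysub, minlength=2))
    out = []
    for pos, a in enumerate(avail_idx):
        block = joint[offsets[pos] : offsets[pos] + sizes[pos]]
        branch_tot = block.sum(axis=1)
        nz = branch_tot > 0
        bt = branch_tot[nz].astype(float)
        jm = block[nz].astype(float)
        p = jm / bt[:, None]
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
        cond = float((bt / n * (-(p * logp).sum(axis=1))).sum())
        gain = parent_H - cond
        if gain <= _EPS or int((branch_tot >= min_leaf).sum()) < 2:
            continue
        frac = bt / n
        split_info = float(-(frac * np.log2(frac)).sum())
        if split_info <= _EPS:
            continue
        out.append((int(a), gain, gain / split_info))
    return out


# -- tree growth -------------------------------------------------------------

@dataclass
class DecisionTree:
    """A fitted multiway categorical decision tree."""

    root: Node
    schema_tag: str
    attribute_names: tuple[str, ...]
    domain_sizes: tuple[int, ...]
    params: TreeParams
    seed: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(PPI) per row of an integer-encoded attribute matrix."""
        out = np.empty(len(X), dtype=float)
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.children[row[node.attr]]
            out[i] = node.proba_ppi
        return out

    def depth(self) -> int:
        def d(node: Node) -> int:
            return 0 if node.is_leaf else 1 + max(d(c) for c in node.children)

        return d(self.root)


def _grow(X: np.ndarray, y: np.ndarray, idx: np.ndarray, available: np.ndarray,
          domain_sizes: Sequence[int], params: TreeParams) -> Node:
    counts = np.bincount(y[idx], minlength=2)
    node = Node(counts=counts)
    if counts[0] == 0 or counts[1] == 0 or not available.any() or len(idx) < 2 * params.min_leaf:
        return node

    avail_idx = np.flatnonzero(available)
    cand = _score_candidates(X, y, idx, avail_idx, domain_sizes, params.min_leaf)
    if not cand:
        return node
    mean_gain = sum(g for _, g, _ in cand) / len(cand)
    eligible = [(a, r) for a, g, r in cand if g >= mean_gain - _EPS]
    # max gain ratio; ties broken by schema order (lowest attribute index)
    best_attr = max(eligible, key=lambda t: (t[1], -t[0]))[0]

    node.attr = int(best_attr)
    sub_avail = available.copy()
    sub_avail[best_attr] = False
    vals = X[idx, best_attr]
    for v in range(domain_sizes[best_attr]):
        child_idx = idx[vals == v]
        if len(child_idx) == 0:
            node.children.append(
                Node(counts=np.zeros(2, dtype=np.int64), fallback_proba=node.proba_ppi)
            )
        else:
            node.children.append(_grow(X, y, child_idx, sub_avail, domain_sizes, params))
    return node


def dataset_to_matrix(table: pd.DataFrame, schema: AttributeSchema) -> tuple[np.ndarray, np.ndarray]:
    """Integer-encode an attribute DataFrame: X[i, a] indexes attribute a's domain.

    Unlabeled rows get y = -1.
    """
    n = len(table)
    X = np.empty((n, len(schema.attributes)), dtype=np.int64)
    for j, attr in enumerate(schema.attributes):
        lut = {code: i for i, code in enumerate(attr.domain)}
        col = table[attr.name]
        try:
            X[:, j] = [lut[v] for v in col]
        except KeyError as exc:
            raise ValueError(
                f"attribute {attr.name!r}: value {exc.args[0]!r} outside domain"
            ) from None
    ymap = {LABEL_NO_PPI: 0, LABEL_PPI: 1}
    y = np.array([ymap.get(l, -1) for l in table["label"]], dtype=np.int64)
    return X, y


def grow_tree(
    table: pd.DataFrame,
    schema: AttributeSchema,
    params: TreeParams = TreeParams(),
    seed: int = 0,
) -> DecisionTree:
    """Fit one gain-ratio decision tree on an encoded, labeled dataset.

    Deterministic for fixed input: splits are chosen by gain ratio with ties
    broken by schema attribute order, so the seed is recorded as metadata but
    does not influence growth.
    """
    if len(table) == 0:
        raise ValueError("cannot grow a tree on an empty instance set")
    X, y = dataset_to_matrix(table, schema)
    if (y < 0).any():
        raise ValueError("all training instances must be labeled")
    return _grow_tree_from_matrix(X, y, schema, params, seed)


def _grow_tree_from_matrix(
    X: np.ndarray, y: np.ndarray, schema: AttributeSchema, params: TreeParams, seed: int
) -> DecisionTree:
    domain_sizes = tuple(len(a.domain) for a in schema.attributes)
    root = _grow(X, y, np.arange(len(y)), np.ones(X.shape[1], dtype=bool),
                 domain_sizes, params)
    if params.prune:
        _prune(root, params.confidence)
    return DecisionTree(
        root=root,
        schema_tag=schema.schema_tag,
        attribute_names=schema.names,
        domain_sizes=domain_sizes,
        params=params,
        seed=seed,
    )


# -- bagging and combination -------------------------------------------------

@dataclass
class BaggedModel:
    """Bootstrap-aggregated trees on one balanced dataset."""

    trees: list[DecisionTree]
    n_bags: int
    seed: int
    schema_tag: str

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.mean([t.predict_proba(X) for t in self.trees], axis=0)


@dataclass
class CombinedModel:
    """Ensemble of per-dataset bagged models; the mean P(PPI) is the score."""

    models: list[BaggedModel]
    schema_tag: str

    def score(self, X: np.ndarray) -> np.ndarray:
        return np.mean([m.predict_proba(X) for m in self.models], axis=0)


@dataclass(frozen=True)
class Prediction:
    id1: str
    id2: str
    score: float  # interaction score, P(PPI)
    rounded_score: float
    label: str  # PPI / no-PPI / unclassified


def bag_train(
    table: pd.DataFrame,
    schema: AttributeSchema,
    params: TreeParams = TreeParams(),
    n_bags: int = 10,
    seed: int = 0,
) -> BaggedModel:
    """Train ``n_bags`` trees on bootstrap resamples (size n, with replacement)."""
    if n_bags < 1:
        raise ValueError("n_bags must be >= 1")
    rng = np.random.default_rng(seed)
    X, y = dataset_to_matrix(table, schema)
    if (y < 0).any():
        raise ValueError("all training instances must be labeled")
    n = len(y)
    trees = []
    for b in range(n_bags):
        sample = rng.integers(0, n, size=n)
        trees.append(_grow_tree_from_matrix(X[sample], y[sample], schema, params, seed=seed + b))
    return BaggedModel(trees=trees, n_bags=n_bags, seed=seed, schema_tag=schema.schema_tag)


def combine(models: Sequence[BaggedModel]) -> CombinedModel:
    """Combine bagged models into the final scorer (unweighted probability mean)."""
    if not models:
        raise ValueError("need at least one bagged model")
    tags = {m.schema_tag for m in models}
    if len(tags) != 1:
        raise ValueError(f"models use different schemas: {sorted(tags)}")
    return CombinedModel(models=list(models), schema_tag=models[0].schema_tag)


def classify(
    model: CombinedModel,
    instances: pd.DataFrame | EncodedInstance,
    schema: AttributeSchema,
) -> list[Prediction]:
    """Score pairs and apply the 0.50 decision rule.

    The emitted score is always the interaction score P(PPI) (a no-PPI
    confidence c is the complement 1 - c by construction). The label is
    decided on the score rounded to two decimals, so a rounded score of
    exactly 0.50 yields "unclassified"; the raw score is also reported.
    """
    if isinstance(instances, EncodedInstance):
        table = pd.DataFrame(
            [(instances.id1, instances.id2, instances.label) + instances.values],
            columns=["id1", "id2", "label", *schema.names],
        )
    else:
        table = instances
    if model.schema_tag != schema.schema_tag:
        raise ValueError("model and schema tags disagree")
    X, _ = dataset_to_matrix(table, schema)
    scores = model.score(X)
    out = []
    for (i1, i2), s in zip(zip(table["id1"], table["id2"]), scores):
        r = round(float(s), 2)
        if r > 0.5:
            label = LABEL_PPI
        elif r < 0.5:
            label = LABEL_NO_PPI
        else:
            label = "unclassified"
        out.append(Prediction(id1=i1, id2=i2, score=float(s), rounded_score=r, label=label))
    return out


def write_predictions_tsv(predictions: Sequence[Prediction], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id1\tid2\tinteraction_score\tlabel\n")
        for p in predictions:
            fh.write(f"{p.id1}\t{p.id2}\t{p.score:.6f}\t{p.label}\n")


# -- tree inspection ---------------------------------------------------------

def root_attribute(tree: DecisionTree) -> Optional[str]:
    """Name of the depth-0 split attribute; None for a single-leaf tree."""
    if tree.root.is_leaf:
        return None
    return tree.attribute_names[tree.root.attr]


def level2_attributes(tree: DecisionTree) -> list[str]:
    """Names of the depth-1 split attributes (duplicates collapsed, order kept)."""
    if tree.root.is_leaf:
        return []
    seen = dict.fromkeys(
        tree.attribute_names[c.attr] for c in tree.root.children if not c.is_leaf
    )
    return list(seen)


def tree_synthesis(models: Sequence[BaggedModel]) -> pd.DataFrame:
    """Tabulate root and level-2 attribute usage across an ensemble's trees."""
    rows = []
    for mi, m in enumerate(models):
        for ti, t in enumerate(m.trees):
            rows.append(
                {
                    "model": mi,
                    "tree": ti,
                    "root": root_attribute(t),
                    "level2": ";".join(level2_attributes(t)),
                }
            )
    return pd.DataFrame(rows)


# -- serialization -----------------------------------------------------------

_FORMAT_VERSION = 1


def _node_to_dict(node: Node) -> dict:
    d = {"counts": node.counts.tolist()}
    if node.fallback_proba is not None:
        d["fallback_proba"] = node.fallback_proba
    if not node.is_leaf:
        d["attr"] = node.attr
        d["children"] = [_node_to_dict(c) for c in node.children]
    return d


def _node_from_dict(d: dict) -> Node:
    node = Node(counts=np.array(d["counts"], dtype=np.int64),
                fallback_proba=d.get("fallback_proba"))
    if "attr" in d:
        node.attr = d["attr"]
        node.children = [_node_from_dict(c) for c in d["children"]]
    return node


def _tree_to_dict(tree: DecisionTree) -> dict:
    return {
        "schema_tag": tree.schema_tag,
        "attribute_names": list(tree.attribute_names),
        "domain_sizes": list(tree.domain_sizes),
        "params": {
            "confidence": tree.params.confidence,
            "min_leaf": tree.params.min_leaf,
            "prune": tree.params.prune,
        },
        "seed": tree.seed,
        "root": _node_to_dict(tree.root),
    }


def _tree_from_dict(d: dict) -> DecisionTree:
    return DecisionTree(
        root=_node_from_dict(d["root"]),
        schema_tag=d["schema_tag"],
        attribute_names=tuple(d["attribute_names"]),
        domain_sizes=tuple(d["domain_sizes"]),
        params=TreeParams(**d["params"]),
        seed=d["seed"],
    )


def save_combined_model(model: CombinedModel, path: str | Path) -> None:
    payload = {
        "format_version": _FORMAT_VERSION,
        "schema_tag": model.schema_tag,
        "models": [
            {
                "n_bags": m.n_bags,
                "seed": m.seed,
                "schema_tag": m.schema_tag,
                "trees": [_tree_to_dict(t) for t in m.trees],
            }
            for m in model.models
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_combined_model(path: str | Path) -> CombinedModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    models = [
        BaggedModel(
            trees=[_tree_from_dict(t) for t in m["trees"]],
            n_bags=m["n_bags"],
            seed=m["seed"],
            schema_tag=m["schema_tag"],
        )
        for m in payload["models"]
    ]
    return CombinedModel(models=models, schema_tag=payload["schema_tag"])
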