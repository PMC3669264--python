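"""Synthetic proteomes and labeled pair tables with known statistical structure.

The generator supports three regimes used throughout testing:

* :func:`random_proteome` — i.i.d. sequences with controllable residue
  composition (defaults emulate a desk-scale proteome: 2,000 proteins of
  length 100-600);
* :func:`planted_interactome` — pair labels determined by a planted rule on
  one discretized symmetric attribute (so the ground truth lies exactly in
  the tree learner's hypothesis space), with tunable label-flip noise;
* :func:`null_interactome` — labels independent of every feature, the
  synthetic analogue of a label-shuffled negative control.

A continuous-rule variant (:func:`planted_interactome_continuous`) labels
pairs on the summed raw descriptor value instead, giving a target that trees
over binned attributes can only approximate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataset_builder import InstanceTable
from .discretization import BinningModel, bin_value
from .pair_encoding import LABEL_NO_PPI, LABEL_PPI, SYMMETRIC_CODES, standardize_code
from .sequence_features import AMINO_ACIDS, ProteinRecord, aa_frequency

DEFAULT_N_PROTEINS = 2000
DEFAULT_LENGTH_RANGE = (100, 600)


@dataclass(frozen=True)
class PlantedRule:
    """Ground-truth labeling rule on one symmetric discretized attribute.

    A pair is a true interaction when the standardized two-letter code of
    ``target_attribute`` (e.g. ``"N~N"``, the Asn-Asn frequency combination)
    falls in ``accepting``; each label is then flipped independently with
    probability ``noise``.
    """

    target_attribute: str = "N~N"
    accepting: frozenset[str] = frozenset({"AA", "AB", "BB"})
    noise: float = 0.0

    def __post_init__(self) -> None:
        d1, _, d2 = self.target_attribute.partition("~")
        if not d1 or d1 != d2:
            raise ValueError("target attribute must be symmetric, e.g. 'N~N'")
        if not self.accepting or not self.accepting < set(SYMMETRIC_CODES):
            raise ValueError(
                "accepting set must be a non-empty proper subset of the "
                f"standardized codes {SYMMETRIC_CODES}"
            )
        if not 0.0 <= self.noise < 0.5:
            raise ValueError("label-noise rate must lie in [0, 0.5)")

    @property
    def descriptor(self) -> str:
        return self.target_attribute.partition("~")[0]


def random_proteome(
    n: int = DEFAULT_N_PROTEINS,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    residue_weights: Optional[Sequence[float]] = None,
    seed: int = 0,
    id_prefix: str = "prot",
) -> list[ProteinRecord]:
    """Generate i.i.d. protein sequences with residues drawn from given weights.

    ``residue_weights`` follows the alphabetical amino-acid order (uniform by
    default); lengths are uniform over the inclusive ``length_range``.
    """
    if n < 1:
        raise ValueError("need n >= 1 proteins")
    lo, hi = length_range
    if lo < 20 or hi < lo:
        raise ValueError("length range must satisfy 20 <= lo <= hi")
    if residue_weights is None:
        weights = np.full(20, 1.0 / 20)
    else:
        weights = np.asarray(residue_weights, dtype=float)
        if len(weights) != 20 or (weights < 0).any() or weights.sum() <= 0:
            raise ValueError("residue weights: 20 non-negative values, not all zero")
        weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AMINO_ACIDS))
    records = []
    width = len(str(n - 1))
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=weights))
        records.append(ProteinRecord(id=f"{id_prefix}{i:0{width}d}", sequence=seq))
    return records


def _target_letters(
    proteome: Sequence[ProteinRecord], descriptor: str, binning: BinningModel
) -> dict[str, str]:
    """Per-protein bin letter of one frequency descriptor under a frozen model."""
    avg, stdv = binning.stats(descriptor)
    out = {}
    for rec in proteome:
        value = aa_frequency(rec).as_dict()[descriptor]
        out[rec.id] = bin_value(value, avg, stdv)
    return out


def planted_interactome(
    proteome: Sequence[ProteinRecord],
    rule: PlantedRule,
    binning: BinningModel,
    n_pos: int,
    n_neg: int,
    seed: int = 0,
    max_draw_factor: int = 500,
) -> InstanceTable:
    """Sample labeled pairs whose true label follows the planted rule.

    Unordered pairs are drawn uniformly without repetition; the true label is
    ``standardized code in rule.accepting``, flipped independently with
    probability ``rule.noise``; drawing continues (rejection sampling) until
    exactly ``n_pos`` positives and ``n_neg`` negatives are collected.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need n_pos >= 1 and n_neg >= 1")
    letters = _target_letters(proteome, rule.descriptor, binning)
    ids = [rec.id for rec in proteome]
    rng = np.random.default_rng(seed)
    seen: set[frozenset[str]] = set()
    pos_rows, neg_rows = [], []
    budget = max_draw_factor * (n_pos + n_neg)
    drawn = 0
    while (len(pos_rows) < n_pos or len(neg_rows) < n_neg) and drawn < budget:
        batch = rng.integers(0, len(ids), size=(4096, 2))
        flips = rng.random(4096)
        for (i, j), u in zip(batch, flips):
            drawn += 1
            key = frozenset((ids[i], ids[j]))
            if key in seen:
                continue
            seen.add(key)
            code = standardize_code(letters[ids[i]] + letters[ids[j]])
            label_ppi = code in rule.accepting
            if u < rule.noise:
                label_ppi = not label_ppi
            if label_ppi and len(pos_rows) < n_pos:
                pos_rows.append((ids[i], ids[j], LABEL_PPI))
            elif not label_ppi and len(neg_rows) < n_neg:
                neg_rows.append((ids[i], ids[j], LABEL_NO_PPI))
            if len(pos_rows) >= n_pos and len(neg_rows) >= n_neg:
                break
    if len(pos_rows) < n_pos or len(neg_rows) < n_neg:
        raise RuntimeError(
            f"could not realize {n_pos} positives / {n_neg} negatives within "
            f"{budget} draws (got {len(pos_rows)} / {len(neg_rows)}); the "
            "proteome may be too small or the rule too skewed"
        )
    df = pd.DataFrame(pos_rows + neg_rows, columns=["id1", "id2", "label"])
    return InstanceTable(data=df, provenance="synthetic/planted")


def planted_interactome_continuous(
    proteome: Sequence[ProteinRecord],
    descriptor: str,
    threshold: float,
    n_pos: int,
    n_neg: int,
    seed: int = 0,
    noise: float = 0.0,
    max_draw_factor: int = 500,
) -> InstanceTable:
    """Continuous-rule variant: a pair interacts when the two proteins' summed
    raw descriptor percentages stay below ``threshold``.

    The decision boundary cuts through bin interiors, so binned trees can
    only approximate it — useful for harder, approximate recovery tests.
    """
    if not 0.0 <= noise < 0.5:
        raise ValueError("noise must lie in [0, 0.5)")
    values = {rec.id: aa_frequency(rec).as_dict()[descriptor] for rec in proteome}
    ids = [rec.id for rec in proteome]
    rng = np.random.default_rng(seed)
    seen: set[frozenset[str]] = set()
    pos_rows, neg_rows = [], []
    budget = max_draw_factor * (n_pos + n_neg)
    drawn = 0
    while (len(pos_rows) < n_pos or len(neg_rows) < n_neg) and drawn < budget:
        batch = rng.integers(0, len(ids), size=(4096, 2))
        flips = rng.random(4096)
        for (i, j), u in zip(batch, flips):
            drawn += 1
            key = frozenset((ids[i], ids[j]))
            if key in seen:
                continue
            seen.add(key)
            label_ppi = values[ids[i]] + values[ids[j]] < threshold
            if u < noise:
                label_ppi = not label_ppi
            if label_ppi and len(pos_rows) < n_pos:
                pos_rows.append((ids[i], ids[j], LABEL_PPI))
            elif not label_ppi and len(neg_rows) < n_neg:
                neg_rows.append((ids[i], ids[j], LABEL_NO_PPI))
            if len(pos_rows) >= n_pos and len(neg_rows) >= n_neg:
                break
    if len(pos_rows) < n_pos or len(neg_rows) < n_neg:
        raise RuntimeError(
            f"could not realize {n_pos} positives / {n_neg} negatives within {budget} draws"
        )
    df = pd.DataFrame(pos_rows + neg_rows, columns=["id1", "id2", "label"])
    return InstanceTable(data=df, provenance="synthetic/planted-continuous")


def null_interactome(
    proteome: Sequence[ProteinRecord],
    n_pos: int,
    n_neg: int,
    seed: int = 0,
) -> InstanceTable:
    """Sample pairs and assign labels independently of every feature."""
    if n_pos < 0 or n_neg < 0 or n_pos + n_neg < 1:
        raise ValueError("need a positive total pair count")
    ids = [rec.id for rec in proteome]
    n_total = n_pos + n_neg
    max_pairs = len(ids) * (len(ids) + 1) // 2
    if n_total > max_pairs:
        raise ValueError(f"requested {n_total} pairs but only {max_pairs} exist")
    rng = np.random.default_rng(seed)
    seen: set[frozenset[str]] = set()
    rows: list[tuple[str, str]] = []
    while len(rows) < n_total:
        batch = rng.integers(0, len(ids), size=(4096, 2))
        for i, j in batch:
            key = frozenset((ids[i], ids[j]))
            if key in seen:
                continue
            seen.add(key)
            rows.append((ids[i], ids[j]))
            if len(rows) >= n_total:
                break
    labels = np.array([LABEL_PPI] * n_pos + [LABEL_NO_PPI] * n_neg)
    rng.shuffle(labels)
    df = pd.DataFrame(
        [(a, b, l) for (a, b), l in zip(rows, labels)], columns=["id1", "id2", "label"]
    )
    return InstanceTable(data=df, provenance="synthetic/null")


def write_fasta(proteome: Sequence[ProteinRecord], path, width: int = 60) -> None:
    """Write a proteome as wrapped FASTA, round-trippable by read_fasta."""
    with open(path, "w") as fh:
        for rec in proteome:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
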