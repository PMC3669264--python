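"""Mean/SD discretization of descriptor values into four nominal bins.

Per descriptor, the mean (``avg``) and sample standard deviation (``stdv``)
are fitted on the *training* proteins once and then frozen; every descriptor
value — training or test — is mapped to one of four letter bins:

====  =========  =========================
bin   meaning    rule
====  =========  =========================
A     low        x < avg - stdv
B     moderate   avg - stdv <= x <= avg
C     high       avg < x <= avg + stdv
D     very high  x > avg + stdv
====  =========  =========================

The boundary ``x == avg - stdv`` is assigned to B (moderate, closed below);
with ``stdv == 0`` the rules collapse to A below the mean, B at the mean and
D above it, with C unreachable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequence_features import DescriptorVector, SetTag

BIN_LETTERS: tuple[str, ...] = ("A", "B", "C", "D")


@dataclass(frozen=True)
class BinningModel:
    """Frozen per-descriptor mean and sample SD defining the A/B/C/D bins."""

    set_tag: SetTag
    descriptors: tuple[str, ...]
    avg: tuple[float, ...]
    stdv: tuple[float, ...]
    n_proteins: int

    def __post_init__(self) -> None:
        expected = {"frequency": 20, "composition": 21}[self.set_tag]
        if len(self.descriptors) != expected:
            raise ValueError(
                f"{self.set_tag} model needs {expected} descriptors, got {len(self.descriptors)}"
            )
        if not (len(self.descriptors) == len(self.avg) == len(self.stdv)):
            raise ValueError("descriptors, avg and stdv must have equal length")
        if any(s < 0 for s in self.stdv):
            raise ValueError("standard deviations must be non-negative")

    def stats(self, descriptor: str) -> tuple[float, float]:
        i = self.descriptors.index(descriptor)
        return self.avg[i], self.stdv[i]

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "set_tag": self.set_tag,
            "n_proteins": self.n_proteins,
            "descriptors": [
                {"descriptor": d, "avg": a, "stdv": s}
                for d, a, s in zip(self.descriptors, self.avg, self.stdv)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "BinningModel":
        payload = json.loads(Path(path).read_text())
        rows = payload["descriptors"]
        return cls(
            set_tag=payload["set_tag"],
            descriptors=tuple(r["descriptor"] for r in rows),
            avg=tuple(float(r["avg"]) for r in rows),
            stdv=tuple(float(r["stdv"]) for r in rows),
            n_proteins=int(payload["n_proteins"]),
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("descriptor\tavg\tstdv\n")
            for d, a, s in zip(self.descriptors, self.avg, self.stdv):
                fh.write(f"{d}\t{a:.10g}\t{s:.10g}\n")


@dataclass(frozen=True)
class BinnedProfile:
    """A protein's descriptors mapped to their bin letters."""

    protein_id: str
    set_tag: str
    bins: tuple[tuple[str, str], ...]  # (descriptor name, letter)

    def __post_init__(self) -> None:
        for name, letter in self.bins:
            if letter not in BIN_LETTERS:
                raise ValueError(f"descriptor {name!r}: invalid bin letter {letter!r}")

    def as_dict(self) -> dict[str, str]:
        return dict(self.bins)

    @property
    def letters(self) -> str:
        return "".join(letter for _, letter in self.bins)


def fit_bins(vectors: Sequence[DescriptorVector]) -> BinningModel:
    """Fit per-descriptor mean and sample SD (n-1 denominator) on training proteins.

    Requires at least two vectors of the same descriptor set, one per protein.
    """
    if len(vectors) < 2:
        raise ValueError(f"need >= 2 descriptor vectors to fit bins, got {len(vectors)}")
    tags = {v.set_tag for v in vectors}
    if len(tags) != 1:
        raise ValueError(f"mixed descriptor sets: {sorted(tags)}")
    ids = [v.protein_id for v in vectors]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids among descriptor vectors")
    names = vectors[0].names
    if any(v.names != names for v in vectors):
        raise ValueError("descriptor vectors disagree on descriptor order")
    mat = np.array([[val for _, val in v.values] for v in vectors], dtype=float)
    avg = mat.mean(axis=0)
    stdv = mat.std(axis=0, ddof=1)
    return BinningModel(
        set_tag=vectors[0].set_tag,
        descriptors=names,
        avg=tuple(avg.tolist()),
        stdv=tuple(stdv.tolist()),
        n_proteins=len(vectors),
    )


def bin_value(x: float, avg: float, stdv: float) -> str:
    """Map one descriptor value to its bin letter under the frozen (avg, stdv)."""
    if stdv < 0:
        raise ValueError("stdv must be non-negative")
    if x < avg - stdv:
        return "A"
    if x <= avg:
        return "B"
    if x <= avg + stdv:
        return "C"
    return "D"


def bin_profile(vector: DescriptorVector, model: BinningModel) -> BinnedProfile:
    """Discretize every descriptor of a protein with the frozen model.

    The model is fitted on training proteins only and reused as-is at test
    time; this function never updates it.
    """
    if vector.set_tag != model.set_tag:
        raise ValueError(
            f"set_tag mismatch: vector is {vector.set_tag!r}, model is {model.set_tag!r}"
        )
    if vector.names != model.descriptors:
        raise ValueError("descriptor order mismatch between vector and model")
    bins = tuple(
        (name, bin_value(val, a, s))
        for (name, val), a, s in zip(vector.values, model.avg, model.stdv)
    )
    return BinnedProfile(protein_id=vector.protein_id, set_tag=vector.set_tag, bins=bins)


def merge_profiles(freq: BinnedProfile, comp: BinnedProfile) -> BinnedProfile:
    """Concatenate a protein's frequency and composition profiles.

    Needed for the combined F+C / F'+C' pair schemas, whose attributes draw
    descriptors from both sets.
    """
    if freq.protein_id != comp.protein_id:
        raise ValueError("profiles belong to different proteins")
    return BinnedProfile(
        protein_id=freq.protein_id,
        set_tag="frequency+composition",
        bins=freq.bins + comp.bins,
    )
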