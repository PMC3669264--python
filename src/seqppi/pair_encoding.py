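"""Pair-level nominal attribute encoding under the six dataset schemas.

A protein pair is encoded by combining the two proteins' bin letters into
two-letter codes, one attribute per descriptor combination:

========  ================================  ==========
schema    attributes                         count
========  ================================  ==========
F         all ordered frequency pairs        400 (20x20)
F'        frequency diagonal (symmetric)     20
C         all ordered composition pairs      441 (21x21)
C'        composition diagonal (symmetric)   21
F+C       F then C concatenated              841
F'+C'     F' then C' concatenated            41
========  ================================  ==========

Symmetric attributes (same descriptor on both proteins) are standardized so
that protein order is irrelevant: the codes BA, CA, CB, DA, DB, DC become
AB, AC, BC, AD, BD, CD. Asymmetric attributes keep the input protein order
and therefore admit all 16 ordered codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd

from .discretization import BIN_LETTERS, BinnedProfile

SchemaTag = Literal["F", "Fp", "C", "Cp", "FC", "FpCp"]
SCHEMA_TAGS: tuple[SchemaTag, ...] = ("F", "Fp", "C", "Cp", "FC", "FpCp")

#: 16 ordered two-letter codes, the value domain of asymmetric attributes.
ASYMMETRIC_CODES: tuple[str, ...] = tuple(a + b for a, b in product(BIN_LETTERS, BIN_LETTERS))
#: 10 standardized codes, the value domain of symmetric attributes.
SYMMETRIC_CODES: tuple[str, ...] = tuple(
    a + b for a, b in product(BIN_LETTERS, BIN_LETTERS) if a <= b
)

LABEL_PPI = "PPI"
LABEL_NO_PPI = "no-PPI"
LABEL_UNLABELED = "unlabeled"


@dataclass(frozen=True)
class Attribute:
    """One pair attribute: descriptor of protein 1 combined with one of protein 2."""

    name: str
    descriptor1: str
    descriptor2: str
    symmetric: bool

    @property
    def domain(self) -> tuple[str, ...]:
        return SYMMETRIC_CODES if self.symmetric else ASYMMETRIC_CODES


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered attribute list for one of the six pair-encoding schemas."""

    schema_tag: SchemaTag
    attributes: tuple[Attribute, ...]

    EXPECTED_COUNTS = {"F": 400, "Fp": 20, "C": 441, "Cp": 21, "FC": 841, "FpCp": 41}

    def __post_init__(self) -> None:
        expected = self.EXPECTED_COUNTS[self.schema_tag]
        if len(self.attributes) != expected:
            raise ValueError(
                f"schema {self.schema_tag}: expected {expected} attributes, "
                f"got {len(self.attributes)}"
            )
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ValueError("attribute names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    @property
    def required_descriptors(self) -> frozenset[str]:
        return frozenset(
            d for a in self.attributes for d in (a.descriptor1, a.descriptor2)
        )


@dataclass(frozen=True)
class EncodedInstance:
    """A protein pair encoded as nominal attributes, optionally labeled."""

    id1: str
    id2: str
    schema_tag: SchemaTag
    values: tuple[str, ...]  # aligned with the schema's attribute order
    label: str = LABEL_UNLABELED

    @property
    def pair_id(self) -> frozenset[str] | tuple[str, str]:
        """Unordered pair identity (self-pairs collapse to a singleton)."""
        return frozenset((self.id1, self.id2))


def _cross_attributes(names1: Sequence[str], names2: Sequence[str]) -> tuple[Attribute, ...]:
    return tuple(
        Attribute(name=f"{d1}~{d2}", descriptor1=d1, descriptor2=d2,
                  symmetric=False)
        for d1 in names1
        for d2 in names2
    )


def _diagonal_attributes(names: Sequence[str]) -> tuple[Attribute, ...]:
    return tuple(
        Attribute(name=f"{d}~{d}", descriptor1=d, descriptor2=d, symmetric=True)
        for d in names
    )


def build_schema(
    tag: SchemaTag,
    frequency_names: Optional[Sequence[str]] = None,
    composition_names: Optional[Sequence[str]] = None,
) -> AttributeSchema:
    """Build the attribute schema for one of the six dataset layouts.

    ``frequency_names`` (20) and/or ``composition_names`` (21) must be given
    as required by the tag; F/C enumerate all ordered descriptor pairs while
    F'/C' keep only the symmetric diagonal, and FC / F'+C' concatenate.
    """
    if tag not in SCHEMA_TAGS:
        raise ValueError(f"unknown schema tag {tag!r}; expected one of {SCHEMA_TAGS}")
    need_f = tag in ("F", "Fp", "FC", "FpCp")
    need_c = tag in ("C", "Cp", "FC", "FpCp")
    if need_f:
        if frequency_names is None or len(frequency_names) != 20:
            raise ValueError(f"schema {tag}: need exactly 20 frequency descriptor names")
    if need_c:
        if composition_names is None or len(composition_names) != 21:
            raise ValueError(f"schema {tag}: need exactly 21 composition descriptor names")

    if tag == "F":
        attrs = _cross_attributes(frequency_names, frequency_names)
    elif tag == "Fp":
        attrs = _diagonal_attributes(frequency_names)
    elif tag == "C":
        attrs = _cross_attributes(composition_names, composition_names)
    elif tag == "Cp":
        attrs = _diagonal_attributes(composition_names)
    elif tag == "FC":
        attrs = _cross_attributes(frequency_names, frequency_names) + _cross_attributes(
            composition_names, composition_names
        )
    else:  # FpCp
        attrs = _diagonal_attributes(frequency_names) + _diagonal_attributes(
            composition_names
        )
    return AttributeSchema(schema_tag=tag, attributes=attrs)


def standardize_code(code: str) -> str:
    """Sort a two-letter bin code so symmetric attributes ignore protein order.

    BA, CA, CB, DA, DB, DC map to AB, AC, BC, AD, BD, CD; already-sorted
    codes (including doubled letters) pass through. Idempotent.
    """
    if len(code) != 2 or code[0] not in BIN_LETTERS or code[1] not in BIN_LETTERS:
        raise ValueError(f"invalid bin code {code!r}")
    return code if code[0] <= code[1] else code[1] + code[0]


def encode_pair(
    p1: BinnedProfile,
    p2: BinnedProfile,
    schema: AttributeSchema,
    label: str = LABEL_UNLABELED,
) -> EncodedInstance:
    """Encode a protein pair under a schema.

    Asymmetric attributes take ``letter(p1, d1) + letter(p2, d2)`` in the
    given protein order; symmetric attributes apply :func:`standardize_code`
    so the result is invariant to swapping the two proteins.
    """
    b1, b2 = p1.as_dict(), p2.as_dict()
    missing = schema.required_descriptors - (set(b1) & set(b2))
    if missing:
        raise ValueError(
            f"profiles missing descriptors required by schema "
            f"{schema.schema_tag}: {sorted(missing)[:5]}"
        )
    values = []
    for attr in schema.attributes:
        code = b1[attr.descriptor1] + b2[attr.descriptor2]
        values.append(standardize_code(code) if attr.symmetric else code)
    return EncodedInstance(
        id1=p1.protein_id,
        id2=p2.protein_id,
        schema_tag=schema.schema_tag,
        values=tuple(values),
        label=label,
    )


# -- tabular encoding and I/O -----------------------------------------------

def encode_table(
    pairs: pd.DataFrame,
    profiles: dict[str, BinnedProfile],
    schema: AttributeSchema,
) -> pd.DataFrame:
    """Encode a (id1, id2[, label]) pair table into an attribute DataFrame.

    Output columns: id1, id2, label, then one column per schema attribute.
    Pairs referencing proteins without a profile raise a KeyError naming them.
    """
    missing = sorted(
        {p for col in ("id1", "id2") for p in pairs[col] if p not in profiles}
    )
    if missing:
        raise KeyError(f"no binned profile for proteins: {missing[:10]}")
    labels = pairs["label"] if "label" in pairs.columns else [LABEL_UNLABELED] * len(pairs)
    rows = []
    for (i1, i2), lab in zip(zip(pairs["id1"], pairs["id2"]), labels):
        inst = encode_pair(profiles[i1], profiles[i2], schema, label=lab)
        rows.append((inst.id1, inst.id2, inst.label) + inst.values)
    cols = ["id1", "id2", "label", *schema.names]
    return pd.DataFrame(rows, columns=cols)


def write_encoded_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_encoded_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_arff(table: pd.DataFrame, schema: AttributeSchema, path: str | Path,
               relation: str = "protein_pairs") -> None:
    """Export an encoded dataset in ARFF with per-attribute nominal domains."""
    with open(path, "w") as fh:
        fh.write(f"@relation {relation}\n\n")
        for attr in schema.attributes:
            domain = ",".join(attr.domain)
            fh.write(f"@attribute '{attr.name}' {{{domain}}}\n")
        fh.write(f"@attribute class {{{LABEL_PPI},{LABEL_NO_PPI}}}\n\n@data\n")
        for _, row in table.iterrows():
            vals = ",".join(row[name] for name in schema.names)
            fh.write(f"{vals},{row['label']}\n")
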