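"""Protein sequence parsing and per-protein descriptor computation.

Two descriptor sets are computed for every protein:

* ``frequency`` — the percentage of each of the 20 standard amino acids in
  the sequence, ``100 * N_A / N`` where ``N_A`` counts residues of type A and
  ``N`` is the sequence length (20 descriptors).
* ``composition`` — residues are assigned to one of three groups for each of
  seven physicochemical properties (hydrophobicity, normalized van der Waals
  volume, polarity, polarizability, charge, secondary structure, solvent
  accessibility) and the percentage of each group is reported
  (3 groups x 7 properties = 21 descriptors).

Both sets are expressed in percentage units so that, per protein, the 20
frequency values sum to 100 and each property's three group values sum to 100.
"""

from __future__ import annotations

import importlib.resources
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import yaml
from Bio import SeqIO

logger = logging.getLogger("seqppi")

#: The 20 standard amino acids, alphabetical by one-letter code. This is the
#: canonical descriptor order for the "frequency" set and is fixed so that
#: serialized descriptor vectors are byte-stable across runs.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
_AA_SET = frozenset(AMINO_ACIDS)

SetTag = Literal["frequency", "composition"]


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains residues outside the standard alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique identifier.

    The sequence is expected to use the 20 standard one-letter codes;
    membership is checked by :func:`validate_sequence`, not the constructor,
    so that parsers can carry non-standard records to the validation policy.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")

    @property
    def nonstandard_residues(self) -> list[tuple[int, str]]:
        """1-based positions and characters outside the standard alphabet."""
        return [(i, c) for i, c in enumerate(self.sequence, start=1) if c not in _AA_SET]

    @property
    def is_standard(self) -> bool:
        return not self.nonstandard_residues


@dataclass(frozen=True)
class DescriptorVector:
    """Ordered per-protein descriptor percentages for one descriptor set."""

    protein_id: str
    set_tag: SetTag
    values: tuple[tuple[str, float], ...]  # (descriptor name, percentage)

    def __post_init__(self) -> None:
        expected = {"frequency": 20, "composition": 21}[self.set_tag]
        if len(self.values) != expected:
            raise ValueError(
                f"{self.set_tag} vector needs {expected} descriptors, got {len(self.values)}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


@dataclass(frozen=True)
class GroupingTable:
    """Amino-acid to group assignments for the composition descriptors.

    ``properties`` maps each property name to a 3-tuple of residue sets
    (group1, group2, group3). Every property must partition the 20-letter
    alphabet: the groups are disjoint and their union is the full alphabet.
    """

    properties: tuple[tuple[str, tuple[frozenset[str], frozenset[str], frozenset[str]]], ...]

    def __post_init__(self) -> None:
        if len(self.properties) != 7:
            raise ValueError(f"expected 7 properties, got {len(self.properties)}")
        for name, groups in self.properties:
            if len(groups) != 3:
                raise ValueError(f"property {name!r}: expected 3 groups")
            union = frozenset().union(*groups)
            total = sum(len(g) for g in groups)
            if union != _AA_SET or total != 20:
                raise ValueError(
                    f"property {name!r}: groups must partition the 20-letter "
                    f"alphabet (union size {len(union)}, total {total})"
                )

    @property
    def property_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.properties)

    def descriptor_names(self) -> tuple[str, ...]:
        """21 composition descriptor names, property order x group 1..3."""
        return tuple(
            f"{name}.g{g}" for name, _ in self.properties for g in (1, 2, 3)
        )


def load_grouping_table(path: str | Path | None = None) -> GroupingTable:
    """Load a grouping table from YAML; the packaged default if ``path`` is None.

    Expected layout: ``property: {group1: [aa...], group2: [...], group3: [...]}``.
    """
    if path is None:
        source = importlib.resources.files("seqppi.data").joinpath("ctd_groups.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or not raw:
        raise ValueError("grouping table file must map property names to groups")
    props = []
    for name, groups in raw.items():
        try:
            triple = tuple(
                frozenset(str(aa).upper() for aa in groups[f"group{g}"]) for g in (1, 2, 3)
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"property {name!r}: expected keys group1/group2/group3") from exc
        props.append((str(name), triple))
    return GroupingTable(properties=tuple(props))


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly wrapped, mixed-case) FASTA file into protein records.

    The id of each record is the header token before the first whitespace;
    sequences are uppercased. Raises :class:`FastaParseError` on structural
    problems (naming the offending line) and on duplicate ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    # Structural pre-scan: data before the first header is the one malformation
    # Bio.SeqIO silently tolerates or reports without a location.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header '>' before "
                    f"sequence data, found {stripped[:30]!r}"
                )
            break
        else:
            raise FastaParseError(f"{path}: file contains no FASTA records")

    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not str(rec.seq):
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))

    counts = Counter(r.id for r in records)
    dupes = sorted(i for i, c in counts.items() if c > 1)
    if dupes:
        raise FastaParseError(f"{path}: duplicate protein ids: {', '.join(dupes)}")
    return records


def validate_sequence(
    record: ProteinRecord, policy: Literal["strict", "drop"] = "strict"
) -> ProteinRecord | None:
    """Enforce the 20-letter alphabet on a record.

    ``strict`` raises :class:`SequenceValidationError` naming the offending
    characters and their 1-based positions; ``drop`` returns ``None`` with a
    logged warning so callers can exclude the protein (and every pair
    referencing it) downstream.
    """
    bad = record.nonstandard_residues
    if not bad:
        return record
    detail = ", ".join(f"{c!r} at position {i}" for i, c in bad[:10])
    if policy == "strict":
        raise SequenceValidationError(
            f"protein {record.id!r}: non-standard residues: {detail}"
        )
    if policy == "drop":
        logger.warning("dropping protein %r: non-standard residues: %s", record.id, detail)
        return None
    raise ValueError(f"unknown validation policy {policy!r}")


def validate_proteome(
    records: Iterable[ProteinRecord], policy: Literal["strict", "drop"] = "strict"
) -> list[ProteinRecord]:
    """Apply :func:`validate_sequence` to every record, dropping rejects."""
    kept = []
    for rec in records:
        out = validate_sequence(rec, policy)
        if out is not None:
            kept.append(out)
    return kept


def aa_frequency(record: ProteinRecord) -> DescriptorVector:
    """Percentage of each of the 20 amino acids: ``100 * N_A / N``.

    Descriptors are ordered alphabetically by one-letter code.
    """
    if not record.is_standard:
        raise SequenceValidationError(
            f"protein {record.id!r}: cannot compute frequencies over "
            f"non-standard residues; run validate_sequence first"
        )
    n = len(record.sequence)
    counts = Counter(record.sequence)
    values = tuple((aa, 100.0 * counts.get(aa, 0) / n) for aa in AMINO_ACIDS)
    return DescriptorVector(protein_id=record.id, set_tag="frequency", values=values)


def ctd_composition(record: ProteinRecord, table: GroupingTable) -> DescriptorVector:
    """Group percentages per physicochemical property: ``100 * nr / N``.

    ``nr`` counts the residues falling in group 1, 2 or 3 of each property;
    each property therefore contributes three descriptors summing to 100.
    """
    if not record.is_standard:
        raise SequenceValidationError(
            f"protein {record.id!r}: cannot compute composition over "
            f"non-standard residues; run validate_sequence first"
        )
    n = len(record.sequence)
    counts = Counter(record.sequence)
    values = []
    for name, groups in table.properties:
        for g, members in zip((1, 2, 3), groups):
            nr = sum(counts.get(aa, 0) for aa in members)
            values.append((f"{name}.g{g}", 100.0 * nr / n))
    return DescriptorVector(protein_id=record.id, set_tag="composition", values=tuple(values))


def frequency_descriptor_names() -> tuple[str, ...]:
    """Canonical names of the 20 frequency descriptors."""
    return AMINO_ACIDS


def write_descriptor_tsv(vectors: Sequence[DescriptorVector], path: str | Path) -> None:
    """Write descriptor vectors to TSV: protein_id then descriptor columns."""
    if not vectors:
        raise ValueError("no descriptor vectors to write")
    names = vectors[0].names
    with open(path, "w") as fh:
        fh.write("protein_id\t" + "\t".join(names) + "\n")
        for vec in vectors:
            if vec.names != names:
                raise ValueError("mixed descriptor sets in one TSV")
            row = "\t".join(format(v, ".10g") for _, v in vec.values)
            fh.write(f"{vec.protein_id}\t{row}\n")


def read_descriptor_tsv(path: str | Path, set_tag: SetTag) -> list[DescriptorVector]:
    """Read descriptor vectors written by :func:`write_descriptor_tsv`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "protein_id":
            raise ValueError(f"{path}: expected 'protein_id' as first column")
        names = header[1:]
        out = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            values = tuple(zip(names, (float(x) for x in parts[1:])))
            out.append(DescriptorVector(protein_id=parts[0], set_tag=set_tag, values=values))
    return out
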