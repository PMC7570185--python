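"""Readers and writers for the on-disk formats the pipeline touches.

All validation happens at this boundary: identifiers are checked for
uniqueness, protein sequences for their alphabet, interaction pairs for
referential integrity against the loaded drug and protein lists.

Formats
-------
- drugs: ``.smi`` — one record per nonempty line, ``SMILES <whitespace> id``
- proteins: FASTA; the header token up to the first whitespace is the id
- interactions: two-column TSV ``drug_id <tab> protein_id``, no header by
  default (``header=True`` tolerates one header line)
- feature matrices: CSV, first column the record id, remaining columns the
  named feature values (round-trip exact: floats are printed at repr
  precision)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "ValidationError",
    "DrugRecord",
    "ProteinRecord",
    "InteractionTable",
    "CANONICAL_AA",
    "AMBIGUOUS_AA",
    "read_smiles_file",
    "read_fasta",
    "read_interactions",
    "write_feature_matrix",
    "read_feature_matrix",
]

#: The 20 canonical amino acids, one-letter codes, alphabetical order.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-standard codes that are rejected by default.
AMBIGUOUS_AA = frozenset("BJOUXZ")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant (ids, alphabet, refs)."""


def _check_id(kind: str, value: str) -> str:
    if not value:
        raise ValidationError(f"empty {kind} identifier")
    if "|" in value or any(c.isspace() for c in value):
        raise ValidationError(
            f"{kind} identifier {value!r} must not contain '|' or whitespace"
        )
    return value


@dataclass(frozen=True)
class DrugRecord:
    """A drug as read from disk: opaque identifier plus SMILES string."""

    drug_id: str
    smiles: str

    def __post_init__(self) -> None:
        _check_id("drug", self.drug_id)
        if not self.smiles:
            raise ValidationError(f"drug {self.drug_id!r} has an empty SMILES")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein target: opaque identifier plus amino-acid sequence."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        _check_id("protein", self.protein_id)
        if not self.sequence:
            raise ValidationError(f"protein {self.protein_id!r} has an empty sequence")


@dataclass(frozen=True)
class InteractionTable:
    """A bipartite positive pair set over ordered drug and target lists.

    The unlabeled set is the Cartesian complement of ``positives`` and is
    never materialized here; only its size is exposed.
    """

    drugs: tuple[str, ...]
    targets: tuple[str, ...]
    positives: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.drugs)) != len(self.drugs):
            raise ValidationError("duplicate drug ids in interaction table")
        if len(set(self.targets)) != len(self.targets):
            raise ValidationError("duplicate target ids in interaction table")
        dset, tset = set(self.drugs), set(self.targets)
        for d, t in self.positives:
            if d not in dset:
                raise ValidationError(f"positive pair references unknown drug {d!r}")
            if t not in tset:
                raise ValidationError(f"positive pair references unknown protein {t!r}")

    @property
    def n_pairs(self) -> int:
        """Size of the full drug x target Cartesian product."""
        return len(self.drugs) * len(self.targets)

    @property
    def n_positive(self) -> int:
        return len(self.positives)

    @property
    def n_unlabeled(self) -> int:
        return self.n_pairs - len(self.positives)

    @property
    def positive_fraction(self) -> float:
        return len(self.positives) / self.n_pairs


def read_smiles_file(path: str | Path) -> list[DrugRecord]:
    """Read a ``.smi`` file: one ``SMILES <whitespace> identifier`` per line.

    Records are returned in file order. Blank lines are skipped; duplicate
    identifiers and lines with fewer than two fields are errors.
    """
    path = Path(path)
    records: list[DrugRecord] = []
    seen: set[str] = set()
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'SMILES identifier', got {line!r}"
                )
            smiles, drug_id = fields[0], fields[1]
            if drug_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate drug id {drug_id!r}")
            seen.add(drug_id)
            records.append(DrugRecord(drug_id=drug_id, smiles=smiles))
    return records


def read_fasta(path: str | Path, *, allow_ambiguous: bool = False) -> list[ProteinRecord]:
    """Read protein records from FASTA.

    Multi-line sequences are concatenated and case-folded to upper. By
    default any character outside the 20 canonical one-letter codes is a
    validation error naming its (1-based) position; ``allow_ambiguous=True``
    additionally tolerates the codes B, J, O, U, X, Z (downstream featurizers
    decide how to treat them).
    """
    path = Path(path)
    accepted = set(CANONICAL_AA) | (AMBIGUOUS_AA if allow_ambiguous else set())
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in accepted:
                raise ValidationError(
                    f"{path}: protein {rec.id!r}: invalid residue {ch!r} at position {pos}"
                )
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(protein_id=rec.id, sequence=seq))
    return records


def read_interactions(
    path: str | Path,
    drugs: Sequence[DrugRecord] | Iterable[str],
    proteins: Sequence[ProteinRecord] | Iterable[str],
    *,
    header: bool = False,
) -> InteractionTable:
    """Read a two-column TSV of positive (drug_id, protein_id) pairs.

    Repeated pairs are eliminated. A pair referencing an id absent from
    ``drugs`` / ``proteins`` is an error rather than a silent drop — silent
    drops would corrupt the unlabeled complement used for negative sampling.
    """
    path = Path(path)
    drug_ids = tuple(d.drug_id if isinstance(d, DrugRecord) else str(d) for d in drugs)
    protein_ids = tuple(
        p.protein_id if isinstance(p, ProteinRecord) else str(p) for p in proteins
    )
    dset, tset = set(drug_ids), set(protein_ids)
    positives: set[tuple[str, str]] = set()
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected two tab-separated columns, got {line!r}"
                )
            d, t = fields[0].strip(), fields[1].strip()
            if d not in dset:
                raise ValidationError(f"{path}:{lineno}: unknown drug id {d!r}")
            if t not in tset:
                raise ValidationError(f"{path}:{lineno}: unknown protein id {t!r}")
            positives.add((d, t))
    return InteractionTable(drugs=drug_ids, targets=protein_ids, positives=frozenset(positives))


def write_feature_matrix(frame: pd.DataFrame, path: str | Path, *, index_label: str = "id") -> None:
    """Write a feature matrix CSV (id column first, repr-precision floats)."""
    frame.to_csv(Path(path), index=True, index_label=index_label, float_format=None)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature matrix CSV written by :func:`write_feature_matrix`."""
    # round_trip parsing: repr-printed floats must come back bit-exact
    return pd.read_csv(Path(path), index_col=0, float_precision="round_trip")
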