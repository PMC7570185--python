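"""79-bit electrotopological-state (E-state) atom-type fingerprints.

Each heavy atom of the hydrogen-suppressed molecular graph is classified
into one of the 79 published Kier-Hall E-state atom types. A type is the
combination of the element, the multiset of bond orders to heavy neighbours
(single / double / triple / aromatic) and the number of attached hydrogens
— e.g. ``sCH3`` is a carbon with one single bond and three hydrogens,
``aaCH`` an aromatic CH with two aromatic bonds. The fingerprint is the
binary presence vector over the 79 types: bit *i* is 1 iff at least one
atom of type *i* occurs in the molecule.

SMILES parsing and aromaticity perception are delegated to RDKit (its
default sanitization model); the typing itself is implemented here as a
signature lookup against the table shipped in ``data/estate_types.tsv``,
plus two special rules that the published type definitions state in terms
of bond-order-agnostic terminal oxygens:

- ``ddsN`` (nitro-like nitrogen): a 3-connected N with no hydrogens, at
  least two terminal-oxygen neighbours, and a single or aromatic bond to
  the remaining substituent — this captures both the charge-separated
  ``[N+](=O)[O-]`` and the pentavalent ``N(=O)=O`` spellings of a nitro
  group.
- ``ddssS`` (sulfone-like sulfur): a 4-connected S with no hydrogens, two
  terminal-oxygen neighbours and two single bonds.

Atoms matching no type (exotic elements, unusual valence states) receive
the sentinel :data:`UNTYPED` and do not touch the fingerprint; a warning
is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .io import DrugRecord

__all__ = [
    "SmilesParseError",
    "UNTYPED",
    "ESTATE_TYPE_NAMES",
    "N_ESTATE_TYPES",
    "MolecularGraph",
    "EStateFingerprint",
    "perceive_graph",
    "assign_estate_types",
    "estate_fingerprint",
    "featurize_drugs",
]

logger = logging.getLogger(__name__)

#: Sentinel label for heavy atoms that match none of the 79 types.
UNTYPED = "untyped"

BondOrder = Literal["single", "double", "triple", "aromatic"]

_BOND_ORDER_MAP = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the string."""

    def __init__(self, smiles: str):
        super().__init__(f"unparsable SMILES: {smiles!r}")
        self.smiles = smiles


@dataclass(frozen=True)
class MolecularGraph:
    """Hydrogen-suppressed molecular graph.

    ``atoms`` holds one ``(element, n_hydrogens, formal_charge)`` triple per
    heavy atom; ``bonds`` holds ``(i, j, order)`` with ``order`` one of
    ``single``/``double``/``triple``/``aromatic``.
    """

    atoms: tuple[tuple[str, int, int], ...]
    bonds: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) endpoint out of range (n={n})")

    def neighbours(self, idx: int) -> list[tuple[int, str]]:
        """Return (neighbour index, bond order) pairs for atom ``idx``."""
        out = []
        for i, j, order in self.bonds:
            if i == idx:
                out.append((j, order))
            elif j == idx:
                out.append((i, order))
        return out


def _load_type_table() -> pd.DataFrame:
    with resources.files("dtikit.data").joinpath("estate_types.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


_TYPE_TABLE = _load_type_table()

#: The 79 type labels, in fixed fingerprint bit order.
ESTATE_TYPE_NAMES: tuple[str, ...] = tuple(_TYPE_TABLE["name"])
N_ESTATE_TYPES = len(ESTATE_TYPE_NAMES)

_TYPE_INDEX = {name: i for i, name in enumerate(ESTATE_TYPE_NAMES)}

# exact-signature lookup: (element, n_aromatic, n_triple, n_double, n_single, nH)
_SIGNATURE_LOOKUP: dict[tuple[str, int, int, int, int, int], str] = {}
# hydrogen-agnostic lookup for types whose published pattern leaves H free
_ANYH_LOOKUP: dict[tuple[str, int, int, int, int], str] = {}
for _row in _TYPE_TABLE.itertuples():
    _sig = (_row.element, _row.aromatic, _row.triple, _row.double, _row.single)
    if _row.hydrogens < 0:
        _ANYH_LOOKUP[_sig] = _row.name
    else:
        _SIGNATURE_LOOKUP[(*_sig, _row.hydrogens)] = _row.name
# aasN's published pattern lets the third attachment be aromatic as well
# (bridgehead aromatic N, e.g. indolizine), giving a 3-aromatic-bond variant.
_SIGNATURE_LOOKUP[("N", 3, 0, 0, 0, 0)] = "aasN"


@dataclass(frozen=True)
class EStateFingerprint:
    """Binary presence vector over the 79 E-state atom types."""

    bits: np.ndarray
    type_names: tuple[str, ...] = ESTATE_TYPE_NAMES

    def __post_init__(self) -> None:
        if self.bits.shape != (N_ESTATE_TYPES,):
            raise ValueError(f"fingerprint must have length {N_ESTATE_TYPES}")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0 or 1")

    def on_types(self) -> tuple[str, ...]:
        """Names of the types whose presence bit is set."""
        return tuple(n for n, b in zip(self.type_names, self.bits) if b)


def perceive_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-suppressed graph.

    Aromaticity is perceived with RDKit's default sanitization; implicit
    hydrogens are counted onto their heavy atoms.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    atoms = tuple(
        (a.GetSymbol(), a.GetTotalNumHs(), a.GetFormalCharge()) for a in mol.GetAtoms()
    )
    bonds = tuple(
        (
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            _BOND_ORDER_MAP.get(b.GetBondType(), "other"),
        )
        for b in mol.GetBonds()
    )
    return MolecularGraph(atoms=atoms, bonds=bonds)


def _is_terminal_oxygen(graph: MolecularGraph, idx: int) -> bool:
    elem, n_h, _ = graph.atoms[idx]
    return elem == "O" and n_h == 0 and len(graph.neighbours(idx)) == 1


def _special_type(graph: MolecularGraph, idx: int, nbrs: list[tuple[int, str]]) -> str | None:
    elem, n_h, _ = graph.atoms[idx]
    if elem == "N" and n_h == 0 and len(nbrs) == 3:
        # nitro-like N: two terminal O (any bond order), third bond single/aromatic
        term = [k for k, (j, _) in enumerate(nbrs) if _is_terminal_oxygen(graph, j)]
        for pair in combinations(term, 2):
            (rest,) = [k for k in range(3) if k not in pair]
            if nbrs[rest][1] in ("single", "aromatic"):
                return "ddsN"
    if elem == "S" and n_h == 0 and len(nbrs) == 4:
        # sulfone-like S: two terminal O (any bond order), two single bonds
        term = [k for k, (j, _) in enumerate(nbrs) if _is_terminal_oxygen(graph, j)]
        for pair in combinations(term, 2):
            rest = [k for k in range(4) if k not in pair]
            if all(nbrs[k][1] == "single" for k in rest):
                return "ddssS"
    return None


def assign_estate_types(graph: MolecularGraph) -> list[str]:
    """Map every heavy atom to its E-state type label (or :data:`UNTYPED`).

    The assignment is deterministic: special oxygen rules first, then exact
    signature lookup on (element, bond-order counts, hydrogen count).
    """
    labels: list[str] = []
    for idx, (elem, n_h, _charge) in enumerate(graph.atoms):
        nbrs = graph.neighbours(idx)
        label = _special_type(graph, idx, nbrs)
        if label is None:
            orders = [o for _, o in nbrs]
            sig = (
                elem,
                orders.count("aromatic"),
                orders.count("triple"),
                orders.count("double"),
                orders.count("single"),
            )
            label = _SIGNATURE_LOOKUP.get((*sig, n_h)) or _ANYH_LOOKUP.get(sig)
        if label is None:
            label = UNTYPED
            logger.warning(
                "atom %d (%s, %dH) matches no E-state type; leaving untyped",
                idx,
                elem,
                n_h,
            )
        labels.append(label)
    return labels


def estate_fingerprint(smiles: str) -> EStateFingerprint:
    """Compute the 79-bit E-state presence fingerprint of a SMILES string.

    Bit *i* is 1 iff at least one heavy atom of type *i* is present. All
    fragments of a multi-fragment (salt) SMILES are typed; untyped atoms
    leave the fingerprint unaffected.
    """
    graph = perceive_graph(smiles)
    bits = np.zeros(N_ESTATE_TYPES, dtype=np.int8)
    for label in assign_estate_types(graph):
        if label != UNTYPED:
            bits[_TYPE_INDEX[label]] = 1
    return EStateFingerprint(bits=bits)


def featurize_drugs(records: Sequence[DrugRecord] | Iterable[DrugRecord]) -> pd.DataFrame:
    """Fingerprint a collection of drugs.

    Returns a DataFrame indexed by ``drug_id`` with one 0/1 column per
    E-state type, in fixed bit order.
    """
    records = list(records)
    data = np.zeros((len(records), N_ESTATE_TYPES), dtype=np.int8)
    for k, rec in enumerate(records):
        data[k] = estate_fingerprint(rec.smiles).bits
    return pd.DataFrame(
        data,
        index=pd.Index([r.drug_id for r in records], name="drug_id"),
        columns=list(ESTATE_TYPE_NAMES),
    )
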