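"""Amphiphilic pseudo amino acid composition (APAAC).

A protein sequence of length N over the 20 canonical amino acids is encoded
as 20 composition components followed by 2*lam sequence-order correlation
factors built from standardized hydrophobicity (H1) and hydrophilicity (H2)
scales — the amphiphilic formulation, in which H1 and H2 correlations
alternate:

    tau_{2j-1} = (1/(N-j)) * sum_{k=1..N-j} h1(R_k) * h1(R_{k+j})
    tau_{2j}   = (1/(N-j)) * sum_{k=1..N-j} h2(R_k) * h2(R_{k+j})

for j = 1..lam. With f_u the relative frequency of amino acid u (so the
f's sum to 1), the components are

    p_u      = f_u / (1 + w * sum(tau))          u = 1..20
    p_{20+j} = w * tau_j / (1 + w * sum(tau))    j = 1..2*lam

so the full vector sums to 1. Defaults lam=30, w=0.05 give the standard
80-dimensional descriptor (20 + 2*30).

Scales are standardized to mean 0 and population standard deviation 1 over
the 20 amino acids (divide by sqrt(mean of squared deviations), not the
sample form). Raw values ship in ``data/aa_scales.tsv``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AMBIGUOUS_AA, CANONICAL_AA, ProteinRecord, ValidationError

__all__ = [
    "APAACConfig",
    "NormalizedScales",
    "ShortSequenceError",
    "load_raw_scales",
    "normalize_scales",
    "default_scales",
    "correlation_factors",
    "apaac",
    "apaac_feature_names",
    "featurize_proteins",
]


class ShortSequenceError(ValueError):
    """Sequence length must strictly exceed the correlation rank lam."""


@dataclass(frozen=True)
class APAACConfig:
    """APAAC parameters: correlation rank ``lam`` and weight ``weight``.

    Output dimension is ``20 + 2 * lam``; the defaults give 80.
    """

    lam: int = 30
    weight: float = 0.05

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError("lam must be a positive integer")
        if self.weight <= 0:
            raise ValueError("weight must be positive")

    @property
    def dimension(self) -> int:
        return 20 + 2 * self.lam


@dataclass(frozen=True)
class NormalizedScales:
    """Standardized hydrophobicity (h1) and hydrophilicity (h2) scales."""

    h1: Mapping[str, float]
    h2: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, scale in (("h1", self.h1), ("h2", self.h2)):
            if set(scale) != set(CANONICAL_AA):
                raise ValueError(f"{name} must cover exactly the 20 canonical amino acids")
            vals = np.array([scale[a] for a in CANONICAL_AA])
            if abs(vals.mean()) > 1e-9 or abs(vals.std() - 1.0) > 1e-9:
                raise ValueError(f"{name} is not standardized (mean 0, population SD 1)")


def load_raw_scales() -> tuple[dict[str, float], dict[str, float]]:
    """Load the raw (unstandardized) H1/H2 values from the packaged table."""
    with resources.files("dtikit.data").joinpath("aa_scales.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t", comment="#", index_col="aa")
    return (
        table["hydrophobicity"].to_dict(),
        table["hydrophilicity"].to_dict(),
    )


def normalize_scales(
    raw_h1: Mapping[str, float], raw_h2: Mapping[str, float]
) -> NormalizedScales:
    """Standardize raw scales: subtract the mean over the 20 amino acids and
    divide by the population standard deviation. A constant scale is an error."""

    def _std(raw: Mapping[str, float], name: str) -> dict[str, float]:
        vals = np.array([raw[a] for a in CANONICAL_AA], dtype=float)
        sd = vals.std()  # population form (divide by 20)
        if sd == 0:
            raise ValueError(f"{name} scale is constant; cannot standardize")
        return {a: (raw[a] - vals.mean()) / sd for a in CANONICAL_AA}

    return NormalizedScales(h1=_std(raw_h1, "h1"), h2=_std(raw_h2, "h2"))


_DEFAULT_SCALES: NormalizedScales | None = None


def default_scales() -> NormalizedScales:
    """The packaged scales, standardized (cached)."""
    global _DEFAULT_SCALES
    if _DEFAULT_SCALES is None:
        _DEFAULT_SCALES = normalize_scales(*load_raw_scales())
    return _DEFAULT_SCALES


def _validate_sequence(sequence: str, strict: bool) -> str:
    canonical = set(CANONICAL_AA)
    bad = [(i, c) for i, c in enumerate(sequence, start=1) if c not in canonical]
    if not bad:
        return sequence
    if strict:
        pos, ch = bad[0]
        raise ValidationError(
            f"invalid residue {ch!r} at position {pos}; "
            "pass strict=False to drop ambiguous codes (B, J, O, U, X, Z)"
        )
    unknown = [(i, c) for i, c in bad if c not in AMBIGUOUS_AA]
    if unknown:
        pos, ch = unknown[0]
        raise ValidationError(f"invalid residue {ch!r} at position {pos}")
    return "".join(c for c in sequence if c in canonical)


def correlation_factors(
    sequence: str, lam: int, scales: NormalizedScales | None = None
) -> np.ndarray:
    """Sequence-order correlation factors tau, length ``2 * lam``.

    Odd slots (1-based) hold the hydrophobicity products, even slots the
    hydrophilicity products, each averaged over the N-j residue pairs at
    separation j. Requires N > lam.
    """
    scales = scales or default_scales()
    n = len(sequence)
    if n <= lam:
        raise ShortSequenceError(
            f"sequence length {n} too short for lam={lam}; need at least {lam + 1} residues"
        )
    h1 = np.array([scales.h1[c] for c in sequence])
    h2 = np.array([scales.h2[c] for c in sequence])
    tau = np.empty(2 * lam)
    for j in range(1, lam + 1):
        tau[2 * j - 2] = np.mean(h1[:-j] * h1[j:])
        tau[2 * j - 1] = np.mean(h2[:-j] * h2[j:])
    return tau


def apaac(
    sequence: str,
    config: APAACConfig | None = None,
    scales: NormalizedScales | None = None,
    *,
    strict: bool = True,
) -> np.ndarray:
    """Compute the APAAC vector of a sequence (length ``20 + 2 * lam``).

    With ``strict=True`` (default) any residue outside the canonical 20 is
    an error; with ``strict=False`` the ambiguity codes B, J, O, U, X, Z are
    dropped before computation (N shrinks accordingly).
    """
    config = config or APAACConfig()
    scales = scales or default_scales()
    seq = _validate_sequence(sequence, strict)
    tau = correlation_factors(seq, config.lam, scales)
    counts = np.array([seq.count(a) for a in CANONICAL_AA], dtype=float)
    freqs = counts / len(seq)  # sums to 1 by construction
    denom = 1.0 + config.weight * tau.sum()
    assert denom != 0, "APAAC denominator vanished"
    return np.concatenate([freqs / denom, config.weight * tau / denom])


def apaac_feature_names(lam: int = 30) -> list[str]:
    """Column labels: ``comp_A..comp_Y`` then ``tau01_h1, tau01_h2, ...``."""
    names = [f"comp_{a}" for a in CANONICAL_AA]
    for j in range(1, lam + 1):
        names += [f"tau{j:02d}_h1", f"tau{j:02d}_h2"]
    return names


def featurize_proteins(
    records: Sequence[ProteinRecord] | Iterable[ProteinRecord],
    config: APAACConfig | None = None,
    *,
    strict: bool = True,
) -> pd.DataFrame:
    """APAAC-featurize a collection of proteins.

    Returns a DataFrame indexed by ``protein_id`` with ``20 + 2 * lam``
    columns in fixed order.
    """
    config = config or APAACConfig()
    records = list(records)
    data = np.zeros((len(records), config.dimension))
    for k, rec in enumerate(records):
        data[k] = apaac(rec.sequence, config, strict=strict)
    return pd.DataFrame(
        data,
        index=pd.Index([r.protein_id for r in records], name="protein_id"),
        columns=apaac_feature_names(config.lam),
    )
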