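"""Pair feature assembly, reliable-negative sampling and CV splitting.

The central object is the :class:`PairFeatureMatrix`: one row per
(drug, target) pair, the drug fingerprint (79 bits) concatenated with the
target APAAC vector (80 components) into a 159-dimensional feature vector,
and a label in {positive, negative, unlabeled}.

Negative sampling follows the positive-unlabeled scheme: the *positive
center* is the mean of all positive rows (optionally after a PCA rotation),
every unlabeled pair is ranked by Euclidean distance from that center, and
the farthest pairs — the ones least similar to any known interaction — are
relabeled as reliable negatives, by default as many as there are positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .io import InteractionTable

__all__ = [
    "PAIR_SEP",
    "PairFeatureMatrix",
    "PositiveCenter",
    "SamplingPlan",
    "assemble_pairs",
    "positive_center",
    "rank_unlabeled",
    "sample_negatives",
    "split_cv",
]

#: Separator joining drug and protein ids into a pair key.
PAIR_SEP = "|"

_META_COLS = ("drug_id", "protein_id", "label")

Label = Literal["positive", "negative", "unlabeled"]


@dataclass
class PairFeatureMatrix:
    """Labeled (drug, target) pair features.

    ``frame`` is indexed by the pair key ``"drug_id|protein_id"`` and holds
    the metadata columns ``drug_id``, ``protein_id``, ``label`` followed by
    the feature columns ``f000..f158`` (or ``f{0:03d}..`` for other widths).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _META_COLS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"pair matrix missing columns {missing}")
        if not self.frame.index.is_unique:
            raise ValueError("pair keys must be unique")
        bad = set(self.frame["label"]) - {"positive", "negative", "unlabeled"}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in _META_COLS]

    @property
    def width(self) -> int:
        return len(self.feature_columns)

    def keys(self, label: Label | None = None) -> list[str]:
        if label is None:
            return list(self.frame.index)
        return list(self.frame.index[self.frame["label"] == label])

    def features(self, keys: Sequence[str] | None = None) -> np.ndarray:
        sub = self.frame if keys is None else self.frame.loc[list(keys)]
        return sub[self.feature_columns].to_numpy(dtype=float)

    def labels(self, keys: Sequence[str] | None = None) -> np.ndarray:
        sub = self.frame if keys is None else self.frame.loc[list(keys)]
        return sub["label"].to_numpy()

    def counts(self) -> dict[str, int]:
        c = self.frame["label"].value_counts().to_dict()
        return {lab: int(c.get(lab, 0)) for lab in ("positive", "negative", "unlabeled")}

    def subset(self, keys: Sequence[str]) -> "PairFeatureMatrix":
        return PairFeatureMatrix(self.frame.loc[list(keys)].copy())

    def balanced(self) -> "PairFeatureMatrix":
        """The labeled (positive + negative) rows only."""
        mask = self.frame["label"].isin(("positive", "negative"))
        return PairFeatureMatrix(self.frame[mask].copy())

    def save(self, path: str | Path) -> None:
        """Write as CSV (pair key first column; repr-precision floats)."""
        self.frame.to_csv(Path(path), index=True, index_label="pair")

    @classmethod
    def load(cls, path: str | Path) -> "PairFeatureMatrix":
        frame = pd.read_csv(Path(path), index_col="pair", float_precision="round_trip")
        return cls(frame)


@dataclass(frozen=True)
class PositiveCenter:
    """Anchor point for distance-based sampling.

    ``method="mean"`` is the arithmetic mean of the positive rows in the
    original feature space. ``method="pca-mean"`` first rotates the space
    with the principal axes of the positive rows (a complete orthonormal
    basis from an SVD, optionally truncated to ``pca_components``), then
    takes the mean of the projected rows; distances are computed in the
    projected space. With all components retained the rotation preserves
    Euclidean distances, so the two methods rank pairs identically.
    """

    center: np.ndarray
    method: Literal["mean", "pca-mean"]
    pca_components: int | Literal["all"] = "all"
    rotation: np.ndarray | None = None  # (q, width) orthonormal rows
    shift: np.ndarray | None = None  # mean subtracted before rotation

    def __post_init__(self) -> None:
        if not np.isfinite(self.center).all():
            raise ValueError("positive center contains non-finite entries")

    def distances(self, x: np.ndarray) -> np.ndarray:
        """Euclidean distance of each row of ``x`` from the center."""
        if self.rotation is not None:
            x = (x - self.shift) @ self.rotation.T
        return np.linalg.norm(x - self.center, axis=1)


@dataclass(frozen=True)
class SamplingPlan:
    """How to pick negatives: ``distance`` (deterministic) or ``random``.

    ``k=None`` means "as many negatives as there are positives" — the
    balanced design the benchmark uses.
    """

    method: Literal["distance", "random"] = "distance"
    k: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("distance", "random"):
            raise ValueError(f"unknown sampling method {self.method!r}")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")


def _feature_names(width: int) -> list[str]:
    return [f"f{i:03d}" for i in range(width)]


def assemble_pairs(
    interactions: InteractionTable,
    drug_matrix: pd.DataFrame,
    protein_matrix: pd.DataFrame,
) -> PairFeatureMatrix:
    """Build the full Cartesian pair matrix.

    Every (drug, target) pair gets the concatenation of its drug and
    protein feature rows; known interactions are labeled positive, all
    other pairs unlabeled. Every referenced id must have a feature row.
    """
    if not interactions.positives:
        raise ValueError("no positive interactions; positive center would be undefined")
    missing_d = [d for d in interactions.drugs if d not in drug_matrix.index]
    if missing_d:
        raise ValueError(f"drugs without feature rows: {missing_d[:5]}")
    missing_t = [t for t in interactions.targets if t not in protein_matrix.index]
    if missing_t:
        raise ValueError(f"targets without feature rows: {missing_t[:5]}")

    drugs = list(interactions.drugs)
    targets = list(interactions.targets)
    nd, nt = len(drugs), len(targets)
    dmat = drug_matrix.loc[drugs].to_numpy(dtype=float)
    pmat = protein_matrix.loc[targets].to_numpy(dtype=float)

    # drug-major Cartesian product
    features = np.hstack(
        [np.repeat(dmat, nt, axis=0), np.tile(pmat, (nd, 1))]
    )
    drug_col = np.repeat(drugs, nt)
    prot_col = np.tile(targets, nd)
    keys = [f"{d}{PAIR_SEP}{t}" for d, t in zip(drug_col, prot_col)]
    labels = [
        "positive" if (d, t) in interactions.positives else "unlabeled"
        for d, t in zip(drug_col, prot_col)
    ]
    frame = pd.DataFrame(features, index=pd.Index(keys, name="pair"),
                         columns=_feature_names(features.shape[1]))
    frame.insert(0, "drug_id", drug_col)
    frame.insert(1, "protein_id", prot_col)
    frame.insert(2, "label", labels)
    return PairFeatureMatrix(frame)


def positive_center(
    matrix: PairFeatureMatrix,
    method: Literal["mean", "pca-mean"] = "mean",
    pca_components: int | Literal["all"] = "all",
) -> PositiveCenter:
    """Compute the positive center (see :class:`PositiveCenter`)."""
    pos = matrix.features(matrix.keys("positive"))
    if pos.shape[0] == 0:
        raise ValueError("no positive rows; cannot define a positive center")
    if method == "mean":
        return PositiveCenter(center=pos.mean(axis=0), method="mean")
    if method != "pca-mean":
        raise ValueError(f"unknown center method {method!r}")
    shift = pos.mean(axis=0)
    # full_matrices=True keeps a complete orthonormal basis even when there
    # are fewer positives than features, so "all components" is a genuine
    # rotation and preserves distances exactly.
    _, _, vt = np.linalg.svd(pos - shift, full_matrices=True)
    q = vt.shape[0] if pca_components == "all" else int(pca_components)
    if not 1 <= q <= vt.shape[0]:
        raise ValueError(f"pca_components must be in 1..{vt.shape[0]}")
    rotation = vt[:q]
    projected = (pos - shift) @ rotation.T
    return PositiveCenter(
        center=projected.mean(axis=0),
        method="pca-mean",
        pca_components=pca_components,
        rotation=rotation,
        shift=shift,
    )


def rank_unlabeled(
    matrix: PairFeatureMatrix, center: PositiveCenter
) -> list[tuple[str, float]]:
    """Rank unlabeled pairs by distance from the positive center, descending.

    Ties are broken by the lexicographically smaller pair key so the
    ordering is reproducible across platforms.
    """
    keys = np.array(matrix.keys("unlabeled"))
    if keys.size == 0:
        return []
    dist = center.distances(matrix.features(keys))
    order = np.lexsort((keys, -dist))
    return [(str(keys[i]), float(dist[i])) for i in order]


def sample_negatives(
    matrix: PairFeatureMatrix,
    plan: SamplingPlan,
    center: PositiveCenter | None = None,
) -> PairFeatureMatrix:
    """Relabel ``k`` unlabeled pairs as negatives; returns a new matrix.

    ``distance``: the k pairs farthest from the positive center (reliable
    negatives — the farther a pair lies from every known interaction, the
    less likely it is to be a missed positive). Deterministic given the
    matrix. ``random``: uniform without replacement under ``plan.seed``.
    """
    counts = matrix.counts()
    k = plan.k if plan.k is not None else counts["positive"]
    if k > counts["unlabeled"]:
        raise ValueError(f"k={k} exceeds unlabeled pool size {counts['unlabeled']}")
    if plan.method == "distance":
        if center is None:
            center = positive_center(matrix, method="mean")
        chosen = [key for key, _ in rank_unlabeled(matrix, center)[:k]]
    else:
        rng = np.random.default_rng(plan.seed)
        pool = matrix.keys("unlabeled")
        chosen = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
    frame = matrix.frame.copy()
    frame.loc[chosen, "label"] = "negative"
    return PairFeatureMatrix(frame)


def split_cv(
    matrix: PairFeatureMatrix, folds: int = 5, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Stratified k-fold split of the labeled (positive/negative) rows.

    Returns ``folds`` (train_keys, test_keys) tuples; each labeled row
    appears in exactly one test fold, and the class ratio is preserved to
    within one row per class per fold.
    """
    balanced = matrix.balanced()
    keys = np.array(balanced.keys())
    labels = balanced.labels()
    for lab in ("positive", "negative"):
        if (labels == lab).sum() < folds:
            raise ValueError(f"fewer {lab} rows than folds={folds}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [
        (list(keys[train_idx]), list(keys[test_idx]))
        for train_idx, test_idx in skf.split(keys, labels)
    ]
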