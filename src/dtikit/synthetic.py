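"""Self-contained synthetic bipartite interaction studies.

Real DTI benchmarks cannot be redistributed or downloaded at test time, so
this module fabricates studies with the same shape: a pool of drugs (valid
SMILES), a pool of protein targets (generated sequences), a sparse positive
pair list, and — unlike real data — ground-truth interaction labels for
every pair.

Signal is planted through latent classes. Drugs of class *c* are drawn from
a curated pool of molecules sharing functional groups distinctive to that
class (hence distinctive E-state bits); targets of class *c* draw their
residues from a class-specific composition (a Dirichlet perturbation of the
uniform background, hence distinctive APAAC compositions). A pair (d, t) is
a true interaction with probability

    signal * [class(d) == class(t)] + (1 - signal) * positive_rate

so ``signal=0`` is a null study (interactions independent of features) and
``signal=1`` makes interaction equivalent to class matching. The observed
positive list is a uniform subsample of the true interactions at the target
``positive_rate``; the rest of the true interactions hide in the unlabeled
pool, exactly as in real positive-unlabeled data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import CANONICAL_AA, DrugRecord, InteractionTable, ProteinRecord

__all__ = [
    "SMILES_POOLS",
    "SyntheticStudyConfig",
    "SyntheticStudy",
    "generate_study",
    "emulate_gold_standard_shape",
    "GOLD_STANDARD_SHAPES",
    "write_study",
]

#: Curated class pools of valid SMILES. Each class carries distinct
#: functional groups so that E-state presence bits separate the classes:
#: 0 aliphatic alcohols/ethers, 1 (hetero)aromatics, 2 halogenated/nitro
#: compounds, 3 amines/amides/sulfones/nitriles.
SMILES_POOLS: tuple[tuple[str, ...], ...] = (
    (
        "CCO", "CCCO", "CC(C)O", "CCOC", "CCCC", "CC(C)CO", "OCCO",
        "CCCCO", "CC(C)(C)O", "CCOCC", "CCCOC", "OCC(O)CO",
    ),
    (
        "c1ccccc1", "Cc1ccccc1", "Oc1ccccc1", "COc1ccccc1",
        "c1ccc2ccccc2c1", "Cc1ccc(C)cc1", "Oc1ccc(C)cc1", "c1ccncc1",
        "Cc1ccncc1", "c1ccc(-c2ccccc2)cc1", "COc1ccc(O)cc1", "c1ccoc1",
    ),
    (
        "CCCl", "CCBr", "ClCCCl", "Clc1ccccc1", "O=[N+]([O-])c1ccccc1",
        "CC(C)Cl", "FC(F)F", "BrCCBr", "Clc1ccc(Cl)cc1",
        "CC[N+](=O)[O-]", "FCC(F)F", "ICCCl",
    ),
    (
        "CCN", "CCNC", "CC(=O)N", "CC(=O)NC", "CS(=O)(=O)C",
        "CS(=O)(=O)N", "NCCN", "CC(=O)NCC", "NC(=O)CC", "CC#N",
        "CCS", "CSC",
    ),
)

#: Sequence length bounds (uniform inclusive range).
SEQ_LENGTH_RANGE = (60, 300)

#: Dirichlet concentration for the class residue-frequency perturbation;
#: smaller = more distinct class compositions.
DIRICHLET_CONCENTRATION = 5.0


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Shape and signal of a synthetic study.

    ``signal`` in [0, 1] sets how strongly interaction follows the latent
    classes (0 = null study); ``positive_rate`` is the fraction of the
    drug x target Cartesian product reported as known positives.
    """

    n_drugs: int = 40
    n_targets: int = 40
    n_classes: int = 2
    signal: float = 0.8
    positive_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1 or self.n_targets < 1:
            raise ValueError("n_drugs and n_targets must be positive")
        if not 1 <= self.n_classes <= min(self.n_drugs, self.n_targets):
            raise ValueError("need 1 <= n_classes <= min(n_drugs, n_targets)")
        if self.n_classes > len(SMILES_POOLS):
            raise ValueError(f"at most {len(SMILES_POOLS)} classes supported")
        if not 0 <= self.signal <= 1:
            raise ValueError("signal must lie in [0, 1]")
        if not 0 < self.positive_rate < 1:
            raise ValueError("positive_rate must lie strictly between 0 and 1")

    @property
    def n_pairs(self) -> int:
        return self.n_drugs * self.n_targets

    @property
    def n_positive_target(self) -> int:
        """Number of observed positives implied by ``positive_rate``."""
        return round(self.positive_rate * self.n_pairs)

    @property
    def positive_pct(self) -> float:
        """Positive proportion of the pair space, in percent."""
        return 100.0 * self.n_positive_target / self.n_pairs


@dataclass(frozen=True)
class SyntheticStudy:
    """A generated study plus its ground truth."""

    config: SyntheticStudyConfig
    drugs: tuple[DrugRecord, ...]
    proteins: tuple[ProteinRecord, ...]
    interactions: InteractionTable
    true_interactions: frozenset[tuple[str, str]]
    drug_classes: dict[str, int] = field(default_factory=dict)
    target_classes: dict[str, int] = field(default_factory=dict)

    def is_true_negative(self, drug_id: str, protein_id: str) -> bool:
        return (drug_id, protein_id) not in self.true_interactions


def generate_study(config: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate a reproducible synthetic study (see module docstring).

    Raises if ``positive_rate`` asks for zero positives; when the Bernoulli
    stage yields fewer true interactions than the target count, all of them
    become observed positives (possible in near-null studies).
    """
    rng = np.random.default_rng(config.seed)
    k_target = config.n_positive_target
    if k_target < 1:
        raise ValueError("positive_rate too small: zero positives requested")

    drug_classes = {f"d{i:04d}": i % config.n_classes for i in range(config.n_drugs)}
    target_classes = {f"t{i:04d}": i % config.n_classes for i in range(config.n_targets)}

    drugs = tuple(
        DrugRecord(drug_id=d, smiles=SMILES_POOLS[c][rng.integers(len(SMILES_POOLS[c]))])
        for d, c in drug_classes.items()
    )

    lengths = rng.integers(SEQ_LENGTH_RANGE[0], SEQ_LENGTH_RANGE[1] + 1,
                           size=config.n_targets)
    class_freqs = rng.dirichlet(
        np.full(len(CANONICAL_AA), DIRICHLET_CONCENTRATION), size=config.n_classes
    )
    aa = np.array(list(CANONICAL_AA))
    proteins = tuple(
        ProteinRecord(
            protein_id=t,
            sequence="".join(rng.choice(aa, size=lengths[i], p=class_freqs[c])),
        )
        for i, (t, c) in enumerate(target_classes.items())
    )

    # Bernoulli truth, then uniform subsample to the observed positive list.
    true_pairs: list[tuple[str, str]] = []
    for d, cd in drug_classes.items():
        same = np.array([cd == ct for ct in target_classes.values()])
        prob = config.signal * same + (1 - config.signal) * config.positive_rate
        hits = rng.random(config.n_targets) < prob
        true_pairs.extend((d, t) for t, h in zip(target_classes, hits) if h)

    if not true_pairs:
        raise ValueError("no true interactions generated; positive_rate/signal infeasible")
    if len(true_pairs) > k_target:
        idx = rng.choice(len(true_pairs), size=k_target, replace=False)
        observed = [true_pairs[i] for i in sorted(idx)]
    else:
        observed = true_pairs

    interactions = InteractionTable(
        drugs=tuple(drug_classes),
        targets=tuple(target_classes),
        positives=frozenset(observed),
    )
    return SyntheticStudy(
        config=config,
        drugs=drugs,
        proteins=proteins,
        interactions=interactions,
        true_interactions=frozenset(true_pairs),
        drug_classes=drug_classes,
        target_classes=target_classes,
    )


#: (drugs, targets, positives) of the four published benchmark subdatasets.
GOLD_STANDARD_SHAPES: dict[str, tuple[int, int, int]] = {
    "enzyme": (445, 664, 2926),
    "gpcr": (223, 95, 635),
    "ion_channel": (210, 204, 1476),
    "nuclear_receptor": (54, 26, 90),
}


def emulate_gold_standard_shape(name: str, **overrides) -> SyntheticStudyConfig:
    """A config with the drug/target/positive counts of a benchmark subdataset.

    ``positive_rate`` is set to the exact positive fraction so that
    ``n_positive_target`` reproduces the published positive count. Other
    config fields (signal, seed, n_classes) keep their defaults unless
    overridden.
    """
    try:
        n_drugs, n_targets, n_pos = GOLD_STANDARD_SHAPES[name]
    except KeyError:
        raise ValueError(
            f"unknown dataset shape {name!r}; choose from {sorted(GOLD_STANDARD_SHAPES)}"
        ) from None
    config = SyntheticStudyConfig(
        n_drugs=n_drugs,
        n_targets=n_targets,
        positive_rate=n_pos / (n_drugs * n_targets),
    )
    return replace(config, **overrides) if overrides else config


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write a study as drugs.smi / targets.fasta / interactions.tsv / truth.tsv.

    Returns the paths written. Output is byte-identical for identical
    studies.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "smiles": out / "drugs.smi",
        "fasta": out / "targets.fasta",
        "interactions": out / "interactions.tsv",
        "truth": out / "truth.tsv",
    }
    with paths["smiles"].open("w") as fh:
        for rec in study.drugs:
            fh.write(f"{rec.smiles}\t{rec.drug_id}\n")
    with paths["fasta"].open("w") as fh:
        for rec in study.proteins:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
    with paths["interactions"].open("w") as fh:
        for d, t in sorted(study.interactions.positives):
            fh.write(f"{d}\t{t}\n")
    with paths["truth"].open("w") as fh:
        for d, t in sorted(study.true_interactions):
            fh.write(f"{d}\t{t}\n")
    return paths
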