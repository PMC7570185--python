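import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # smiles_fixtures / oracles

from dtikit.dataset import assemble_pairs
from dtikit.drug_features import featurize_drugs
from dtikit.protein_features import featurize_proteins
from dtikit.synthetic import SyntheticStudyConfig, generate_study


def featurized_study(config: SyntheticStudyConfig):
    """Generate a study and assemble its full pair feature matrix."""
    study = generate_study(config)
    matrix = assemble_pairs(
        study.interactions,
        featurize_drugs(study.drugs),
        featurize_proteins(study.proteins),
    )
    return study, matrix


@pytest.fixture(scope="session")
def small_study():
    """A 12x12 two-class study with strong planted signal."""
    return generate_study(
        SyntheticStudyConfig(
            n_drugs=12, n_targets=12, n_classes=2, signal=0.9, positive_rate=0.15, seed=11
        )
    )


@pytest.fixture(scope="session")
def small_matrix(small_study):
    return assemble_pairs(
        small_study.interactions,
        featurize_drugs(small_study.drugs),
        featurize_proteins(small_study.proteins),
    )
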