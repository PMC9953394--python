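import numpy as np
import pytest

from g4vivo.dataset import LabeledDataset
from g4vivo.features import build_feature_matrix
from g4vivo.labeling import label_entries
from g4vivo.synthetic import SyntheticConfig, generate_synthetic_study


@pytest.fixture(scope="session")
def small_study():
    """A miniature planted study: 1 chromosome, 150 candidates, strong skew
    softened (15% active) so both classes are well populated at small n."""
    cfg = SyntheticConfig(
        n_chroms=1, chrom_length=400_000, n_candidates=150, active_fraction=0.15
    )
    return generate_synthetic_study(cfg, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_study):
    """Labeled feature dataset built from the small study (2200 columns)."""
    s = small_study
    lab = label_entries(s.candidates, s.invivo)
    fm = build_feature_matrix(lab, s.track, s.genome)
    return LabeledDataset.from_labeled_candidates(lab, fm)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
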