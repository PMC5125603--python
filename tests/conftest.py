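import numpy as np
import pytest

from harhmm.hierarchy import ThreeStageClassifier
from harhmm.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def synth_default():
    """The generator's default six-activity corpus (train, test)."""
    return generate(SyntheticSpec())


@pytest.fixture(scope="session")
def fitted_three_stage(synth_default):
    """A three-stage classifier fitted once on the default corpus."""
    train, _ = synth_default
    clf = ThreeStageClassifier(random_state=0)
    clf.fit(train.X, train.y, feature_names=train.feature_names)
    return clf


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
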