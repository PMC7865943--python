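import warnings

import numpy as np
import pytest

from haradapt import generate_cohort

from helpers import featurize_recording  # noqa: F401  (tests dir on sys.path)


@pytest.fixture(scope="session")
def cohort_small():
    """7 shifted subjects at default difficulty, scaled down for speed."""
    recs, manifest = generate_cohort(n_subjects=7, difficulty=1.0, segments_per_class=12, seed=7)
    return recs, manifest


@pytest.fixture(scope="session")
def two_domain(cohort_small):
    """Pooled 2-subject source and one 70-segment target from the cohort."""
    recs, _ = cohort_small
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        feats = [featurize_recording(r) for r in recs[:3]]
    Xs = np.hstack([feats[0][0], feats[1][0]])
    ys = np.concatenate([feats[0][1], feats[1][1]])
    Xt, yt = feats[2]
    return Xs, ys, Xt, yt


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Shifted cohorts legitimately produce empty-cluster/absent-class warnings."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="empty K-means cluster")
        warnings.filterwarnings("ignore", message="class\\(es\\).*absent")
        warnings.filterwarnings("ignore", message="class with zero predicted positives")
        yield
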