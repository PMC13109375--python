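import numpy as np
import pytest

import connlearn as cl
from connlearn import synthgen as sg

PLANTED_FC = ("lAMY-lHIP", "lHIP-lPFC", "rAMY-rHIP")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_study_designs():
    return [
        sg.StudyDesign("S1", "FL", "SCR", 30),
        sg.StudyDesign("S4", "PL", "behavioural", 30),
    ]


@pytest.fixture(scope="session")
def planted_cohort(two_study_designs):
    """Small two-study cohort with a 3-edge FC effect planted on acquisition."""
    effect = sg.PlantedEffect(
        modality="FC", effect_edges=PLANTED_FC, coefficients=(1.0, 1.0, 1.0),
        target_r2=0.15,
    )
    return sg.gen_cohort(two_study_designs, effect=effect, seed=1)


@pytest.fixture(scope="session")
def acquisition_design(planted_cohort):
    scores = cl.score_cohort(planted_cohort, "acquisition")
    return cl.build_design(planted_cohort, "FC", "acquisition", scores)


def random_design(rng, n=60, p=10, r2=0.0, k=3, labels=None, groups=None):
    """Matrix-level design helper: optional planted k-predictor effect."""
    X = rng.standard_normal((n, p))
    if r2 > 0:
        beta = np.zeros(p)
        beta[:k] = 1.0
        signal = X @ beta
        noise_sd = np.sqrt(signal.var() * (1 - r2) / r2)
        y = signal + noise_sd * rng.standard_normal(n)
    else:
        y = rng.standard_normal(n)
    return cl.DesignMatrix(
        X=X,
        y=y,
        labels=labels or [f"x{i}" for i in range(p)],
        penalty_exempt=np.zeros(p, dtype=bool),
        penalty_weights=np.ones(p),
        groups=np.asarray(groups if groups is not None else ["S1"] * n),
        paradigm=np.asarray(["FL"] * n),
    )
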