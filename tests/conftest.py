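import numpy as np
import pandas as pd
import pytest

import bingedbs as bd


@pytest.fixture(scope="session")
def uniform_recording() -> bd.LFPRecording:
    """60 s, 4-channel recording with one shared source per band (a = 1)."""
    spec = bd.MixingSpec.from_shared_gains(np.ones((4, 6)), duration=60.0, seed=11)
    return bd.simulate_lfp_recording(spec)


@pytest.fixture(scope="session")
def uniform_features(uniform_recording) -> bd.FeatureVector:
    return bd.extract_feature_vector(uniform_recording, animal_id="a0", session_id="T1")


@pytest.fixture(scope="session")
def null_design() -> bd.DesignMatrix:
    """Feature-level null cohort: 12 animals x 2 sessions, labels random."""
    rng = np.random.default_rng(42)
    animals = np.repeat([f"a{i:02d}" for i in range(12)], 2)
    X = pd.DataFrame(
        rng.standard_normal((24, 60)), columns=[f"f{i:02d}" for i in range(60)]
    )
    y = np.repeat([0] * 6 + [1] * 6, 2)
    return bd.DesignMatrix(X=X, y=y, groups=animals)


@pytest.fixture(scope="session")
def planted_design(null_design) -> bd.DesignMatrix:
    """Null cohort plus one feature separated by 6 within-group SDs."""
    X = null_design.X.copy()
    X["f00"] = X["f00"] + 6.0 * null_design.y
    return bd.DesignMatrix(X=X, y=null_design.y, groups=null_design.groups)
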