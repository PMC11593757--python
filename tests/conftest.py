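import math

import numpy as np
import pytest

from careband.synth import ContaminantProbs, Disruption, ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture
def clean_config():
    """Tiny single-factor scenario with no contaminants or nuisance noise."""
    return ScenarioConfig(
        n_persons=400,
        baseline_log_rate={"bp": math.log(0.1)},
        seasonal_amplitude={"bp": 0.0},
        seasonal_phase={"bp": 0.0},
        age_effect={b: 0.0 for b in ("18-39", "40-59", "60-79", "80+")},
        sex_effect={"female": 0.0, "male": 0.0},
        ethnicity_effect={e: 0.0 for e in
                          ("White", "Asian", "Black", "Mixed", "Other/Unknown")},
        imd_effect={q: 0.0 for q in range(1, 6)},
        annual_trend=0.0,
        disruption={"bp": Disruption(depth=1.0)},
        dispersion_phi=1.0,
        dup_prob=0.0,
        valueless_prob=0.0,
        contaminants=ContaminantProbs(0.0, 0.0, 0.0, 0.0),
        death_hazard={b: 0.0 for b in ("18-39", "40-59", "60-79", "80+")},
        seed=11,
    )
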