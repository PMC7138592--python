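"""Shared fixtures: small phantom cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from wmlpredict import default_phantom_spec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject default phantom with DTI channels (session-wide)."""
    return generate_cohort(default_phantom_spec(n_subjects=12, seed=11))


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Cohort whose scores carry zero noise (for generative-model checks)."""
    from dataclasses import replace

    spec = default_phantom_spec(n_subjects=30, seed=23, include_dti=False)
    silent = {
        name: replace(m, noise_sd=0.0) for name, m in spec.score_model.items()
    }
    return generate_cohort(spec.replace(score_model=silent))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
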