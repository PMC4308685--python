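import numpy as np
import pytest

from tedg.cohort_io import CohortTable, LesionMeasurement


@pytest.fixture
def stable_noise_cohort():
    """200 patients, one sample pair each; every pair's frequency change
    is drawn with the model's own noise law at sigma = 0.03 (no
    treatment)."""
    rng = np.random.default_rng(12345)
    sigma = 0.03
    ms = []
    for i in range(200):
        f_ngs = 0.3 + rng.normal(0, sigma * np.sqrt(0.3 * 0.7))
        f_fish = 0.4 + rng.normal(0, sigma * np.sqrt(0.4 * 0.6))
        for t, fn, ff in ((0.0, 0.3, 0.4), (12.0, f_ngs, f_fish)):
            ms.append(LesionMeasurement(f"P{i:03d}", t, "mutA", "NGS",
                                        float(np.clip(fn, 0, 1)), 1.0))
            ms.append(LesionMeasurement(f"P{i:03d}", t, "delB", "FISH",
                                        float(np.clip(ff, 0, 1)), 1.0))
    return CohortTable(ms)
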