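import numpy as np
import pytest

import wavegap as wg
import wavegap.columns as C


@pytest.fixture(scope="session")
def cohort():
    """Mid-sized default cohort shared across read-only tests."""
    params = wg.GeneratorParams(n_participants=3000, seed=5)
    return wg.generate_cohort(params)


@pytest.fixture(scope="session")
def masked_cohort(cohort):
    """Cohort with the ideation item masked at wave 2, plus held-out truth."""
    masked, record = wg.mask_wave_item(cohort, C.IDEATION_ITEM, "W2")
    truth_bin = wg.dichotomize_ideation(np.asarray(record.truth, dtype=np.int64))
    return masked, record, truth_bin


@pytest.fixture(scope="session")
def completed_phq_bin(masked_cohort):
    """A small PHQ-BIN completed set reused by several checks."""
    from wavegap.fcs import prepare_target_column

    masked, record, _ = masked_cohort
    work, _name = prepare_target_column(masked, C.IDEATION_ITEM, "binary")
    specs, visit = wg.apply_preset("PHQ-BIN")
    cfg = wg.ImputationConfig(preset="PHQ-BIN", m_imputations=5,
                              visit_sequence=visit, seed=404)
    return wg.fit_fcs(work, specs, cfg)
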