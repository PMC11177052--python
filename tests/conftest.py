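import warnings

import pytest

from icuglucose.curate import curate
from icuglucose.match import build_analysis_table
from icuglucose.synth import SynthConfig, generate_cohort


def _cohort(config: SynthConfig):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle, truth = generate_cohort(config)
        curated, included, report = curate(bundle)
        rows = build_analysis_table(bundle, curated, included)
    return bundle, truth, curated, included, report, rows


@pytest.fixture(scope="session")
def small_cohort():
    """120-patient default-truth cohort shared by read-only tests."""
    return _cohort(SynthConfig(n_patients=120, seed=5))


@pytest.fixture(scope="session")
def small_rows(small_cohort):
    return small_cohort[5]


@pytest.fixture(scope="session")
def m4_fits(small_rows):
    """REML and ML fits of the final model on the shared cohort."""
    from icuglucose.models import fit_model

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            "REML": fit_model(small_rows, "m4", reml=True),
            "ML": fit_model(small_rows, "m4", reml=False),
        }
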