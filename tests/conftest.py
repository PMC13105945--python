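import numpy as np
import pytest

from acfc.bandpower import band_power_series, zscore_global
from acfc.synth import SynthSpec, synth_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort: 5 participants, 600 s at 1 kHz,
    designed same-type envelope correlation 0.6, cross-type 0.2."""
    return synth_cohort(SynthSpec(seed=11))


@pytest.fixture(scope="session")
def cohort_bandpower(default_cohort):
    """Globally z-scored 2-s/1-s band-power series per participant and muscle."""
    scheme = default_cohort.spec.scheme()
    out = []
    for chans in default_cohort.participants:
        out.append({
            name: [zscore_global(s) for s in band_power_series(rec, scheme)]
            for name, rec in chans.items() if rec.kind.value == "emg"
        })
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
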