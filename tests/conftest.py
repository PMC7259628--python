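import numpy as np
import pytest

from tumorkinetics.io import PatientSeries, ScanRecord


def make_series(points, pid="P1", new_lesion_at=()):
    """Build a PatientSeries from (t, sld) pairs; new_lesion_at marks times."""
    scans = [
        ScanRecord(pid, float(t), float(sld), t in new_lesion_at) for t, sld in points
    ]
    return PatientSeries(pid, scans)


def segmented_sld(t, y0, rg, rs):
    """Noise-free segmented exponential: the model's own data-generating curve."""
    t = np.asarray(t, dtype=float)
    rate = np.where(t <= 0, rg, rs)
    return y0 * np.exp(rate * t)


@pytest.fixture
def flat_series():
    return make_series([(-2.0, 100.0), (-0.5, 100.0), (1.4, 100.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
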