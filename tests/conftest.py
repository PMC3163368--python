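import numpy as np
import pytest
from hypothesis import settings

from seldiclass.spectra import CANCER, CONTROL, MzGrid, SpectraSet, Spectrum

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_set(cancer_rows, control_rows, mz=None) -> SpectraSet:
    """Build a SpectraSet from two lists of intensity rows."""
    cancer_rows = np.atleast_2d(np.asarray(cancer_rows, dtype=float))
    control_rows = np.atleast_2d(np.asarray(control_rows, dtype=float))
    n_feat = cancer_rows.shape[1]
    if mz is None:
        mz = np.arange(1.0, n_feat + 1.0)
    grid = MzGrid(np.asarray(mz, dtype=float))
    spectra, labels = [], {}
    for i, row in enumerate(cancer_rows):
        sid = f"can{i}"
        spectra.append(Spectrum(sid, row))
        labels[sid] = CANCER
    for i, row in enumerate(control_rows):
        sid = f"con{i}"
        spectra.append(Spectrum(sid, row))
        labels[sid] = CONTROL
    return SpectraSet(grid, spectra, labels)


@pytest.fixture
def separable_set() -> SpectraSet:
    """40 samples, 3 features; feature 0 separates the classes with a gap."""
    rng = np.random.default_rng(7)
    cancer = np.column_stack(
        [rng.uniform(5.0, 6.0, 20), rng.normal(3.0, 1.0, 20), rng.normal(1.0, 0.5, 20)]
    )
    control = np.column_stack(
        [rng.uniform(1.0, 2.0, 20), rng.normal(3.0, 1.0, 20), rng.normal(1.0, 0.5, 20)]
    )
    return make_set(np.abs(cancer), np.abs(control))
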