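import numpy as np
import pytest

from biodyn.features import extract_feature_table, fit_zscores, pool_features
from biodyn.holography import OpticsConfig
from biodyn.phenotyping import phenotype_wells
from biodyn.spectral import SpectralModel
from biodyn.spectroscopy import drug_response_spectrogram
from biodyn.trial import TrialDesign, simulate_trial


@pytest.fixture(scope="session")
def knee_model():
    return SpectralModel(s0=1.0, knee_freq=0.4, slope=1.7, floor=1e-3)


@pytest.fixture(scope="session")
def small_optics():
    return OpticsConfig(image_px=256)


@pytest.fixture(scope="session")
def small_trial():
    """A small but complete two-cohort trial, processed to biomarkers.

    4 + 4 patients x (4 drugs x 3 wells + 2 controls): enough structure
    to exercise phenotyping and aggregation while staying fast.
    """
    design = TrialDesign(
        n_resistant=4,
        n_sensitive=4,
        wells_per_drug=3,
        n_control_wells=2,
        seed=11,
    )
    ds = simulate_trial(design)
    meta, features = extract_feature_table(ds.wells)
    biomarkers = pool_features(features, zstats=fit_zscores(features))
    spectrograms = {w.well_id: drug_response_spectrogram(w) for w in ds.wells}
    treated = meta.index[meta["drug"] != "medium"]
    assignment = phenotype_wells(biomarkers.loc[treated], spectrograms, k=4)
    return {
        "dataset": ds,
        "meta": meta,
        "features": features,
        "biomarkers": biomarkers,
        "spectrograms": spectrograms,
        "assignment": assignment,
        "treated": treated,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
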