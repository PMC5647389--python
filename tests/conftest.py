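import pytest

from peaktarget import (
    SimConfig,
    SummitClassifier,
    simulate_annotation,
    simulate_peaks,
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        seed=7, n_chroms=2, n_genes=30, n_peaks=100,
        n_deg_down=40, n_deg_up=40, n_nonsig=300,
        frac_deg_with_peak=0.25, n_qc_genes=200,
    )


@pytest.fixture(scope="session")
def models(small_config):
    return simulate_annotation(small_config)


@pytest.fixture(scope="session")
def peaks_and_truth(small_config, models):
    return simulate_peaks(small_config, models)


@pytest.fixture(scope="session")
def fitted_classifier(models):
    return SummitClassifier().fit(models)
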