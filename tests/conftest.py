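import numpy as np
import pytest

import specfusion as sf


@pytest.fixture(scope="session")
def study():
    """Default-noise synthetic study (the standard test bed)."""
    return sf.generate_dataset(sf.DesignConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_study():
    """Ideal spectra: exactly affine in concentration."""
    return sf.generate_dataset(sf.DesignConfig.noiseless(seed=7))


@pytest.fixture(scope="session")
def pipeline_reports():
    """Full end-to-end runs for seeds 0..4 (shared across tests)."""
    from specfusion.pipeline import run_experiment

    return {seed: run_experiment({"seed": seed}) for seed in range(5)}


def make_set(block, concs=None, meshes=None, reps=None, modality="NIR",
             unit="nm", axis=None):
    """Small SpectraSet builder for unit tests."""
    block = np.atleast_2d(np.asarray(block, dtype=float))
    n, p = block.shape
    if axis is None:
        axis = np.arange(p, dtype=float) * 2.0 + 860.0
    meta = [
        sf.SampleMeta(
            sample_id=f"s{i}",
            concentration=None if concs is None else float(concs[i]),
            mesh=None if meshes is None else int(meshes[i]),
            replicate=None if reps is None else int(reps[i]),
        )
        for i in range(n)
    ]
    return sf.SpectraSet(sf.SpectralAxis(modality, unit, axis), block, meta)


@pytest.fixture()
def spectra_builder():
    return make_set
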