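import dataclasses

import numpy as np
import pytest

from eicapvt import synthetic as syn


@pytest.fixture(scope="session")
def small_shape():
    return (8, 8, 6)


@pytest.fixture(scope="session")
def small_network(small_shape):
    """One compact task-positive network with finite-support response,
    so noiseless deconvolution is exact."""
    net = syn.gaussian_blob_network(
        small_shape,
        [(4.0, 4.0, 3.0)],
        sigma_vox=1.2,
        name="blob",
        amp={("normal", "HS"): 1.0, ("normal", "SS"): 0.9,
             ("lapse", "HS"): 1.5, ("lapse", "SS"): 1.5},
        latency_shift={("lapse", "HS"): 1.0, ("lapse", "SS"): 1.0},
    )
    # support + the 1-s lapse latency shift must stay inside the 32-s
    # deconvolution window for exact recovery
    return dataclasses.replace(net, support_s=31.0)


@pytest.fixture(scope="session")
def isolated_schedule():
    """Events far enough apart that their 48-s windows never overlap."""
    onsets = np.array([40.0, 100.0, 160.0, 220.0])
    return syn.PvtSchedule(
        onsets=onsets,
        isis=np.diff(np.concatenate([[0.0], onsets])),
        n_sets=1,
        isi_values=(40.0, 60.0),
    )


@pytest.fixture()
def noiseless_session(small_shape, small_network, isolated_schedule):
    spec = syn.SyntheticSessionSpec(shape=small_shape, noise_sigma=0.0, seed=7)
    rts = np.array([300.0, 600.0, 320.0, 650.0])
    return syn.synthesize_session(
        spec, isolated_schedule, rts, [small_network], "HS"
    )


@pytest.fixture()
def noisy_session(small_shape, small_network, isolated_schedule):
    spec = syn.SyntheticSessionSpec(shape=small_shape, noise_sigma=0.4, seed=11)
    rts = np.array([310.0, 640.0, 290.0, 700.0])
    return syn.synthesize_session(
        spec, isolated_schedule, rts, [small_network], "SS"
    )
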