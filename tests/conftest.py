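"""Shared fixtures: scaled-down designs and simulated subjects.

Unit tests run the full pipeline logic on reduced problem sizes (fewer
blocks/repetitions, 8-16 electrodes, 128 Hz) so the suite stays fast; the
structural-constant tests construct the full default design where counting
is the point.
"""

import numpy as np
import pandas as pd
import pytest

import graspmvpa as g


SMALL = dict(blocks_per_action=2, reps_per_object=2, sampling_rate=128.0,
             epoch_window=(-100.0, 400.0), n_electrodes=8)


@pytest.fixture(scope="session")
def montage8():
    return g.standard_montage(8)


@pytest.fixture(scope="session")
def montage16():
    return g.standard_montage(16)


@pytest.fixture(scope="session")
def small_design():
    return g.build_design(1, seed=13, **SMALL)


@pytest.fixture(scope="session")
def null_epochs(small_design, montage8):
    """One subject of pure correlated noise (no invalid trials)."""
    return g.simulate_epochs(small_design, [],
                             g.NoiseModel(invalid_fraction=0.0),
                             seed=21, montage=montage8)[0]


@pytest.fixture(scope="session")
def montage64():
    return g.standard_montage(64)


@pytest.fixture(scope="session")
def dense_epochs(montage64):
    """Noise-only subject on the full 64-electrode montage, short epochs.

    Cleaning operates on local neighbor correlations, which only behave
    realistically at full electrode density; the short epoch keeps it cheap.
    """
    d = g.build_design(1, seed=17, blocks_per_action=1, reps_per_object=2,
                       sampling_rate=256.0, epoch_window=(-100.0, 150.0),
                       n_electrodes=64)
    return g.simulate_epochs(d, [], g.NoiseModel(invalid_fraction=0.0),
                             seed=19, montage=montage64)[0]


@pytest.fixture(scope="session")
def default_trial_labels():
    """Trial table of the full default design (labels only, no signal)."""
    return g.build_design(1, seed=5).trial_tables[0]


@pytest.fixture(scope="session")
def default_pseudo_labels(default_trial_labels):
    """Pseudo-trial label table of the full default design.

    Built through average_pseudotrials on a stub EpochSet with 2 electrodes
    and 4 samples, so the (block, object) bookkeeping is exercised without
    simulating full-size data.
    """
    lab = default_trial_labels.copy()
    lab["valid"] = True
    lab["reaction_time"] = 300.0
    stub = g.EpochSet(subject=0, data=np.zeros((len(lab), 2, 4)),
                      times=np.arange(4, dtype=float), labels=lab, sfreq=512.0)
    return g.average_pseudotrials(stub).labels
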