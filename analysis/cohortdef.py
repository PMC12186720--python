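"""Shared definition of the demonstration cohort used by the analysis scripts.

One place to hold the scaled-down study conditions (8 subjects, 3 blocks per
movement type, 16 electrodes, 128 Hz) and the injected ground truth: a
grasp-specific reactivated color code (early window re-appearing later, same
topography, mirrored in beta band) and a sustained shape code present for
both actions.
"""

from pathlib import Path

import numpy as np

import graspmvpa as g

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

SEED = 20260901

_SFREQ = 256.0
_WINDOW_MS = 5 * 1000.0 / _SFREQ               # ~19.5 ms feature windows


def _edge(k: int) -> float:
    """k-th feature-window edge relative to the -100 ms epoch start."""
    return -100.0 + k * _WINDOW_MS


# the reactivated color code re-appears ~250-330 ms with the topography it
# had ~134-212 ms; windows are aligned to the feature-window grid
_COLOR_WINDOWS = [(_edge(12), _edge(16)), (_edge(18), _edge(22))]

COHORT = dict(
    n_subjects=8,
    blocks_per_action=3,
    reps_per_object=4,
    sampling_rate=_SFREQ,
    epoch_window=(-100.0, 520.0),
    n_electrodes=16,
    effects=[
        dict(feature="color", dynamic="reactivated", windows=_COLOR_WINDOWS,
             amplitude=1.2, action_specific=True),
        dict(feature="color", dynamic="reactivated", windows=_COLOR_WINDOWS,
             amplitude=1.5, carrier="beta", action_specific=True),
        dict(feature="shape", dynamic="sustained",
             windows=[(130.0, 450.0)], amplitude=1.0),
    ],
)


def cohort_montage() -> g.Montage:
    return g.standard_montage(COHORT["n_electrodes"])


def cohort_effects(montage: g.Montage) -> list[g.GroundTruthEffect]:
    # spatially separated sources per feature: overlapping same-site codes
    # would add feature-interaction terms to band power that neither the
    # recordings they emulate nor the decoding contrasts assume
    pos = montage.positions_mm
    posterior_right = int(np.argmin(pos[:, 1] - 0.6 * pos[:, 0]))
    posterior_left = int(np.argmin(pos[:, 1] + 0.6 * pos[:, 0]))
    centers = {"color": posterior_right, "shape": posterior_left}
    out = []
    for spec in COHORT["effects"]:
        topo = g.make_topography(montage, centers[spec["feature"]],
                                 fwhm_mm=50.0)
        out.append(g.GroundTruthEffect(
            feature=spec["feature"], dynamic=spec["dynamic"],
            windows=spec["windows"], topography=topo,
            amplitude=spec["amplitude"], carrier=spec.get("carrier"),
            action_specific=spec.get("action_specific", False)))
    return out


def simulate_cohort(seed: int = SEED):
    montage = cohort_montage()
    design = g.build_design(
        COHORT["n_subjects"], seed=seed,
        blocks_per_action=COHORT["blocks_per_action"],
        reps_per_object=COHORT["reps_per_object"],
        sampling_rate=COHORT["sampling_rate"],
        epoch_window=COHORT["epoch_window"],
        n_electrodes=COHORT["n_electrodes"])
    subjects = g.simulate_epochs(design, cohort_effects(montage),
                                 g.NoiseModel(), seed=seed + 1,
                                 montage=montage)
    return design, subjects


def cleaned_features(band: str | None = None):
    """Simulate, clean and featurize the whole cohort (one tensor/subject)."""
    from graspmvpa.pipeline import features_for_subject

    montage = cohort_montage()
    _, subjects = simulate_cohort()
    tensors = []
    for ep in subjects:
        clean, _ = g.clean_epochs(ep, montage)
        tensors.append(features_for_subject(clean, band))
    return montage, tensors
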