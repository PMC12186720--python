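"""Temporal generalization and ROI-based reactivation test for color.

Builds train-time x test-time accuracy matrices for color in both pools,
contrasts grasping vs knuckling within the geometric ROIs of the
generalization plane (baseline / diagonal / arms / triangular), and labels
the dominant dynamic. The injected grasp-specific color code reactivates an
early topography later, so the arms ROI should carry the difference.

Run from the repository root:  python analysis/03_generalization_rois.py
"""

import json

import numpy as np

import graspmvpa as g
from graspmvpa.inference import ROISpec
from graspmvpa.io import gmats_to_frame
from cohortdef import RESULTS, SCRATCH, SEED, cleaned_features


def scaled_rois() -> dict[str, ROISpec]:
    """Default ROI geometry rescaled to ~39 ms windows (see docs/methods.md)."""
    arms = ROISpec("arms", "arms", diag_halfwidth_ms=45.0,
                   train_band=(140.0, 210.0), test_band=(240.0, 500.0))
    return {
        "baseline": ROISpec("baseline", "box", t_range=(-100.0, 50.0)),
        "diagonal": ROISpec("diagonal", "diagonal", diag_halfwidth_ms=45.0),
        "arms": arms,
        "triangular": ROISpec("triangular", "triangular",
                              diag_halfwidth_ms=45.0, exclude=(arms,)),
    }


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    _, tensors = cleaned_features()

    gmats = {"grasping": [], "knuckling": []}
    centers = None
    for subj, ft in enumerate(tensors):
        for pool in gmats:
            scheme = g.make_cv_scheme(ft.labels, "color", pool, seed=SEED)
            gm = g.decode_generalization(ft, scheme, t_min=-100.0, t_max=500.0)
            gm.subject = subj
            gmats[pool].append(gm)
            centers = gm.window_centers_ms

    res = g.roi_difference_test(
        np.array([m.accuracy for m in gmats["grasping"]]),
        np.array([m.accuracy for m in gmats["knuckling"]]),
        centers, rois=scaled_rois(), n_boot=10_000, seed=SEED)

    report = {"differences": res.differences, "ci_lower": res.ci_lower,
              "ci_upper": res.ci_upper, "significant": res.significant,
              "dynamics": g.classify_dynamics(res)}
    (RESULTS / "03_roi_test.json").write_text(json.dumps(report, indent=2))
    # group-mean matrices to results/, bulky per-subject tables to scratch/
    mean_rows = []
    for pool, mats in gmats.items():
        mean = np.mean([m.accuracy for m in mats], axis=0)
        for i, tr in enumerate(centers):
            for j, te in enumerate(centers):
                mean_rows.append({"pool": pool, "train_ms": tr, "test_ms": te,
                                  "accuracy": round(float(mean[i, j]), 4)})
    import pandas as pd
    pd.DataFrame(mean_rows).to_csv(RESULTS / "03_generalization_mean.csv",
                                   index=False)
    SCRATCH.mkdir(exist_ok=True)
    gmats_to_frame(gmats["grasping"] + gmats["knuckling"]).to_csv(
        SCRATCH / "03_generalization_full.csv", index=False)

    for name in res.differences:
        star = " *" if res.significant.get(name) else ""
        print(f"{name:10s} grasp-knuckle diff {res.differences[name]:+.3f} "
              f"[{res.ci_lower[name]:+.3f}, {res.ci_upper[name]:+.3f}]{star}")
    print(f"dominant dynamic: {report['dynamics']}")
    print(f"wrote {RESULTS / '03_roi_test.json'} and 03_generalization_mean.csv")


if __name__ == "__main__":
    main()
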