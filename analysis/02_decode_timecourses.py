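"""Time-resolved decoding of shape and color for grasping vs knuckling.

Decodes the cleaned cohort per subject and pool, runs the group-level
cluster-based sign-permutation test against chance, and writes the curves
(long CSV) plus a cluster summary. The injected ground truth predicts
above-chance color decoding in the grasping pool only (the color code is
grasp-specific) and shape decoding in both pools.

Run from the repository root:  python analysis/02_decode_timecourses.py
"""

import json

import numpy as np

import graspmvpa as g
from graspmvpa.io import curves_to_frame
from cohortdef import RESULTS, SEED, cleaned_features


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    _, tensors = cleaned_features()

    curves = []
    clusters = {}
    for effect in ("shape", "color"):
        for pool in ("grasping", "knuckling"):
            per_subj = []
            for subj, ft in enumerate(tensors):
                scheme = g.make_cv_scheme(ft.labels, effect, pool, seed=SEED)
                c = g.decode_timeresolved(ft, scheme)
                c.subject = subj
                curves.append(c)
                per_subj.append(c.accuracy)
            res = g.cluster_test_time(np.array(per_subj), n_perm=10_000,
                                      seed=SEED)
            t = curves[-1].window_centers_ms
            sig = res.significant_mask
            spans = [(float(t[c.members[0]]), float(t[c.members[-1]]))
                     for c in res.clusters if c.significant]
            clusters[f"{effect}:{pool}"] = {
                "significant_windows": int(sig.sum()),
                "cluster_spans_ms": spans,
                "peak_accuracy": float(np.array(per_subj).mean(0).max()),
                "peak_ms": float(t[np.array(per_subj).mean(0).argmax()])}
            print(f"{effect:6s} {pool:9s}: peak "
                  f"{clusters[f'{effect}:{pool}']['peak_accuracy']:.2f} at "
                  f"{clusters[f'{effect}:{pool}']['peak_ms']:.0f} ms, "
                  f"significant spans {spans}")

    curves_to_frame(curves).to_csv(RESULTS / "02_curves.csv", index=False)
    (RESULTS / "02_clusters.json").write_text(json.dumps(clusters, indent=2))
    print(f"wrote {RESULTS / '02_curves.csv'} and 02_clusters.json")


if __name__ == "__main__":
    main()
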