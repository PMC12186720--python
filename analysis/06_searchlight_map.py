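"""Electrode searchlight: where on the scalp the color code is decodable.

Decodes color within each electrode's spatial neighborhood per 100-ms bin
for the grasping pool and runs the spatial cluster test per bin. The
injected topography is a posterior blob, so significant electrodes should
cluster over posterior sites during the effect windows.

Run from the repository root:  python analysis/06_searchlight_map.py
"""

import json

import numpy as np
import pandas as pd

import graspmvpa as g
from cohortdef import RESULTS, SEED, cohort_montage, simulate_cohort


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    montage = cohort_montage()
    _, subjects = simulate_cohort()

    maps = []
    for ep in subjects:
        clean, _ = g.clean_epochs(ep, montage)
        ps = g.z_winsorize(g.noise_normalize(g.average_pseudotrials(clean)))
        scheme = g.make_cv_scheme(ps.labels, "color", "grasping", seed=SEED)
        sm = g.searchlight_decode(ps, montage, scheme, radius_mm=60.0)
        sm.subject = ep.subject
        maps.append(sm)

    stack = np.array([m.accuracy for m in maps])     # subj x elec x bin
    bins = maps[0].bin_centers_ms
    # cluster adjacency uses a wider radius than the searchlight: the
    # 16-electrode demo montage is sparse, and electrodes without any
    # neighbor can never form a supra-threshold cluster of size > 1
    results = g.cluster_test_spatial(stack, montage.adjacency(95.0),
                                     n_perm=5000, seed=SEED)

    rows, sig_summary = [], {}
    for b, res in enumerate(results):
        sig = res.significant_mask
        names = [montage.names[i] for i in np.flatnonzero(sig)]
        sig_summary[f"{bins[b]:.0f}ms"] = names
        for e in range(stack.shape[1]):
            rows.append({"electrode": montage.names[e],
                         "bin_ms": bins[b],
                         "mean_accuracy": stack[:, e, b].mean(),
                         "significant": bool(sig[e])})
        if names:
            print(f"bin {bins[b]:5.0f} ms: significant electrodes {names}")

    pd.DataFrame(rows).to_csv(RESULTS / "06_searchlight.csv", index=False)
    (RESULTS / "06_searchlight_clusters.json").write_text(
        json.dumps(sig_summary, indent=2))
    print(f"wrote {RESULTS / '06_searchlight.csv'} and cluster summary")


if __name__ == "__main__":
    main()
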