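"""Shape-and-color conjunction decoding against the optimal-additive model.

For each subject and pool, decodes the four conjunction targets, averages
them, and compares the curve with the optimal additive combination of the
same subject's single-feature (shape, color) classifiers. The cohort's
ground truth contains only single-feature codes, so on average the
conjunction curve should not exceed the additive ceiling. One caveat this
script illustrates: where BOTH single-feature codes saturate, a joint
linear readout of the two clean signals can top the
independent-combination ceiling without any integrated representation, so
conjunction > additive is only evidence of integration away from
saturation (see docs/methods.md).

Run from the repository root:  python analysis/05_conjunction_additive.py
"""

import json

import numpy as np
import pandas as pd

import graspmvpa as g
from cohortdef import RESULTS, SEED, cleaned_features


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    _, tensors = cleaned_features()

    rows, summary = [], {}
    for pool in ("grasping", "knuckling"):
        excess = []
        for subj, ft in enumerate(tensors):
            shape = g.decode_timeresolved(
                ft, g.make_cv_scheme(ft.labels, "shape", pool, seed=SEED))
            color = g.decode_timeresolved(
                ft, g.make_cv_scheme(ft.labels, "color", pool, seed=SEED))
            conj = g.conjunction_decode(ft, pool, seed=SEED)
            ceiling = g.additive_baseline(shape.accuracy, color.accuracy)
            excess.append(conj.accuracy - ceiling)
            for t, cj, ce in zip(conj.window_centers_ms, conj.accuracy,
                                 ceiling):
                rows.append({"subject": subj, "pool": pool, "time_ms": t,
                             "conjunction": cj, "additive_ceiling": ce,
                             "difference": cj - ce})
        excess = np.array(excess)
        summary[pool] = {
            "mean_difference": float(excess.mean()),
            "max_group_difference": float(excess.mean(0).max()),
            "windows_above_ceiling": int((excess.mean(0) > 0).sum()),
            "n_windows": int(excess.shape[1])}
        print(f"{pool:9s}: conjunction - additive mean "
              f"{summary[pool]['mean_difference']:+.3f}, group max "
              f"{summary[pool]['max_group_difference']:+.3f}")

    pd.DataFrame(rows).to_csv(RESULTS / "05_conjunction.csv", index=False)
    (RESULTS / "05_conjunction_summary.json").write_text(
        json.dumps(summary, indent=2))
    print(f"wrote {RESULTS / '05_conjunction.csv'} and summary")


if __name__ == "__main__":
    main()
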