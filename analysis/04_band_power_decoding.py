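"""Narrow-band power decoding of the grasp-specific color code.

Re-runs the color decoding on Hilbert band power instead of voltages, per
frequency band. The injected beta-carrier color effect should appear in
beta-band power in the grasping pool and nowhere else; delta serves as the
negative control.

Run from the repository root:  python analysis/04_band_power_decoding.py
"""

import json

import numpy as np

import graspmvpa as g
from graspmvpa.io import curves_to_frame
from cohortdef import RESULTS, SEED, cleaned_features


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    curves, summary = [], {}
    for band in ("beta", "theta", "delta"):
        _, tensors = cleaned_features(band)
        for pool in ("grasping", "knuckling"):
            per_subj = []
            for subj, ft in enumerate(tensors):
                scheme = g.make_cv_scheme(ft.labels, "color", pool, seed=SEED)
                c = g.decode_timeresolved(ft, scheme)
                c.subject, c.band = subj, band
                curves.append(c)
                per_subj.append(c.accuracy)
            acc = np.array(per_subj)
            t = curves[-1].window_centers_ms
            effect_win = (t >= 130) & (t <= 340)
            summary[f"{band}:{pool}"] = {
                "mean_accuracy_130_340ms": float(acc[:, effect_win].mean()),
                "peak_accuracy": float(acc.mean(0).max())}
            print(f"{band:5s} {pool:9s}: mean acc 130-340 ms "
                  f"{summary[f'{band}:{pool}']['mean_accuracy_130_340ms']:.3f}")

    curves_to_frame(curves).to_csv(RESULTS / "04_band_curves.csv", index=False)
    (RESULTS / "04_band_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {RESULTS / '04_band_curves.csv'} and 04_band_summary.json")


if __name__ == "__main__":
    main()
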