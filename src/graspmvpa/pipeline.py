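"""End-to-end orchestration: one config in, a reproducible result bundle out.

``run_pipeline`` executes simulate -> clean -> features -> decode ->
(optional) temporal generalization + ROI inference -> (optional) conjunction
-> group cluster statistics, writing CSV/JSON results and a manifest.
The master seed fans out to per-stage seeds by stable hashing so any stage
can be re-run independently; identical config + seed give identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import (build_design, simulate_epochs, clean_epochs,
               average_pseudotrials, noise_normalize, z_winsorize,
               window_features, band_power, make_cv_scheme,
               decode_timeresolved, decode_generalization,
               conjunction_decode, additive_baseline, cluster_test_time,
               roi_difference_test, default_rois, classify_dynamics,
               standard_montage, GroundTruthEffect, NoiseModel,
               make_topography)
from .containers import DecodingCurve, GeneralizationMatrix
from .decode import EFFECT_CLASSES, POOLS
from .io import curves_to_frame, gmats_to_frame
from .synthetic import DYNAMICS, FEATURES


@dataclass
class AnalysisConfig:
    """Fully serializable description of one synthetic analysis run."""

    # design
    n_subjects: int = 4
    blocks_per_action: int = 6
    reps_per_object: int = 18
    sampling_rate: float = 512.0
    epoch_window: tuple[float, float] = (-100.0, 1200.0)
    n_electrodes: int = 64
    # ground truth: list of effect dicts (feature, dynamic, windows,
    # topography_center, amplitude, carrier, action_specific)
    effects: list[dict] = field(default_factory=list)
    noise: dict = field(default_factory=dict)
    # pipeline toggles
    bands: list[str] = field(default_factory=list)   # [] = ERP path only
    decode_effects: list[tuple[str, str]] = field(
        default_factory=lambda: [("color", "grasping"), ("color", "knuckling")])
    run_generalization: bool = True
    run_conjunction: bool = False
    t_max: float = 500.0
    # inference
    n_perm: int = 10_000
    n_boot: int = 10_000
    alpha: float = 0.05
    # bookkeeping
    seed: int = 0
    out_dir: str = "results/pipeline"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.epoch_window = tuple(cfg.epoch_window)
        cfg.decode_effects = [tuple(e) for e in cfg.decode_effects]
        return cfg

    def validate(self) -> None:
        for eff in self.effects:
            if eff.get("feature") not in FEATURES:
                raise ValueError(f"unknown effect feature {eff.get('feature')!r}")
            if eff.get("dynamic") not in DYNAMICS:
                raise ValueError(f"unknown dynamic {eff.get('dynamic')!r}")
        for effect, pool in self.decode_effects:
            if effect != "conjunction" and effect not in EFFECT_CLASSES:
                raise ValueError(f"unknown decoding effect {effect!r}")
            if pool not in POOLS:
                raise ValueError(f"unknown pool {pool!r}")

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return zlib.crc32(f"{master}:{stage}".encode()) % (2 ** 31)


def _build_effects(cfg: AnalysisConfig, montage) -> list[GroundTruthEffect]:
    out = []
    for eff in cfg.effects:
        center = eff.get("topography_center")
        if center is None:
            # default to the most posterior electrode (occipital blob)
            center = int(np.argmin(montage.positions_mm[:, 1]))
        topo = make_topography(montage, center,
                               eff.get("topography_fwhm_mm", 60.0))
        out.append(GroundTruthEffect(
            feature=eff["feature"], dynamic=eff["dynamic"],
            windows=[tuple(w) for w in eff["windows"]],
            topography=topo, amplitude=eff.get("amplitude", 1.0),
            carrier=eff.get("carrier"),
            action_specific=eff.get("action_specific", False)))
    return out


def features_for_subject(epochs, band: str | None = None,
                         bins_per_window: int = 5):
    """Cleaned epochs -> windowed feature tensor (ERP or band-power path)."""
    src = band_power(epochs, band) if band else epochs
    pseudo = z_winsorize(noise_normalize(average_pseudotrials(src)))
    return window_features(pseudo, bins_per_window=bins_per_window)


def run_pipeline(cfg: AnalysisConfig) -> dict:
    """Execute all requested stages; returns the report bundle as a dict."""
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    montage = standard_montage(cfg.n_electrodes)
    design = build_design(cfg.n_subjects, seed=stage_seed(cfg.seed, "design"),
                          blocks_per_action=cfg.blocks_per_action,
                          reps_per_object=cfg.reps_per_object,
                          sampling_rate=cfg.sampling_rate,
                          epoch_window=cfg.epoch_window,
                          n_electrodes=cfg.n_electrodes)
    effects = _build_effects(cfg, montage)
    noise = NoiseModel(**cfg.noise)
    subjects = simulate_epochs(design, effects, noise,
                               seed=stage_seed(cfg.seed, "simulate"),
                               montage=montage)

    cleaning = []
    tensors: dict[str | None, list] = {}
    band_list: list[str | None] = [None] + list(cfg.bands)
    cleaned = []
    for ep in subjects:
        cl, rep = clean_epochs(ep, montage)
        cleaned.append(cl)
        cleaning.append({"subject": ep.subject,
                         "interpolated": rep.interpolated,
                         "fraction_removed": rep.fraction_removed})
    for band in band_list:
        tensors[band] = [features_for_subject(cl, band) for cl in cleaned]

    curves: list[DecodingCurve] = []
    gmats: list[GeneralizationMatrix] = []
    gmat_by: dict[tuple, list[GeneralizationMatrix]] = {}
    roi_reports = {}
    cv_seed = stage_seed(cfg.seed, "cv")
    for band in band_list:
        for effect, pool in cfg.decode_effects:
            for subj, ft in enumerate(tensors[band]):
                if effect == "conjunction":
                    c = conjunction_decode(ft, pool, seed=cv_seed)
                else:
                    scheme = make_cv_scheme(ft.labels, effect, pool, seed=cv_seed)
                    c = decode_timeresolved(ft, scheme)
                    if cfg.run_generalization:
                        gm = decode_generalization(ft, scheme, t_max=cfg.t_max)
                        gm.subject = subj
                        gmats.append(gm)
                        gmat_by.setdefault((band, effect, pool), []).append(gm)
                c.subject, c.band = subj, band
                curves.append(c)

    # group statistics per (band, effect, pool)
    cluster_reports = {}
    inf_seed = stage_seed(cfg.seed, "inference")
    for band in band_list:
        for effect, pool in cfg.decode_effects:
            key = f"{band or 'erp'}:{effect}:{pool}"
            sub = [c.accuracy for c in curves
                   if c.effect == effect and c.pool == pool and c.band == band]
            if len(sub) >= 2:
                res = cluster_test_time(np.array(sub), n_perm=cfg.n_perm,
                                        alpha=cfg.alpha, seed=inf_seed)
                cluster_reports[key] = {
                    "n_clusters": len(res.clusters),
                    "significant_windows": int(res.significant_mask.sum()),
                    "size_threshold": res.size_threshold}

    # ROI contrast grasping vs knuckling where both pools were decoded
    if cfg.run_generalization:
        for (band, effect), pools in _paired_pools(gmat_by).items():
            a = np.array([g.accuracy for g in pools["grasping"]])
            b = np.array([g.accuracy for g in pools["knuckling"]])
            if a.shape[0] < 2:
                continue
            res = roi_difference_test(
                a, b, pools["grasping"][0].window_centers_ms,
                n_boot=cfg.n_boot, seed=inf_seed)
            roi_reports[f"{band or 'erp'}:{effect}"] = {
                "differences": res.differences,
                "significant": res.significant,
                "dynamics": classify_dynamics(res)}

    # outputs
    curves_to_frame(curves).to_csv(out_dir / "curves.csv", index=False)
    if gmats:
        gmats_to_frame(gmats).to_csv(out_dir / "generalization.csv", index=False)
    bundle = {"config_digest": cfg.digest(), "seed": cfg.seed,
              "stage_seeds": {s: stage_seed(cfg.seed, s)
                              for s in ("design", "simulate", "cv", "inference")},
              "cleaning": cleaning, "clusters": cluster_reports,
              "rois": roi_reports}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=str)
    cfg.to_yaml(out_dir / "config.yaml")
    return bundle


def _paired_pools(by: dict) -> dict:
    """Group generalization matrices into grasping/knuckling pairs."""
    out = {}
    for (band, effect, pool), mats in by.items():
        out.setdefault((band, effect), {})[pool] = mats
    return {k: v for k, v in out.items()
            if "grasping" in v and "knuckling" in v}
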