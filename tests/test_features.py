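"""Pseudo-trials, whitening, winsorization, windowing, band power."""

import numpy as np
import pandas as pd
import pytest

import graspmvpa as g
from graspmvpa.containers import EpochSet, PseudoTrialSet
from graspmvpa.features import BANDS, _fir_bandpass


def _pseudo(traces, sfreq=128.0, state="raw"):
    n = traces.shape[0]
    lab = pd.DataFrame({"block": np.arange(n) // 4,
                        "action": "grasp_cw", "orientation": "cw",
                        "shape": ["pillow", "flower"] * (n // 2),
                        "color": ["red"] * (n // 2) + ["blue"] * (n - n // 2)})
    times = np.arange(traces.shape[2]) / sfreq * 1000.0
    return PseudoTrialSet(subject=0, traces=traces, times=times, labels=lab,
                          sfreq=sfreq, state=state)


class TestAveragePseudotrials:
    def test_six_traces_per_condition_under_default_design(
            self, default_pseudo_labels):
        lab = default_pseudo_labels
        cells = lab.groupby(["action", "orientation", "shape", "color"],
                            dropna=False).size()
        assert (cells == 6).all()             # one trace per contributing block
        grasp = lab[lab["action"].isin(("grasp_cw", "grasp_ccw"))]
        assert len(grasp) == 48               # 12 grasp blocks x 4 objects

    def test_identical_epochs_average_to_themselves(self, null_epochs):
        ep = null_epochs.copy()
        lab = ep.labels
        cell = (lab["block"] == 0) & (lab["shape"] == "pillow") & \
               (lab["color"] == "red")
        ep.data[cell.to_numpy()] = ep.data[np.flatnonzero(cell)[0]]
        ps = g.average_pseudotrials(ep)
        row = (ps.labels["block"] == 0) & (ps.labels["shape"] == "pillow") & \
              (ps.labels["color"] == "red")
        assert np.allclose(ps.traces[np.flatnonzero(row)[0]],
                           ep.data[np.flatnonzero(cell)[0]])

    def test_averaging_reduces_variance_by_trial_count(self):
        # closed form: variance of a mean of n iid epochs is var/n
        rng = np.random.default_rng(3)
        n_rep = 18
        lab = pd.DataFrame({
            "block": 0, "action": "knuckle", "orientation": None,
            "shape": ["pillow"] * n_rep + ["flower"] * n_rep,
            "color": "red", "valid": True, "reaction_time": 300.0})
        data = rng.standard_normal((2 * n_rep, 4, 2000))
        ep = EpochSet(subject=0, data=data, times=np.arange(2000.0),
                      labels=lab, sfreq=512.0)
        ps = g.average_pseudotrials(ep)
        ratio = ps.traces.var() / data.var()
        assert ratio == pytest.approx(1.0 / n_rep, rel=0.1)

    def test_empty_cell_warns_and_omits_trace(self, null_epochs):
        ep = null_epochs
        drop = ~((ep.labels["block"] == 0) & (ep.labels["shape"] == "pillow") &
                 (ep.labels["color"] == "red")).to_numpy()
        with pytest.warns(UserWarning, match="no surviving"):
            ps = g.average_pseudotrials(ep.select(drop))
        assert ps.n_traces == ep.labels["block"].nunique() * 4 - 1


class TestNoiseNormalize:
    def test_recovers_identity_covariance(self):
        # oracle: generate traces with known electrode covariance, whiten,
        # re-estimate -> correlations near zero off the diagonal
        rng = np.random.default_rng(5)
        p, n_per, T = 6, 40, 50
        A = rng.standard_normal((p, p))
        sigma = A @ A.T + p * np.eye(p)
        L = np.linalg.cholesky(sigma)
        traces = np.einsum("pq,tqs->tps", L,
                           rng.standard_normal((4 * n_per, p, T)))
        lab = pd.DataFrame({"block": np.arange(4 * n_per) % 4,
                            "action": "knuckle", "orientation": None,
                            "shape": np.repeat(["pillow", "flower"], 2 * n_per),
                            "color": ["red", "blue"] * (2 * n_per)})
        ps = PseudoTrialSet(subject=0, traces=traces,
                            times=np.arange(float(T)), labels=lab,
                            sfreq=128.0, state="raw")
        w = g.noise_normalize(ps, shrinkage=0.01)
        flat = w.traces.transpose(1, 0, 2).reshape(p, -1)
        corr = np.corrcoef(flat)
        off = corr[~np.eye(p, dtype=bool)]
        assert np.max(np.abs(off)) < 0.1

    def test_identity_input_only_rescaled(self):
        # already-white data: the fitted transform is a scalar multiple of
        # the identity (up to covariance estimation noise)
        rng = np.random.default_rng(6)
        traces = rng.standard_normal((400, 5, 50))
        ps = _pseudo(traces)
        w = g.noise_normalize(ps, shrinkage=0.0)
        W = np.linalg.lstsq(traces.transpose(0, 2, 1).reshape(-1, 5),
                            w.traces.transpose(0, 2, 1).reshape(-1, 5),
                            rcond=None)[0].T
        assert np.allclose(W / np.diag(W).mean(), np.eye(5), atol=0.05)

    def test_single_whitening_transform_for_all_conditions(self):
        # whitening is one linear map: applying it to the difference of two
        # traces equals the difference of the whitened traces
        rng = np.random.default_rng(7)
        traces = rng.standard_normal((16, 5, 30))
        ps = _pseudo(traces)
        w = g.noise_normalize(ps)
        # recover the (single) linear map from inputs to outputs and check
        # it reproduces every trace exactly
        W = np.linalg.lstsq(traces.transpose(0, 2, 1).reshape(-1, 5),
                            w.traces.transpose(0, 2, 1).reshape(-1, 5),
                            rcond=None)[0].T
        assert np.allclose(W @ traces[3], w.traces[3], atol=1e-8)

    def test_requires_replicated_conditions(self):
        traces = np.random.default_rng(8).standard_normal((4, 5, 30))
        ps = _pseudo(traces)
        ps.labels["block"] = np.arange(4)      # one trace per condition cell
        ps.labels["shape"] = ["pillow", "flower", "pillow", "flower"]
        ps.labels["color"] = ["red", "red", "blue", "blue"]
        ps.labels.loc[1:, "action"] = ["grasp_ccw", "knuckle", "knuckle"]
        ps.labels.loc[ps.labels["action"] == "knuckle", "orientation"] = None
        ps.labels.loc[ps.labels["action"] == "grasp_ccw", "orientation"] = "ccw"
        with pytest.raises(ValueError, match="covariance"):
            g.noise_normalize(ps)


class TestZWinsorize:
    def test_output_bounded_and_standardized(self):
        rng = np.random.default_rng(9)
        traces = 5 + 3 * rng.standard_normal((8, 4, 500))
        z = g.z_winsorize(_pseudo(traces, state="whitened"))
        assert np.abs(z.traces).max() <= 3.0
        assert np.allclose(z.traces.mean(axis=(1, 2)), 0.0, atol=0.02)
        assert np.allclose(z.traces.std(axis=(1, 2)), 1.0, atol=0.02)

    def test_standard_normal_trace_only_clipped(self):
        rng = np.random.default_rng(10)
        traces = rng.standard_normal((2, 4, 2000))
        mu = traces.mean(axis=(1, 2), keepdims=True)
        sd = traces.std(axis=(1, 2), keepdims=True)
        z = g.z_winsorize(_pseudo(traces, state="whitened"))
        expect = np.clip((traces - mu) / sd, -3, 3)
        assert np.allclose(z.traces, expect)

    def test_constant_trace_rejected(self):
        traces = np.zeros((2, 4, 10))
        with pytest.raises(ValueError, match="constant"):
            g.z_winsorize(_pseudo(traces, state="whitened"))

    def test_pipeline_order_enforced(self):
        traces = np.random.default_rng(11).standard_normal((8, 4, 20))
        with pytest.raises(ValueError, match="whitened"):
            g.z_winsorize(_pseudo(traces, state="raw"))
        with pytest.raises(ValueError, match="raw"):
            g.noise_normalize(_pseudo(traces, state="whitened"))


class TestWindowFeatures:
    def test_default_design_feature_geometry(self):
        # 64 electrodes x 5 bins = 320 features; 665 samples -> 133 windows
        traces = np.random.default_rng(12).standard_normal((4, 64, 665))
        ft = g.window_features(_pseudo(traces, sfreq=512.0,
                                       state="z_winsorized"))
        assert ft.X.shape == (133, 4, 320)
        # bin duration at 512 Hz is ~1.95 ms -> 5-bin windows of ~9.8 ms
        assert 1000.0 / 512.0 == pytest.approx(1.953, abs=0.001)

    def test_single_electrode_window(self):
        traces = np.random.default_rng(13).standard_normal((4, 1, 17))
        ft = g.window_features(_pseudo(traces, state="z_winsorized"),
                               bins_per_window=5)
        assert ft.X.shape == (3, 4, 5)        # partial final window dropped

    def test_window_content_matches_slices(self):
        traces = np.arange(2 * 3 * 10, dtype=float).reshape(2, 3, 10)
        ft = g.window_features(_pseudo(traces, state="z_winsorized"),
                               bins_per_window=5)
        assert np.array_equal(ft.X[1, 0], traces[0, :, 5:10].ravel())

    def test_oversized_window_rejected(self):
        traces = np.zeros((2, 3, 4))
        with pytest.raises(ValueError):
            g.window_features(_pseudo(traces, state="z_winsorized"),
                              bins_per_window=5)


class TestBandPower:
    def test_band_table(self):
        assert BANDS == {"delta": (1.0, 3.0), "theta": (3.0, 8.0),
                         "alpha": (8.0, 12.0), "beta": (15.0, 25.0),
                         "gamma": (30.0, 40.0)}

    def test_sinusoid_power_is_band_specific(self):
        sfreq, n = 512.0, 2048
        t = np.arange(n) / sfreq
        sig = np.sin(2 * np.pi * 20.0 * t)
        lab = pd.DataFrame({"block": [0], "action": ["knuckle"],
                            "orientation": [None], "shape": ["pillow"],
                            "color": ["red"], "valid": [True],
                            "reaction_time": [300.0]})
        ep = EpochSet(subject=0, data=np.tile(sig, (1, 3, 1)),
                      times=t * 1000.0, labels=lab, sfreq=sfreq)
        steady = slice(n // 4, 3 * n // 4)
        beta = g.band_power(ep, "beta").data[0, 0, steady].mean()
        theta = g.band_power(ep, "theta").data[0, 0, steady].mean()
        assert beta / theta > 100
        # squared analytic envelope of a unit sine is 1 (up to passband ripple)
        assert beta == pytest.approx(1.0, rel=0.15)

    def test_dc_has_no_band_power(self):
        lab = pd.DataFrame({"block": [0], "action": ["knuckle"],
                            "orientation": [None], "shape": ["pillow"],
                            "color": ["red"], "valid": [True],
                            "reaction_time": [300.0]})
        ep = EpochSet(subject=0, data=np.full((1, 2, 1024), 7.0),
                      times=np.arange(1024) / 512.0 * 1000, labels=lab,
                      sfreq=512.0)
        for band in BANDS:
            p = g.band_power(ep, band).data
            assert p.max() < 1e-3

    def test_band_above_nyquist_guarded(self):
        with pytest.raises(ValueError, match="invalid"):
            _fir_bandpass((30.0, 80.0), 128.0, 1000)

    def test_power_units_propagate(self, null_epochs):
        bp = g.band_power(null_epochs, "alpha")
        assert bp.units == "power"
        assert bp.band == "alpha"
        assert np.all(bp.data >= 0)
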