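"""File formats, round trips, configuration, and the pipeline surface."""
import numpy as np
import pandas as pd
import pytest

from photoperant import io, synthetic as syn
from photoperant.config import ConfigError, PipelineConfig
from photoperant.datatypes import EventStream, OrientationTrace, ValidationError
from photoperant.pipeline import run_pipeline
from photoperant.perievent import PeriEventTensor, bin_centers


class TestEventsIo:
    def test_round_trip(self, tmp_path):
        ev = syn.generate_behavior_session(
            syn.air_behavior_config(seed=1), session_id="s1", group_label="air")
        p = tmp_path / "events.csv"
        io.write_events(ev, p)
        back = io.read_events(p, session_id="s1", group_label="air")
        assert back == ev

    def test_unknown_kind_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_s,kind\n1.0,press\n2.0,lick\n")
        with pytest.raises(ValidationError, match="lick"):
            io.read_events(p)

    def test_empty_data_section(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("time_s,kind\n")
        ev = io.read_events(p)
        assert len(ev) == 0

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_s,kind\n1.0,press\nxyz,press\n")
        with pytest.raises(io.ParseError, match="line 3"):
            io.read_events(p)


class TestTraceIo:
    def test_round_trip_and_rate_inference(self, tmp_path):
        ev = EventStream(np.array([]), np.array([], dtype=object))
        s = syn.generate_photometry_trace(
            ev, syn.PhotometrySimConfig(duration_s=60.0, seed=2))
        p = tmp_path / "trace.csv"
        io.write_trace(s, p)
        back = io.read_trace(p)
        assert back.sampling_rate_hz == pytest.approx(20.0, rel=1e-9)
        np.testing.assert_allclose(back.fluorescence, s.fluorescence, rtol=1e-9)

    def test_jittered_timestamps_rejected(self, tmp_path):
        t = np.arange(100) / 20.0 + np.random.default_rng(0).uniform(0, 0.01, 100)
        p = tmp_path / "trace.csv"
        pd.DataFrame({"time_s": t, "fluorescence": np.ones(100)}).to_csv(p, index=False)
        with pytest.raises(ValidationError, match="non-uniform"):
            io.read_trace(p)

    def test_single_sample_rejected(self, tmp_path):
        p = tmp_path / "trace.csv"
        p.write_text("time_s,fluorescence\n0.0,1.0\n")
        with pytest.raises(ValidationError):
            io.read_trace(p)


class TestOrientationEpscIo:
    def test_orientation_round_trip(self, tmp_path):
        tr = syn.generate_orientation_trace(
            syn.OrientationSimConfig(n_cw=2, n_ccw=1, jitter_sd_rad=0.02, seed=3))
        p = tmp_path / "orientation.csv"
        io.write_orientation(tr, p)
        back = io.read_orientation(p)
        np.testing.assert_allclose(back.orientation_rad, tr.orientation_rad, rtol=1e-9)

    def test_epsc_round_trip(self, tmp_path):
        s = syn.generate_epsc_series(syn.EphysSimConfig(
            protocol="DSE", noise_sd_pA=3.0, seed=4))
        p = tmp_path / "epsc.csv"
        io.write_epsc(s, p)
        back = io.read_epsc(p, time_unit="s")
        np.testing.assert_allclose(back.amplitude_pA, s.amplitude_pA, rtol=1e-9)
        np.testing.assert_array_equal(back.trial_id, s.trial_id)

    def test_tensor_round_trip(self, tmp_path, rng):
        t = PeriEventTensor(
            z=rng.normal(size=(5, 200)), bin_centers_s=bin_centers(),
            session_ids=np.array(["a"] * 5, dtype=object),
            event_times_s=np.arange(5.0),
        )
        p = tmp_path / "tensor.csv"
        io.write_tensor(t, p)
        back = io.read_tensor(p)
        np.testing.assert_allclose(back.z, t.z, rtol=1e-9)
        np.testing.assert_allclose(back.bin_centers_s, t.bin_centers_s, atol=1e-4)


class TestPipelineConfig:
    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            PipelineConfig.from_dict({"no_such_knob": 1})

    def test_defaults_are_the_reference_values(self):
        cfg = PipelineConfig()
        assert cfg.baseline_window_s == 15.0
        assert cfg.baseline_percentile == 10.0
        assert cfg.n_permutations == 1000
        assert cfg.min_run == 4
        assert cfg.rotation_threshold_rad == 6.28

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump({"alpha": 0.01, "min_run": 5}))
        cfg = PipelineConfig.from_yaml(p)
        assert cfg.alpha == 0.01 and cfg.min_run == 5

    def test_invalid_values(self):
        with pytest.raises(ConfigError):
            PipelineConfig(alpha=1.5)
        with pytest.raises(ConfigError):
            PipelineConfig(rotation_mode="spiral")


def _write_study(tmp_path, n_per_group=2, seed0=0, duration=360.0):
    rows = []
    for g, make_beh, make_ph in (
        ("air", syn.air_behavior_config, syn.air_photometry_config),
        ("cie", syn.cie_behavior_config, syn.cie_photometry_config),
    ):
        for i in range(n_per_group):
            seed = seed0 + hash((g, i)) % 1000
            sid = f"{g}{i}"
            beh = make_beh(seed=seed, session_length_s=duration - 40.0, n_bouts=6,
                           between_bout_gap_mean_s=35.0, between_bout_gap_min_s=12.0)
            ev = syn.generate_behavior_session(beh, session_id=sid, group_label=g)
            tr = syn.generate_photometry_trace(ev, make_ph(seed=seed, duration_s=duration))
            io.write_events(ev, tmp_path / f"{sid}_events.csv")
            io.write_trace(tr, tmp_path / f"{sid}_trace.csv")
            rows.append({"session_id": sid, "group": g,
                         "trace_path": f"{sid}_trace.csv",
                         "events_path": f"{sid}_events.csv"})
    mpath = tmp_path / "manifest.csv"
    pd.DataFrame(rows).to_csv(mpath, index=False)
    return mpath


@pytest.fixture(scope="module")
def study(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("study")
    mpath = _write_study(tmp)
    cfg = PipelineConfig(n_permutations=200, seed=0)
    return run_pipeline(mpath, cfg), mpath, cfg


class TestRunPipeline:
    def test_structural_outputs(self, study):
        results, _, _ = study
        assert {"group_traces", "auc", "permutation", "epochs",
                "bouts", "qc", "exclusions"} <= set(results)
        assert set(results["qc"]["group"]) == {"air", "cie"}
        # one comparison table per event type with trials in both groups
        assert results["permutation"]["event_type"].nunique() >= 1
        assert (results["permutation"].groupby("event_type").size() == 80).all()

    def test_rerun_is_identical(self, study):
        results, mpath, cfg = study
        again = run_pipeline(mpath, cfg)
        for name in results:
            pd.testing.assert_frame_equal(results[name], again[name])

    def test_failed_qc_session_excluded_and_logged(self, tmp_path):
        # one flat (transient-free) trace: fails QC, lands in the exclusion log
        ev = EventStream(np.array([60.0]), np.array(["press"], dtype=object),
                         session_id="flat")
        tr = syn.generate_photometry_trace(
            ev, syn.PhotometrySimConfig(duration_s=120.0, noise_sd=0.0,
                                        event_response_amp={}))
        io.write_events(ev, tmp_path / "flat_events.csv")
        io.write_trace(tr, tmp_path / "flat_trace.csv")
        pd.DataFrame([{"session_id": "flat", "group": "air",
                       "trace_path": "flat_trace.csv",
                       "events_path": "flat_events.csv"}]).to_csv(
            tmp_path / "m.csv", index=False)
        results = run_pipeline(tmp_path / "m.csv", PipelineConfig(n_permutations=100))
        assert not results["qc"]["qc_passed"].iloc[0]
        assert len(results["exclusions"]) == 1
        assert results["exclusions"]["stage"].iloc[0] == "qc"
        assert results["auc"].empty
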