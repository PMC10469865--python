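import numpy as np
import pytest
import yaml

from eegasym.features import BANDS, BAND_EDGES, feature_name, relative_band_energy
from eegasym.montage import DEFAULT_MONTAGE, PAIRED_CHANNELS
from eegasym.synthetic import (
    AsymmetryEffect,
    GeneratorSpec,
    generate_band_limited_component,
    generate_dataset,
    seed_iv_spec,
    seed_v_spec,
    write_fixture,
)

from conftest import features_for


class TestBandLimitedComponent:
    def test_alpha_component_is_alpha_dominant(self):
        rng = np.random.default_rng(1)
        x = generate_band_limited_component("alpha", 1.0, 4.0, 200.0, rng)
        bet = relative_band_energy(x, ["A"])
        rel = {b: bet.energy("A", b) for b in BANDS}
        assert max(rel, key=rel.get) == "alpha"

    def test_spectral_power_inside_interval(self):
        rng = np.random.default_rng(2)
        for band in BANDS:
            x = generate_band_limited_component(band, 1.0, 8.0, 200.0, rng)
            spec = np.abs(np.fft.rfft(x)) ** 2
            freqs = np.fft.rfftfreq(len(x), 1 / 200.0)
            lo, hi = BAND_EDGES[band]
            inside = spec[(freqs >= lo) & (freqs < hi)].sum()
            assert inside / spec.sum() >= 0.90

    def test_exact_rms(self):
        rng = np.random.default_rng(3)
        x = generate_band_limited_component("beta", 2.5, 4.0, 200.0, rng)
        assert abs(np.sqrt(np.mean(x**2)) - 2.5) / 2.5 < 0.05

    def test_zero_rms_gives_zeros(self):
        rng = np.random.default_rng(4)
        x = generate_band_limited_component("alpha", 0.0, 4.0, 200.0, rng)
        assert np.all(x == 0)

    def test_seed_contract(self):
        x1 = generate_band_limited_component(
            "delta", 1.0, 4.0, 200.0, np.random.default_rng(1))
        x2 = generate_band_limited_component(
            "delta", 1.0, 4.0, 200.0, np.random.default_rng(2))
        assert not np.allclose(x1, x2)
        assert np.isclose(np.sqrt(np.mean(x1**2)), np.sqrt(np.mean(x2**2)),
                          rtol=1e-9)

    def test_unknown_band_named_in_error(self):
        with pytest.raises(ValueError, match="sigma"):
            generate_band_limited_component(
                "sigma", 1.0, 4.0, 200.0, np.random.default_rng(0))


class TestGeneratorSpec:
    def test_seed_iv_analogue_72_recordings_per_subject(self):
        spec = seed_iv_spec(n_subjects=1, trial_duration=8.0)
        recs = generate_dataset(spec)
        assert len(recs) == 72  # 3 sessions x 24 clips

    def test_seed_v_analogue_count(self):
        spec = seed_v_spec(n_subjects=1, trial_duration=8.0)
        recs = generate_dataset(spec)
        assert len(recs) == 36  # 3 sessions x 12 clips (4 emotions x 3)

    def test_session_emotion_balance(self):
        spec = GeneratorSpec(
            n_subjects=1, n_sessions=2, trials_per_session_per_emotion=3,
            trial_duration=8.0, seed=1,
        )
        recs = generate_dataset(spec)
        for sess in (1, 2):
            emotions = [r.emotion for r in recs if r.session_id == sess]
            assert all(emotions.count(e) == 3 for e in spec.emotions)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(n_subjects=0)

    def test_non_integer_sample_count_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            GeneratorSpec(trial_duration=4.0005, fs=200.0)

    def test_missing_lateral_label_rejected(self):
        montage = tuple(ch for ch in DEFAULT_MONTAGE if ch != "FT7")
        with pytest.raises(ValueError, match="FT7"):
            GeneratorSpec(montage=montage)

    def test_negative_band_weight_rejected(self):
        profiles = {"delta": 2.0, "theta": 1.5, "alpha": -1.0,
                    "beta": 1.2, "gamma": 1.0}
        with pytest.raises(ValueError, match="positive"):
            GeneratorSpec(band_profiles=profiles)

    def test_yaml_roundtrip(self):
        spec = GeneratorSpec(
            n_subjects=2, trial_duration=8.0, seed=9,
            asymmetry_effects=[AsymmetryEffect("sad", "alpha", 0.5, pairs=[7])],
        )
        text = yaml.safe_dump(spec.to_dict())
        back = GeneratorSpec.from_dict(yaml.safe_load(text))
        assert back == spec


class TestDeterminism:
    def test_same_spec_same_seed_bitwise_equal(self):
        spec = GeneratorSpec(
            n_subjects=1, n_sessions=1, trials_per_session_per_emotion=1,
            trial_duration=8.0, seed=77,
            asymmetry_effects=[AsymmetryEffect("happy", "gamma", 0.4)],
        )
        r1 = generate_dataset(spec)
        r2 = generate_dataset(spec)
        assert len(r1) == len(r2)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.data, b.data)
            assert a.emotion == b.emotion

    def test_different_seed_differs(self):
        kw = dict(n_subjects=1, n_sessions=1, trials_per_session_per_emotion=1,
                  trial_duration=8.0)
        r1 = generate_dataset(GeneratorSpec(seed=1, **kw))
        r2 = generate_dataset(GeneratorSpec(seed=2, **kw))
        assert not np.allclose(r1[0].data, r2[0].data)


class TestEffectCalibration:
    def test_planted_effect_recovered_in_mean_delta(self, calibration_features):
        sad = calibration_features[calibration_features.emotion == "sad"]
        assert len(sad) >= 500
        alpha_cols = [feature_name(l, r, "alpha") for l, r in PAIRED_CHANNELS]
        mean_delta = sad[alpha_cols].to_numpy().mean()
        assert abs(mean_delta - 0.6) < 0.1

    def test_untargeted_cells_near_zero(self, calibration_features):
        for emotion in ("neutral", "happy", "fear"):
            rows = calibration_features[calibration_features.emotion == emotion]
            cols = [feature_name(l, r, b)
                    for l, r in PAIRED_CHANNELS for b in BANDS]
            assert abs(rows[cols].to_numpy().mean()) < 0.05
        sad = calibration_features[calibration_features.emotion == "sad"]
        for band in ("delta", "theta", "beta", "gamma"):
            cols = [feature_name(l, r, band) for l, r in PAIRED_CHANNELS]
            assert abs(sad[cols].to_numpy().mean()) < 0.05

    def test_null_spec_mean_delta_near_zero(self, null_features):
        cols = [feature_name(l, r, b) for l, r in PAIRED_CHANNELS for b in BANDS]
        assert abs(null_features[cols].to_numpy().mean()) < 0.02

    def test_pair_subset_targets_only_those_pairs(self):
        spec = GeneratorSpec(
            n_subjects=2, n_sessions=1, trials_per_session_per_emotion=1,
            trial_duration=120.0, seed=11,
            asymmetry_effects=[AsymmetryEffect("fear", "beta", 0.7, pairs=[8])],
        )
        df = features_for(spec)
        fear = df[df.emotion == "fear"]
        target = fear[feature_name("T7", "T8", "beta")].mean()
        others = [feature_name(l, r, "beta")
                  for (l, r) in PAIRED_CHANNELS if (l, r) != ("T7", "T8")]
        assert abs(target - 0.7) < 0.12
        assert abs(fear[others].to_numpy().mean()) < 0.05


class TestWriteFixture:
    def test_roundtrip_bitwise(self, tmp_path):
        from eegasym.io import read_recordings

        spec = GeneratorSpec(
            n_subjects=1, n_sessions=1, trials_per_session_per_emotion=1,
            trial_duration=8.0, seed=3,
        )
        recs = generate_dataset(spec)
        write_fixture(recs, tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        back = read_recordings(tmp_path / "manifest.csv")
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert np.array_equal(a.data, b.data)
            assert a.channels == b.channels
            assert (a.subject_id, a.session_id, a.trial_id, a.emotion) == (
                b.subject_id, b.session_id, b.trial_id, b.emotion)

    def test_one_file_per_recording(self, tmp_path):
        spec = GeneratorSpec(
            n_subjects=1, n_sessions=1, trials_per_session_per_emotion=1,
            trial_duration=8.0, seed=3,
        )
        recs = generate_dataset(spec)[:1]
        write_fixture(recs, tmp_path)
        assert len(list(tmp_path.glob("*.npz"))) == 1

    def test_empty_collection_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_fixture([], tmp_path)
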