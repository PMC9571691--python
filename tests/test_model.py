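"""Split autoencoder: construction, training, split equivalence, persistence."""

import numpy as np
import pytest

from splitbeat import dataset as dio, model as mdl, persistence


class TestBuildModel:
    def test_default_compression_ratio_is_28(self):
        model = mdl.build_model()
        assert model.input_width / model.latent_width == 28
        assert model.input_width == 140 and model.latent_width == 5

    def test_latent_not_smaller_than_input_rejected(self):
        with pytest.raises(mdl.ModelError):
            mdl.build_model(input_width=10, latent_width=10)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(mdl.ModelError):
            mdl.build_model(hidden_widths=(32, 0))

    def test_same_seed_identical_parameters(self):
        a = mdl.build_model(init_seed=5)
        b = mdl.build_model(init_seed=5)
        for pa, pb in zip(a.parameter_arrays(), b.parameter_arrays()):
            np.testing.assert_array_equal(pa, pb)
        c = mdl.build_model(init_seed=6)
        assert any(
            not np.array_equal(pa, pc)
            for pa, pc in zip(a.parameter_arrays(), c.parameter_arrays())
        )

    def test_layer_shapes_mirror(self):
        model = mdl.build_model(input_width=20, latent_width=3, hidden_widths=(8,))
        enc_shapes = [l.W.shape for l in model.encoder_params]
        dec_shapes = [l.W.shape for l in model.decoder_params]
        assert enc_shapes == [(20, 8), (8, 3)]
        assert dec_shapes == [(3, 8), (8, 20)]


class TestTraining:
    def test_constant_beats_drive_loss_below_1e4(self, constant_beat_dataset):
        model = mdl.build_model(init_seed=0)
        model, history = mdl.train(
            model, constant_beat_dataset, None, epochs=200, seed=0
        )
        assert history.train_loss[-1] < 1e-4
        # Decoding the mean training latent reproduces the constant beat.
        latents = mdl.encode(model, constant_beat_dataset.to_array())
        recon = mdl.decode(model, latents.mean(axis=0))
        assert float(np.mean((recon - 0.5) ** 2)) < 1e-3

    def test_history_bookkeeping(self, constant_beat_dataset):
        model = mdl.build_model(init_seed=1)
        model, history = mdl.train(model, constant_beat_dataset, None, epochs=30, seed=1)
        assert len(history) == 30
        running_min = np.minimum.accumulate(history.train_loss)
        assert all(np.diff(running_min) <= 0)
        assert history.train_loss[-1] <= history.train_loss[0]

    def test_training_is_deterministic(self, constant_beat_dataset):
        runs = []
        for _ in range(2):
            model = mdl.build_model(init_seed=2)
            model, history = mdl.train(model, constant_beat_dataset, None, epochs=15, seed=9)
            runs.append(history.train_loss[-1])
        assert runs[0] == runs[1]

    def test_unnormalized_dataset_refused(self):
        raw = dio.BeatDataset(
            records=[dio.BeatRecord(label=1, samples=np.linspace(0, 1, 140))] * 4,
            length=140,
        )
        model = mdl.build_model()
        with pytest.raises(mdl.ModelError, match="not normalized"):
            mdl.train(model, raw, None, epochs=1)

    def test_mismatched_normalization_refused(self, constant_beat_dataset):
        other = dio.apply_normalization(
            dio.BeatDataset(
                records=[dio.BeatRecord(label=1, samples=np.full(140, 0.5))],
                length=140,
            ),
            -1.0,
            2.0,
        )
        model = mdl.build_model()
        with pytest.raises(mdl.ModelError, match="different parameters"):
            mdl.train(model, constant_beat_dataset, other, epochs=1)

    def test_early_stopping_restores_best_and_truncates(self, constant_beat_dataset):
        model = mdl.build_model(init_seed=4)
        model, history = mdl.train(
            model, constant_beat_dataset, constant_beat_dataset,
            epochs=500, seed=4, patience=5,
        )
        assert len(history) <= 500
        assert len(history.val_loss) == len(history.train_loss)


class TestEncodeDecode:
    def test_shapes_and_purity(self, small_trained):
        detector, test_ds, _ = small_trained
        beat = test_ds.records[0].samples
        code = mdl.encode(detector.model, beat)
        assert code.shape == (5,)
        np.testing.assert_array_equal(code, mdl.encode(detector.model, beat))
        recon = mdl.decode(detector.model, code)
        assert recon.shape == (140,)

    def test_wrong_lengths_rejected(self, small_trained):
        detector, _, _ = small_trained
        with pytest.raises(mdl.ModelError, match="139"):
            mdl.encode(detector.model, np.zeros(139))
        with pytest.raises(mdl.ModelError, match="4 values"):
            mdl.decode(detector.model, np.zeros(4))

    def test_untrained_model_refused(self):
        model = mdl.build_model()
        with pytest.raises(mdl.ModelError, match="untrained"):
            mdl.encode(model, np.zeros(140))

    def test_split_equivalence_is_exact(self, small_trained):
        """decode(encode(x)) and the monolithic forward share one arithmetic
        path, so they agree bitwise on 100 seeded random inputs."""
        detector, _, _ = small_trained
        rng = np.random.default_rng(123)
        x = rng.uniform(0, 1, size=(100, 140))
        split = mdl.decode(detector.model, mdl.encode(detector.model, x))
        mono = mdl.forward(detector.model, x)
        np.testing.assert_array_equal(split, mono)


class TestPersistence:
    def test_model_round_trip(self, small_trained, tmp_path):
        detector, test_ds, _ = small_trained
        path = persistence.save_model(detector.model, tmp_path / "m.json")
        back = persistence.load_model(path)
        for pa, pb in zip(detector.model.parameter_arrays(), back.parameter_arrays()):
            np.testing.assert_array_equal(pa, pb)
        assert mdl.decoder_fingerprint(back) == mdl.decoder_fingerprint(detector.model)
        x = test_ds.to_array()[:3]
        np.testing.assert_array_equal(mdl.forward(back, x), mdl.forward(detector.model, x))

    def test_halves_independently_loadable(self, small_trained, tmp_path):
        detector, test_ds, _ = small_trained
        model = detector.model
        enc = persistence.load_encoder(persistence.export_encoder(model, tmp_path / "e.json"))
        dec = persistence.load_decoder(persistence.export_decoder(model, tmp_path / "d.json"))
        beat = test_ds.records[0].samples
        code = enc(beat)
        np.testing.assert_array_equal(code, mdl.encode(model, beat))
        np.testing.assert_array_equal(dec(code), mdl.decode(model, code))
        assert dec.fingerprint == mdl.decoder_fingerprint(model)

    def test_detector_round_trip(self, small_trained, tmp_path):
        detector, _, norm = small_trained
        path = persistence.save_detector(detector, tmp_path / "det.json")
        back = persistence.load_detector(path)
        assert back.threshold == detector.threshold
        assert back.rule == detector.rule
        assert back.normalization == norm
        # Threshold recomputable from the stored rule and error summary.
        assert back.threshold == pytest.approx(
            back.train_error_mean + back.rule.k * back.train_error_std
        )

    def test_wrong_format_rejected(self, small_trained, tmp_path):
        detector, _, _ = small_trained
        path = persistence.save_model(detector.model, tmp_path / "m.json")
        with pytest.raises(mdl.ModelError, match="not a decoder archive"):
            persistence.load_decoder(path)
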