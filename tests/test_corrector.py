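"""Corrector network: targets, training, weight transfer, persistence."""

import numpy as np
import pytest

from fnirs_macorr import (
    build_target,
    decompose,
    load_model,
    save_model,
    train_corrector,
    transfer_correct,
)
from fnirs_macorr.corrector import TrainingTarget


def pearson(a, b):
    return float(np.corrcoef(a, b)[0, 1])


class TestBuildTarget:
    def test_ch4_around_r2_is_mean_of_ch3_ch8(self, jump_recording, layout5):
        rec = jump_recording
        tgt = build_target(rec.observed, layout5, 4, "R2")
        assert tgt.source_channels == (3, 8)
        expected = (rec.observed[rec.channel_index(3)] + rec.observed[rec.channel_index(8)]) / 2
        assert np.allclose(tgt.target, expected)

    def test_single_neighbor_verbatim(self, jump_recording, layout5):
        rec = jump_recording
        tgt = build_target(rec.observed, layout5, 4, "T3")  # only CH9 left
        assert tgt.source_channels == (9,)
        assert np.array_equal(tgt.target, rec.observed[rec.channel_index(9)])

    def test_constant_neighbors_average(self, layout5):
        rec = np.zeros((40, 100))
        rec[layout5.channel_ids.index(3)] = 1.0
        rec[layout5.channel_ids.index(8)] = 3.0
        tgt = build_target(rec, layout5, 4, "R2")
        assert np.allclose(tgt.target, 2.0)


class TestTraining:
    def test_recovers_linear_subband_combination(self, rng):
        """A target that is a fixed linear mix of the 11 components is
        recoverable: the closed-form least-squares optimum is ~0, and the
        network must come within 1e-3 of the target variance."""
        d = decompose(rng.normal(size=1024))
        w = np.linspace(1.0, -1.0, 11)
        tgt = d.stack().T @ w
        X = np.column_stack([d.stack().T, np.ones(tgt.size)])
        resid = tgt - X @ np.linalg.lstsq(X, tgt, rcond=None)[0]
        assert np.mean(resid ** 2) < 1e-12 * np.var(tgt)  # oracle: exactly realizable
        model, out = train_corrector(d, TrainingTarget(0, tgt, ()), epochs=1000, seed=0)
        assert model.train_log[-1] < 1e-3 * np.var(tgt)

    def test_identity_target_driven_to_near_zero_loss(self, rng):
        x = rng.normal(size=1024)
        d = decompose(x)
        model, out = train_corrector(d, TrainingTarget(0, x.copy(), ()), epochs=1000, seed=1)
        assert model.train_log[-1] < 1e-3 * np.var(x)

    def test_loss_decreases(self, rng):
        d = decompose(rng.normal(size=1024))
        model, _ = train_corrector(d, TrainingTarget(0, rng.normal(size=1024), ()),
                                   epochs=200, seed=0)
        assert model.train_log[-1] < model.train_log[0]

    def test_architecture_contract(self, rng):
        d = decompose(rng.normal(size=1024))
        model, _ = train_corrector(d, TrainingTarget(0, rng.normal(size=1024), ()),
                                   epochs=5, seed=0)
        assert model.input_dim == 11
        assert len(model.hidden_layers) == 6
        assert sum(model.hidden_layers) > 400
        assert model.weights[-1].shape[1] == 1

    def test_deterministic_for_fixed_seed(self, rng):
        d = decompose(rng.normal(size=1024))
        tgt = TrainingTarget(0, rng.normal(size=1024), ())
        m1, c1 = train_corrector(d, tgt, epochs=50, seed=9)
        m2, c2 = train_corrector(d, tgt, epochs=50, seed=9)
        assert np.array_equal(c1, c2)
        assert all(np.array_equal(a, b) for a, b in zip(m1.weights, m2.weights))

    def test_length_mismatch_rejected(self, rng):
        d = decompose(rng.normal(size=1024))
        with pytest.raises(ValueError, match="length"):
            train_corrector(d, TrainingTarget(0, np.zeros(100), ()), epochs=1)

    def test_corrects_jump_channel_toward_clean_truth(self, jump_recording, layout5):
        rec = jump_recording
        i4 = rec.channel_index(4)
        model, corrected = train_corrector(
            decompose(rec.observed[i4]), build_target(rec.observed, layout5, 4, "R2"),
            epochs=800, seed=rec.seed,
        )
        assert pearson(corrected, rec.clean[i4]) > pearson(rec.observed[i4], rec.clean[i4])


class TestTransfer:
    def test_zero_iters_is_pure_forward_pass(self, jump_recording, layout5):
        rec = jump_recording
        i4 = rec.channel_index(4)
        d4 = decompose(rec.observed[i4])
        tgt = build_target(rec.observed, layout5, 4, "R2")
        model, corrected = train_corrector(d4, tgt, epochs=100, seed=0)
        _, replay = transfer_correct(model, d4, tgt, iters=0)
        assert np.array_equal(replay, corrected)

    def test_transfer_improves_sibling(self, jump_recording, layout5):
        rec = jump_recording
        i4, i9 = rec.channel_index(4), rec.channel_index(9)
        model, _ = train_corrector(
            decompose(rec.observed[i4]), build_target(rec.observed, layout5, 4, "R2"),
            epochs=800, seed=rec.seed,
        )
        _, corr9 = transfer_correct(
            model, decompose(rec.observed[i9]),
            build_target(rec.observed, layout5, 9, "R5"), iters=100,
        )
        assert pearson(corr9, rec.clean[i9]) > pearson(rec.observed[i9], rec.clean[i9])

    def test_dimension_mismatch_rejected(self, rng):
        d = decompose(rng.normal(size=1024))
        model, _ = train_corrector(d, TrainingTarget(0, rng.normal(size=1024), ()),
                                   epochs=2, seed=0)
        d8 = decompose(rng.normal(size=1024), levels=8)
        with pytest.raises(ValueError, match="dimension"):
            transfer_correct(model, d8, TrainingTarget(0, rng.normal(size=1024), ()))


class TestPersistence:
    def test_save_load_round_trip_bit_exact(self, rng, tmp_path):
        d = decompose(rng.normal(size=1024))
        model, corrected = train_corrector(
            d, TrainingTarget(0, rng.normal(size=1024), ()), epochs=30, seed=4
        )
        p = tmp_path / "model.json"
        save_model(model, p)
        back = load_model(p)
        assert all(np.array_equal(a, b) for a, b in zip(model.weights, back.weights))
        assert all(np.array_equal(a, b) for a, b in zip(model.biases, back.biases))
        assert np.array_equal(back.forward(d.stack().T), corrected)

    def test_rejects_foreign_file(self, tmp_path):
        p = tmp_path / "x.json"
        p.write_text("{}")
        with pytest.raises(ValueError, match="not a corrector model"):
            load_model(p)
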