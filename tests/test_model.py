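"""CNN regressor: encoding, architecture arithmetic, training contracts,
target scaling, persistence, and the fine-tuning epoch search."""

import numpy as np
import pytest

from ribload import simdata
from ribload.model import (
    ModelSpec,
    TrainedModel,
    build_model,
    count_params,
    decode_one_hot,
    encode_sequences,
    evaluate_r2,
    fine_tune,
    one_hot,
    train,
)

from conftest import random_seqs


# -- one-hot encoding ----------------------------------------------------

def test_one_hot_acgt_is_identity():
    np.testing.assert_array_equal(one_hot("ACGT"), np.eye(4, dtype=np.float32))


def test_one_hot_rows_sum_to_one(rng):
    for seq in random_seqs(rng, 50):
        assert (one_hot(seq).sum(axis=1) == 1).all()


def test_one_hot_round_trip(rng):
    for seq in random_seqs(rng, 1_000):
        assert decode_one_hot(one_hot(seq)) == seq


def test_one_hot_rejects_ambiguity_codes():
    with pytest.raises(ValueError):
        one_hot("ACGN")


# -- architecture --------------------------------------------------------

def test_parameter_count_matches_closed_form():
    spec = ModelSpec()
    net = build_model(spec, seed=0)
    closed = 4 * 8 * 120 + 120 + 2 * (120 * 8 * 120 + 120) + (50 * 120) * 40 + 40 + 40 + 1
    assert net.n_params() == closed == count_params(spec)


def test_seeded_init_is_reproducible():
    a = build_model(ModelSpec(), seed=3)
    b = build_model(ModelSpec(), seed=3)
    for pa, pb in zip(a.params, b.params):
        np.testing.assert_array_equal(pa, pb)
    c = build_model(ModelSpec(), seed=4)
    assert any((pa != pc).any() for pa, pc in zip(a.params, c.params))


def test_output_shape(rng):
    net = build_model(ModelSpec(), seed=0)
    x = encode_sequences(random_seqs(rng, 7))
    out, _ = net.forward(x)
    assert out.shape == (7,)


# -- training ------------------------------------------------------------

def test_constant_targets_raise(small_simulated_library):
    lib = small_simulated_library.subset(np.arange(len(small_simulated_library)) < 100)
    frame = lib.frame.copy()
    frame["mrl"] = 5.0
    const = simdata.ReporterLibrary(frame, lib.kind)
    with pytest.raises(ValueError, match="zero variance"):
        train(build_model(ModelSpec(), seed=0), const, epochs=1, seed=0)


def test_history_length_and_determinism(small_simulated_library):
    spec = ModelSpec()
    runs = []
    for _ in range(2):
        trained = train(build_model(spec, seed=5), small_simulated_library,
                        epochs=2, seed=5, spec=spec)
        runs.append(trained)
    assert len(runs[0].history) == 2
    assert runs[0].history == runs[1].history
    assert "val_loss" in runs[0].history[0]


def test_learns_gc_only_linear_target():
    """A noiseless GC-count target is essentially linear: the CNN should
    explain nearly all of it after a short fit."""
    lib = simdata.generate_random_library(4_000, seed=21)
    frame = lib.frame.copy()
    frame["mrl"] = [5.0 - 2.0 * (s.count("G") + s.count("C")) / 50 for s in frame["sequence"]]
    lib = simdata.ReporterLibrary(frame, "random")
    lib = simdata.assign_random_split(lib, 800, seed=21)
    spec = ModelSpec()
    trained = train(build_model(spec, seed=21), lib, epochs=3, seed=21, spec=spec)
    assert evaluate_r2(trained, lib, split="test").r_squared >= 0.9


# -- prediction & scaling ------------------------------------------------

def test_inverse_transform(small_trained_model):
    mean, sd = small_trained_model.scaler
    x = np.zeros((1, 50, 4), dtype=np.float32)
    raw = small_trained_model.predict_scaled(x)[0]
    back = small_trained_model.predict_mrl(x)[0]
    assert back == pytest.approx(raw * sd + mean, rel=1e-6)


def test_scaling_round_trip(rng):
    y = rng.normal(3.0, 1.7, size=500)
    mean, sd = y.mean(), y.std()
    np.testing.assert_allclose((y - mean) / sd * sd + mean, y, atol=1e-10)


def test_prediction_batch_invariance(small_trained_model, rng):
    seqs = random_seqs(rng, 37)
    all_at_once = small_trained_model.predict_mrl(seqs)
    one_by_one = np.concatenate([small_trained_model.predict_mrl([s]) for s in seqs])
    assert np.max(np.abs(all_at_once - one_by_one)) <= 1e-5


# -- evaluation ----------------------------------------------------------

class _IdentityModel:
    """Predicts a fixed vector; lets r² be tested without a network."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)

    def predict_mrl(self, sequences):
        return self.values[: len(sequences)]


def _library_with_mrl(values):
    frame = {"sequence": ["A" * 50] * len(values), "mrl": values}
    import pandas as pd

    return simdata.ReporterLibrary(pd.DataFrame(frame))


def test_r2_perfect_and_mean_predictions():
    y = [1.0, 2.0, 3.0, 4.0, 5.0]
    lib = _library_with_mrl(y)
    assert evaluate_r2(_IdentityModel(y), lib).r_squared == pytest.approx(1.0)
    assert evaluate_r2(_IdentityModel([3.0] * 5), lib).r_squared == pytest.approx(0.0)


def test_r2_closed_form_toy_set():
    y = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
    pred = np.array([3.0, 3.0, 7.0, 7.0, 9.0])
    lib = _library_with_mrl(y)
    expected = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
    assert evaluate_r2(_IdentityModel(pred), lib).r_squared == pytest.approx(expected)


def test_r2_guards():
    with pytest.raises(ValueError):
        evaluate_r2(_IdentityModel([1.0]), _library_with_mrl([1.0]))
    with pytest.raises(ValueError):
        evaluate_r2(_IdentityModel([1.0, 2.0]), _library_with_mrl([3.0, 3.0]))


# -- persistence ---------------------------------------------------------

def test_save_load_bit_identical_predictions(small_trained_model, rng, tmp_path):
    path = tmp_path / "model.npz"
    small_trained_model.save(path)
    loaded = TrainedModel.load(path)
    seqs = random_seqs(rng, 64)
    np.testing.assert_array_equal(
        small_trained_model.predict_mrl(seqs), loaded.predict_mrl(seqs)
    )
    assert loaded.scaler == pytest.approx(small_trained_model.scaler)


# -- fine-tuning ---------------------------------------------------------

@pytest.fixture(scope="module")
def humanlike_library(default_params):
    lib = simdata.generate_humanlike_library(1_500, seed=31)
    lib = simdata.simulate_library(lib, simdata.with_params(default_params, seed=31))
    return simdata.assign_random_split(lib, 300, seed=31)


def test_fine_tune_grid_of_one_equals_continued_training(
    small_trained_model, humanlike_library
):
    from ribload.workflows import pretrained_copy

    tuned_a = fine_tune(pretrained_copy(small_trained_model), humanlike_library,
                        epoch_grid=[1], seed=13)
    tuned_b = fine_tune(pretrained_copy(small_trained_model), humanlike_library,
                        epoch_grid=[1], seed=13)
    seqs = list(humanlike_library.subset_split("test").sequences)
    np.testing.assert_array_equal(tuned_a.predict_mrl(seqs), tuned_b.predict_mrl(seqs))
    assert tuned_a.history[-1]["selected_epochs"] == 1


def test_fine_tune_selects_argmax_on_selection_split(
    small_trained_model, humanlike_library
):
    from ribload.workflows import pretrained_copy

    tuned = fine_tune(pretrained_copy(small_trained_model), humanlike_library,
                      epoch_grid=[1, 2, 3], seed=13)
    scores = tuned.history[-1]["epoch_search"]
    best = tuned.history[-1]["selected_epochs"]
    assert scores[best] == max(scores.values())
    # ties (exact float equality) must resolve to the smallest epoch count
    assert all(scores[best] > v for e, v in scores.items() if e < best)


def test_fine_tune_empty_grid_raises(small_trained_model, humanlike_library):
    with pytest.raises(ValueError):
        fine_tune(small_trained_model, humanlike_library, epoch_grid=[], seed=0)
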