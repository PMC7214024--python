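"""Encoding, the network contract, aggregation and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fusionprior import (
    EncoderConfig,
    ModelConfig,
    PredictionModel,
    ThresholdPolicy,
    aggregate,
    build_model,
    decode,
    encode,
    rank_and_filter,
    score_candidates,
)
from fusionprior.errors import ModelError
from fusionprior.fusions import CandidateProtein, FusionCandidateSet, FusionInput, Breakpoint
from fusionprior.io_tabular import FusionResult
from fusionprior.model import AMINO_ACIDS, encode_batch

SMALL_ENC = EncoderConfig(max_len=40)
SMALL_CFG = ModelConfig(
    embedding_dim=8, conv_filters=12, conv_kernel=5, pool_size=4, lstm_units=10, epochs=2, seed=0
)

aa_text = st.text(alphabet=AMINO_ACIDS + "X", min_size=1, max_size=40)


class TestEncoder:
    def test_padding(self):
        cfg = EncoderConfig(max_len=5)
        v = encode("M", cfg)
        assert v[0] == cfg.alphabet.index("M") + 1
        assert list(v[1:]) == [0, 0, 0, 0]

    def test_truncation_beyond_max_len(self):
        cfg = EncoderConfig(max_len=5)
        v = encode("A" * 15, cfg)
        assert len(v) == 5 and all(x == 1 for x in v)

    def test_unknown_residue_maps_to_x(self):
        cfg = EncoderConfig(max_len=4)
        assert encode("MBZJ", cfg)[1] == cfg.alphabet.index("X") + 1

    def test_empty_sequence_is_error(self):
        with pytest.raises(ModelError):
            encode("", SMALL_ENC)

    @settings(derandomize=True, max_examples=100)
    @given(aa_text)
    def test_decode_inverts_encode(self, seq):
        assert decode(encode(seq, SMALL_ENC), SMALL_ENC) == seq


class TestNetworkContract:
    def test_output_in_unit_interval_and_varied(self):
        model = build_model(SMALL_CFG, SMALL_ENC)
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), size=20)) for _ in range(50)]
        scores = model.score_batch(seqs)
        assert np.all(scores >= 0.0) and np.all(scores <= 1.0)
        assert len(np.unique(np.round(scores, 10))) > 1

    def test_same_seed_identical_weights(self):
        a = build_model(SMALL_CFG, SMALL_ENC, seed=11)
        b = build_model(SMALL_CFG, SMALL_ENC, seed=11)
        for k in a.net.params:
            np.testing.assert_array_equal(a.net.params[k], b.net.params[k])

    def test_different_seed_different_weights(self):
        a = build_model(SMALL_CFG, SMALL_ENC, seed=11)
        b = build_model(SMALL_CFG, SMALL_ENC, seed=12)
        assert any(not np.array_equal(a.net.params[k], b.net.params[k]) for k in a.net.params)

    def test_nonpositive_hyperparameter_is_error(self):
        with pytest.raises(ModelError):
            ModelConfig(conv_filters=0)

    def test_batch_equals_sequential_evaluation(self):
        model = build_model(SMALL_CFG, SMALL_ENC)
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), size=25)) for _ in range(8)]
        batched = model.net.predict(encode_batch(seqs, SMALL_ENC), batch_size=8)
        looped = np.array([model.score(s) for s in seqs])
        np.testing.assert_allclose(batched, looped, atol=1e-6)

    def test_duplicate_sequence_scores_identically(self):
        model = build_model(SMALL_CFG, SMALL_ENC)
        s = "MKTAYIAKQR"
        assert model.score(s) == model.score(s)


class TestArchive:
    def test_save_load_round_trip_scores(self, tmp_path):
        model = build_model(SMALL_CFG, SMALL_ENC, seed=5)
        p = tmp_path / "m.hdf5"
        model.save(p)
        loaded = PredictionModel.load(p)
        seqs = ["MKT", "MVLKPA", "M" + "W" * 30]
        np.testing.assert_allclose(model.score_batch(seqs), loaded.score_batch(seqs), atol=0)
        assert loaded.encoder == model.encoder

    def test_load_rejects_non_archive(self, tmp_path):
        import h5py

        p = tmp_path / "x.hdf5"
        with h5py.File(p, "w") as f:
            f.create_dataset("junk", data=[1, 2])
        with pytest.raises(ModelError):
            PredictionModel.load(p)


class TestAggregate:
    def test_max_of_list(self):
        assert aggregate([0.2, 0.5, 0.9]) == 0.9

    def test_singleton(self):
        assert aggregate([0.7]) == 0.7

    def test_empty_is_error(self):
        with pytest.raises(ModelError):
            aggregate([])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_equals_bruteforce_max(self, scores):
        expected = scores[0]
        for s in scores[1:]:
            if s > expected:
                expected = s
        assert aggregate(scores) == expected

    def test_monotone_in_any_single_score(self):
        scores = [0.3, 0.6, 0.2]
        base = aggregate(scores)
        for i in range(3):
            bumped = list(scores)
            bumped[i] = min(1.0, bumped[i] + 0.3)
            assert aggregate(bumped) >= base

    def test_score_candidates_one_per_protein(self):
        model = build_model(SMALL_CFG, SMALL_ENC)
        fus = FusionInput(Breakpoint("c", 1, "five_prime"), Breakpoint("c", 2, "three_prime"))
        prots = [
            CandidateProtein("MKT", "t1", "t2", 1, False, False, False, True),
            CandidateProtein("MVLKP", "t1", "t3", 2, True, False, False, False),
        ]
        cset = FusionCandidateSet(fus, None, None, prots)
        scores = score_candidates(model, cset)
        assert scores.shape == (2,)
        assert np.all((scores >= 0) & (scores <= 1))


def _results(probs):
    return [
        FusionResult(fusion_pair=f"P{i}", onc_prob=p, source_row=i) for i, p in enumerate(probs)
    ]


class TestRankAndFilter:
    def test_sorted_and_thresholded(self):
        out = rank_and_filter(_results([0.9, 0.1, 0.8]), ThresholdPolicy(0.8))
        assert [r.onc_prob for r in out] == [0.9, 0.8]

    def test_boundary_probability_retained(self):
        out = rank_and_filter(_results([0.80]), ThresholdPolicy(0.8))
        assert len(out) == 1

    def test_threshold_zero_keeps_all_scored(self):
        out = rank_and_filter(_results([0.5, None, 0.2]), ThresholdPolicy(0.0))
        assert [r.onc_prob for r in out] == [0.5, 0.2]  # NA dropped from the view

    def test_retained_count_non_increasing_in_threshold(self):
        rng = np.random.default_rng(1)
        results = _results(list(rng.random(50)))
        counts = [len(rank_and_filter(results, ThresholdPolicy(t))) for t in np.linspace(0, 1, 11)]
        assert counts == sorted(counts, reverse=True)

    def test_ties_stable_by_input_order(self):
        out = rank_and_filter(_results([0.5, 0.9, 0.5]), ThresholdPolicy(0.0))
        assert [r.source_row for r in out] == [1, 0, 2]

    def test_invalid_threshold_is_error(self):
        with pytest.raises(ModelError):
            ThresholdPolicy(1.5)
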