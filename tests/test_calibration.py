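"""Shuffle null, false-discovery curve, thresholding, and dictionaries."""

import numpy as np
import pytest

from ubia import (
    BinaryDataset,
    CalibrationCurve,
    CandidateConfig,
    PipelineConfig,
    consistency_check,
    extract_dictionary,
    false_discovery_curve,
    interaction_pruning_fraction,
    shuffle_dataset,
    solve_trajectory,
    threshold_for,
)
from ubia.calibration import Dictionary, DictionaryEntry
from ubia.data import WordSupport


SMALL = PipelineConfig(candidates=CandidateConfig(k_max=3, n_max=50), R=20)


class TestShuffle:
    def test_column_sums_preserved(self, small_random_data, rng):
        shuffled = shuffle_dataset(small_random_data, rng)
        np.testing.assert_array_equal(
            shuffled.values.sum(axis=0), small_random_data.values.sum(axis=0)
        )

    def test_single_row_unchanged(self, rng):
        data = BinaryDataset(np.array([[1, 0, 1]], dtype=np.uint8))
        assert np.array_equal(shuffle_dataset(data, rng).values, data.values)

    def test_perfect_correlation_destroyed(self, rng):
        M = 1000
        col = (rng.random(M) < 0.5).astype(np.uint8)
        data = BinaryDataset(np.column_stack([col, col]))
        shuffled = shuffle_dataset(data, rng)
        r = np.corrcoef(shuffled.values.T)[0, 1]
        assert abs(r) < 3 / np.sqrt(M)


@pytest.fixture(scope="module")
def curve_and_data():
    rng = np.random.default_rng(7)
    data = BinaryDataset((rng.random((150, 8)) < 0.25).astype(np.uint8))
    curve = false_discovery_curve(data, SMALL, rng=rng)
    return curve, data


class TestCurve:

    def test_monotone_non_increasing(self, curve_and_data):
        curve, _ = curve_and_data
        assert np.all(np.diff(curve.n_false) <= 1e-12)

    def test_extremes(self, curve_and_data):
        curve, _ = curve_and_data
        assert curve.n_false[-1] == 0.0           # above max magnetization
        assert curve.n_false[0] == curve.n_false.max()  # threshold -1 admits all

    def test_threshold_selection(self):
        curve = CalibrationCurve(
            m_grid=np.array([-1.0, 0.1, 0.2, 0.3]),
            n_false=np.array([10.0, 3.0, 0.4, 0.0]),
            R=10,
        )
        assert threshold_for(curve, 0.5) == pytest.approx(0.2)
        assert threshold_for(curve, 100.0) == pytest.approx(-1.0)
        assert threshold_for(curve, 3.0) == pytest.approx(0.1)


class TestDictionary:
    def test_end_to_end_determinism(self, small_random_data):
        d1 = extract_dictionary(small_random_data, SMALL, np.random.default_rng(3))
        d2 = extract_dictionary(small_random_data, SMALL, np.random.default_rng(3))
        assert d1.threshold == d2.threshold
        assert [tuple(e.support) for e in d1.entries] == [
            tuple(e.support) for e in d2.entries
        ]

    def test_empty_dictionary_is_legal(self, rng):
        # independent columns: expect roughly n_false_target detections
        data = BinaryDataset((rng.random((200, 8)) < 0.2).astype(np.uint8))
        d = extract_dictionary(data, SMALL, rng)
        assert len(d) <= 5  # weak null data admits at most a few words

    def test_planted_pairwise_interaction_detected(self):
        """A strong planted second-order dependency enters the dictionary."""
        from ubia import sample_dataset, GenerativeModelSpec

        rng = np.random.default_rng(11)
        found = 0
        runs = 3
        for _ in range(runs):
            spec = GenerativeModelSpec(
                N=10,
                biases=np.full(10, -0.7),
                interactions=[(WordSupport([2, 5]), 1.2)],
            )
            data = sample_dataset(spec, 1600, rng)
            d = extract_dictionary(
                data, PipelineConfig(candidates=CandidateConfig(k_max=3, n_max=100), R=30), rng
            )
            if (2, 5) in {tuple(s) for s in d.supports}:
                found += 1
        assert found >= 2

    def test_json_roundtrip(self, small_random_data, tmp_path):
        import json

        d = extract_dictionary(small_random_data, SMALL, np.random.default_rng(5))
        path = tmp_path / "dict.json"
        d.save(path)
        back = json.loads(path.read_text())
        assert back["threshold"] == pytest.approx(d.threshold)
        assert len(back["entries"]) == len(d)
        assert "eps" in back


class TestSelfConsistency:
    def test_shuffled_data_detections_at_most_target(self):
        """On pre-shuffled (null) data the pipeline detects on average no
        more than the n_false target, within 2 standard errors."""
        rng = np.random.default_rng(17)
        base = BinaryDataset((rng.random((300, 10)) < 0.25).astype(np.uint8))
        cfg = PipelineConfig(candidates=CandidateConfig(k_max=3, n_max=80), R=25)
        counts = []
        for _ in range(50):
            null_data = shuffle_dataset(base, rng)
            d = extract_dictionary(null_data, cfg, rng)
            counts.append(len(d))
        counts = np.asarray(counts, dtype=float)
        sem = counts.std(ddof=1) / np.sqrt(len(counts))
        assert counts.mean() <= cfg.n_false_target + 2 * sem


class TestConsistencyCheck:
    def _dict(self, entries, output_index=0):
        cfg = PipelineConfig(output_index=output_index)
        return Dictionary(
            entries=[
                DictionaryEntry(
                    support=WordSupport(sup), magnetization=0.5, field=10.0,
                    deviation=dev, is_codeword=0 in sup,
                )
                for sup, dev in entries
            ],
            threshold=0.1,
            config=cfg,
        )

    def test_disjoint_codeword_sets(self):
        a = self._dict([((0, 1), 0.1), ((0, 2), -0.1)])
        b = self._dict([((0, 3), 0.1)])
        assert consistency_check(a, b) == 0

    def test_shared_non_codewords_ignored(self):
        a = self._dict([((1, 2), 0.1), ((0, 3), 0.1)])
        b = self._dict([((1, 2), 0.1), ((0, 4), 0.1)])
        assert consistency_check(a, b) == 0

    def test_same_direction_codeword_counted(self):
        a = self._dict([((0, 1), 0.2), ((0, 2), 0.2)])
        b = self._dict([((0, 1), 0.1), ((0, 2), -0.1)])
        assert consistency_check(a, b) == 1

    def test_mismatched_configs_rejected(self):
        a = self._dict([((0, 1), 0.2)], output_index=0)
        b = self._dict([((0, 1), 0.2)], output_index=1)
        with pytest.raises(ValueError, match="mismatched"):
            consistency_check(a, b)


class TestPruning:
    def test_decoupled_system_never_prunes(self):
        """With J = 0, magnetization is monotone in h: nothing with a field
        above the dictionary minimum can be excluded."""
        from ubia import GenerativeModelSpec, sample_dataset

        rng = np.random.default_rng(19)
        spec = GenerativeModelSpec(
            N=8, biases=np.full(8, -0.7),
            interactions=[(WordSupport([1, 4]), 1.0), (WordSupport([2, 6]), 0.9)],
        )
        data = sample_dataset(spec, 1200, rng)
        d = extract_dictionary(
            data, PipelineConfig(candidates=CandidateConfig(k_max=3, n_max=80), R=25), rng
        )
        assert len(d) > 0
        sys0 = d.system
        sys0.J = np.zeros_like(sys0.J)
        traj = solve_trajectory(sys0, data.M)
        m = traj.final_m
        entries = [
            DictionaryEntry(sys0.supports[i], float(m[i]), float(sys0.h[i]), 0.0, False)
            for i in np.flatnonzero(m > d.threshold)
        ]
        assert entries
        d0 = Dictionary(entries=entries, threshold=d.threshold, config=d.config)
        assert interaction_pruning_fraction(sys0, traj, d0) == 0.0

    def test_empty_dictionary_undefined(self, small_random_data):
        d = Dictionary(entries=[], threshold=0.5, config=SMALL)
        sys_ = extract_dictionary(small_random_data, SMALL, np.random.default_rng(2)).system
        assert interaction_pruning_fraction(sys_, None, d) is None
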