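"""Segmentation, splitting and EDF loading."""

from pathlib import Path

import numpy as np
import pytest

import mignet as mg
from mignet.data import (EXCLUDED_SUBJECTS, Trial, load_physionet_subject,
                         load_segments, load_trials, save_segments, save_trials,
                         trials_from_raw)

from _edf_writer import write_edf


def make_trial(L=640, label=0, seed=0, C=4, trial_id=0):
    rng = np.random.default_rng(seed)
    return Trial(data=rng.standard_normal((C, L)), label=label,
                 subject_id=1, trial_id=trial_id)


class TestSlidingWindow:
    @pytest.mark.parametrize(
        "L,window,stride,expected",
        [(640, 160, 20, 25),   # the full protocol: 25 windows per 4-s trial
         (160, 160, 20, 1),    # exact fit
         (200, 160, 20, 3)],   # starts at 0, 20, 40
    )
    def test_window_count(self, L, window, stride, expected):
        segs = mg.sliding_window(make_trial(L), window, stride)
        assert len(segs) == expected

    def test_window_starts_and_bitexact_content(self):
        t = make_trial(200)
        segs = mg.sliding_window(t, 160, 20)
        for w, s in enumerate(segs):
            assert s.window_index == w
            np.testing.assert_array_equal(s.data, t.data[:, w * 20 : w * 20 + 160])
            assert s.label == t.label and s.trial_id == t.trial_id

    def test_single_window_equals_trial(self):
        t = make_trial(160)
        (s,) = mg.sliding_window(t, 160, 20)
        np.testing.assert_array_equal(s.data, t.data)

    def test_window_longer_than_trial_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            mg.sliding_window(make_trial(100), 160, 20)

    def test_subject_segment_count_at_protocol_scale(self):
        # 84 trials per subject (4 balanced tasks) x 25 windows = 2100 segments
        trials = [make_trial(640, label=k % 4, seed=k, trial_id=k) for k in range(84)]
        segs = mg.window_trials(trials)
        assert len(segs) == 2100


@pytest.fixture(scope="module")
def balanced_trials():
    return [make_trial(64, label=k % 4, seed=k, trial_id=k) for k in range(4 * 84)]


class TestSplitTrials:

    def test_stratified_8_to_2_counts(self, balanced_trials):
        tr, te = mg.split_trials(balanced_trials, ratio=0.8, seed=0)
        assert len(tr) == 268 and len(te) == 68   # floor(0.8*84)=67 per class
        for k in range(4):
            assert sum(t.label == k for t in tr) == 67
            assert sum(t.label == k for t in te) == 17

    def test_deterministic_given_seed(self, balanced_trials):
        a = mg.split_trials(balanced_trials, 0.8, seed=5)
        b = mg.split_trials(balanced_trials, 0.8, seed=5)
        assert [t.trial_id for t in a[0]] == [t.trial_id for t in b[0]]
        assert [t.trial_id for t in a[1]] == [t.trial_id for t in b[1]]

    def test_no_trial_in_both_sets_even_after_windowing(self, balanced_trials):
        tr, te = mg.split_trials(balanced_trials, 0.8, seed=1)
        tr_ids = {s.trial_id for s in mg.window_trials(tr, 32, 8)}
        te_ids = {s.trial_id for s in mg.window_trials(te, 32, 8)}
        assert tr_ids.isdisjoint(te_ids)

    @pytest.mark.parametrize("ratio", [0.0, 1.0, 1.5])
    def test_ratio_bounds(self, balanced_trials, ratio):
        with pytest.raises(ValueError, match="ratio"):
            mg.split_trials(balanced_trials, ratio, seed=0)

    def test_undersized_class_raises(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            mg.split_trials([make_trial(64, label=0)], 0.8, seed=0)


class TestArchives:
    def test_segment_archive_roundtrip(self, tmp_path):
        segs = mg.window_trials([make_trial(200, label=2, trial_id=9)], 160, 20)
        p = tmp_path / "segs.npz"
        save_segments(p, segs)
        again = load_segments(p)
        assert len(again) == len(segs)
        for a, b in zip(again, segs):
            np.testing.assert_array_equal(a.data, b.data)
            assert (a.label, a.trial_id, a.window_index) == (b.label, b.trial_id, b.window_index)

    def test_trial_archive_roundtrip(self, tmp_path):
        trials = [make_trial(64, label=1, trial_id=3), make_trial(64, label=2, trial_id=4)]
        p = tmp_path / "trials.npz"
        save_trials(p, trials)
        again = load_trials(p)
        assert [t.trial_id for t in again] == [3, 4]
        np.testing.assert_array_equal(again[0].data, trials[0].data)


def _edf_channel_names(layout):
    # PhysioNet writes e.g. "Fc5." / "Cz.." (mixed case, dot padding)
    return [n.capitalize().ljust(4, ".") for n in layout.names]


class TestEDFLoading:
    @pytest.fixture()
    def edf_file(self, layout, tmp_path):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((64, 160 * 15)) * 40
        path = tmp_path / "S001R04.edf"
        write_edf(path, data, 160.0, _edf_channel_names(layout),
                  annotations=[(0.0, 4.0, "T0"), (2.0, 4.0, "T1"), (8.5, 4.0, "T2")])
        return path, data

    def test_two_annotated_events_become_two_trials(self, edf_file, layout):
        path, source = edf_file
        trials = load_physionet_subject([path], layout)
        assert len(trials) == 2
        assert trials[0].data.shape == (64, 640)
        assert [t.label for t in trials] == [0, 1]  # run 4: T1 -> left, T2 -> right
        # content matches the source slice (mne rescales uV -> V)
        got = trials[0].data[0]
        want = source[0, 320 : 320 + 640]
        assert np.corrcoef(got, want)[0, 1] > 0.999

    def test_run_number_selects_label_map(self, edf_file, layout, tmp_path):
        path, source = edf_file
        r06 = tmp_path / "S001R06.edf"
        r06.write_bytes(Path(path).read_bytes())
        trials = load_physionet_subject([r06], layout)
        assert [t.label for t in trials] == [2, 3]  # run 6: fists / feet

    def test_excluded_subject_skipped(self, edf_file, layout, tmp_path, caplog):
        path, _ = edf_file
        bad = tmp_path / "S088R04.edf"
        bad.write_bytes(Path(path).read_bytes())
        assert 88 in EXCLUDED_SUBJECTS
        with caplog.at_level("INFO"):
            trials = load_physionet_subject([bad], layout)
        assert trials == []
        assert any("excluded" in r.message for r in caplog.records)

    def test_wrong_sampling_rate_raises(self, layout, tmp_path):
        rng = np.random.default_rng(0)
        path = tmp_path / "S001R04.edf"
        write_edf(path, rng.standard_normal((64, 128 * 6)), 128.0,
                  _edf_channel_names(layout), annotations=[(0.0, 4.0, "T1")])
        with pytest.raises(ValueError, match="sampling rate"):
            load_physionet_subject([path], layout)

    def test_non_imagery_run_skipped(self, edf_file, layout, tmp_path):
        path, _ = edf_file
        r03 = tmp_path / "S001R03.edf"  # executed movement, not imagery
        r03.write_bytes(Path(path).read_bytes())
        assert load_physionet_subject([r03], layout) == []


class TestTrialsFromRaw:
    def test_channel_reordering_to_montage(self, layout):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((64, 800))
        shuffled = list(range(64))[::-1]
        trials = trials_from_raw(
            data[shuffled], 160.0, [layout.names[i] for i in shuffled],
            [(0.0, "T1")], run_number=4, subject_id=1, montage=layout,
        )
        np.testing.assert_array_equal(trials[0].data, data[:, :640])

    def test_unknown_annotation_raises(self, layout):
        data = np.zeros((64, 800))
        with pytest.raises(ValueError, match="unknown annotation"):
            trials_from_raw(data, 160.0, list(layout.names), [(0.0, "T7")],
                            run_number=4, subject_id=1, montage=layout)

    def test_missing_channel_raises(self, layout):
        data = np.zeros((63, 800))
        with pytest.raises(ValueError, match="missing montage channels"):
            trials_from_raw(data, 160.0, list(layout.names)[:-1], [(0.0, "T1")],
                            run_number=4, subject_id=1, montage=layout)


def test_bandpass_filter_attenuates_out_of_band():
    fs = 160.0
    t = np.arange(int(fs * 8)) / fs
    x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 60 * t)
    y = mg.bandpass_filter(x[None, :], fs)[0]
    spec = np.abs(np.fft.rfft(y))
    f = np.fft.rfftfreq(len(y), 1 / fs)
    assert spec[np.argmin(abs(f - 60))] < 0.01 * spec[np.argmin(abs(f - 10))]
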