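"""Signal-conditioning contracts: referencing, filtering, interpolation,
stage-gated segmentation."""

import numpy as np
import pytest

from psgstats.preprocess import (Hypnogram, Montage, Recording, highpass,
                                 interpolate_bad, rereference, segment)

from conftest import flat_recording, stage_hypnogram

FS = 500.0


def _rec(data, labels=None, types=None):
    data = np.asarray(data, dtype=float)
    labels = labels or [f"C{i}" for i in range(data.shape[0])]
    types = types or ["EEG"] * data.shape[0]
    return Recording(data, FS, labels, types)


class TestRereference:
    def test_subtracts_mastoid_mean(self):
        rec = _rec(np.array([[5.0], [1.0], [3.0]]), ["Cz", "M1", "M2"],
                   ["EEG", "mastoid", "mastoid"])
        out = rereference(rec, ("M1", "M2"))
        assert out.data[0, 0] == pytest.approx(5.0 - 2.0)
        assert out.reference == "linked:M1+M2"

    def test_zero_reference_is_identity(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((4, 100))
        data[2] = 0.0
        data[3] = 0.0
        rec = _rec(data, ["A", "B", "M1", "M2"])
        out = rereference(rec, ("M1", "M2"))
        np.testing.assert_array_equal(out.data[:2], rec.data[:2])

    def test_preserves_pairwise_differences(self):
        rng = np.random.default_rng(1)
        rec = _rec(rng.standard_normal((5, 200)))
        out = rereference(rec, ("C3", "C4"))
        np.testing.assert_allclose(out.data[0] - out.data[1],
                                   rec.data[0] - rec.data[1], atol=1e-12)

    def test_idempotent_when_reference_mean_is_zero(self):
        # once the mastoid pair averages to zero, re-applying is neutral
        rng = np.random.default_rng(2)
        data = rng.standard_normal((4, 50))
        data[3] = -data[2]               # mean(M1, M2) == 0 samplewise
        rec = _rec(data, ["A", "B", "M1", "M2"])
        once = rereference(rec, ("M1", "M2"))
        again = rereference(once, ("M1", "M2"))
        np.testing.assert_array_equal(again.data, once.data)

    def test_missing_reference_errors(self):
        rec = _rec(np.zeros((2, 10)))
        with pytest.raises(KeyError):
            rereference(rec, ("C0", "nope"))


class TestHighpass:
    def test_dc_rejection(self):
        rec = flat_recording(1, int(60 * FS), value=100.0)
        out = highpass(rec, 0.1)
        assert np.max(np.abs(out.data)) < 1.0

    def test_passband_unity(self):
        t = np.arange(int(120 * FS)) / FS
        rec = _rec(np.sin(2 * np.pi * 10 * t)[None, :])
        out = highpass(rec, 0.1)
        mid = out.data[0, int(30 * FS):-int(30 * FS)]
        amp = np.sqrt(2) * np.sqrt(np.mean(mid**2))  # steady-state amplitude
        assert 0.95 <= amp <= 1.05

    def test_deep_stopband(self):
        # 0.01 Hz is a decade below the 0.1-Hz cutoff
        t = np.arange(int(400 * FS)) / FS
        rec = _rec(np.sin(2 * np.pi * 0.01 * t)[None, :])
        out = highpass(rec, 0.1)
        mid = out.data[0, int(100 * FS):-int(100 * FS)]
        assert np.max(np.abs(mid)) < 0.5

    @pytest.mark.parametrize("cutoff", [0.0, -1.0, 250.0, 400.0])
    def test_invalid_cutoff(self, cutoff):
        rec = flat_recording(1, 1000)
        with pytest.raises(ValueError):
            highpass(rec, cutoff)


class TestInterpolateBad:
    def test_equidistant_pair_average(self):
        mont = Montage({"A": (-1, 0, 0), "B": (1, 0, 0), "X": (0, 0, 0)})
        rec = _rec(np.array([[2.0], [4.0], [99.0]]), ["A", "B", "X"])
        out = interpolate_bad(rec, mont, ["X"])
        assert out.data[2, 0] == pytest.approx(3.0)
        np.testing.assert_array_equal(out.data[:2], rec.data[:2])

    def test_empty_bad_list_is_identity(self):
        mont = Montage({"A": (0, 0, 0), "B": (1, 0, 0)})
        rec = _rec(np.random.default_rng(0).standard_normal((2, 20)),
                   ["A", "B"])
        out = interpolate_bad(rec, mont, [])
        np.testing.assert_array_equal(out.data, rec.data)

    def test_inverse_square_distance_weights(self):
        mont = Montage({"A": (1, 0, 0), "B": (2, 0, 0), "C": (0, 3, 0),
                        "X": (0, 0, 0)})
        vals = np.array([[10.0], [20.0], [30.0], [0.0]])
        rec = _rec(vals, ["A", "B", "C", "X"])
        w = np.array([1 / 1.0, 1 / 4.0, 1 / 9.0])
        expected = (w @ np.array([10.0, 20.0, 30.0])) / w.sum()
        out = interpolate_bad(rec, mont, ["X"])
        assert out.data[3, 0] == pytest.approx(expected)

    def test_too_few_good_channels(self):
        mont = Montage({"A": (0, 0, 0), "B": (1, 0, 0), "C": (2, 0, 0)})
        rec = _rec(np.zeros((3, 5)), ["A", "B", "C"])
        with pytest.raises(ValueError):
            interpolate_bad(rec, mont, ["A", "B"])


class TestSegment:
    def test_window_count_in_continuous_run(self):
        hyp = stage_hypnogram("N2*2")  # 60 s
        rec = flat_recording(2, int(60 * FS))
        eps = segment(rec, hyp, {"N2"})
        assert eps.n_epochs == 13        # floor((60-8.192)/4.096)+1
        assert eps.epochs.shape[2] == 4096

    def test_run_shorter_than_window(self):
        hyp = stage_hypnogram("N2")      # 30 s < 2x8.192 stride maths
        rec = flat_recording(1, int(30 * FS))
        eps = segment(rec, hyp, {"N2"}, epoch_len_s=32.0)
        assert eps.n_epochs == 0

    def test_windows_never_straddle_runs(self):
        hyp = stage_hypnogram("N2,W,N2")   # two 30-s runs split by wake
        rec = flat_recording(1, int(90 * FS))
        eps = segment(rec, hyp, {"N2"})
        # each 30-s run: floor((30-8.192)/4.096)+1 = 6 windows
        assert eps.n_epochs == 12
        spans = [(s, s + 4096) for s in eps.starts]
        wake = (int(30 * FS), int(60 * FS))
        assert all(hi <= wake[0] or lo >= wake[1] for lo, hi in spans)

    def test_artifact_epochs_excluded(self):
        art = np.array([False, True, False])
        hyp = stage_hypnogram("N2,N2,N2", artifact=art)
        rec = flat_recording(1, int(90 * FS))
        eps = segment(rec, hyp, {"N2"})
        bad = (int(30 * FS), int(60 * FS))
        assert eps.n_epochs == 12
        assert all(s + 4096 <= bad[0] or s >= bad[1] for s in eps.starts)

    def test_count_invariant_to_channel_permutation(self):
        hyp = stage_hypnogram("N2*3,REM*2,N2*2")
        rng = np.random.default_rng(5)
        data = rng.standard_normal((4, int(hyp.duration_s * FS)))
        rec = _rec(data)
        eps1 = segment(rec, hyp, {"N2"})
        perm = [2, 0, 3, 1]
        rec2 = _rec(data[perm], labels=[rec.labels[i] for i in perm])
        eps2 = segment(rec2, hyp, {"N2"})
        assert eps1.n_epochs == eps2.n_epochs
        np.testing.assert_array_equal(eps1.starts, eps2.starts)

    def test_empty_result_not_error(self):
        hyp = stage_hypnogram("W*4")
        rec = flat_recording(1, int(120 * FS))
        assert segment(rec, hyp, {"N2"}).n_epochs == 0
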