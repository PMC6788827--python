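import numpy as np
import pandas as pd
import pytest

from confseek.epochs import EpochSet
from confseek import preprocess as pp


def _epochs(data, srate=250.0, t0=-100.0, alignment="stimulus"):
    data = np.asarray(data, float)
    n_samples = data.shape[2]
    dt = 1000.0 / srate
    return EpochSet(data=data, times_ms=t0 + dt * np.arange(n_samples),
                    channel_names=[f"ch{i}" for i in range(data.shape[1])],
                    srate_hz=srate, alignment=alignment,
                    trial_index=np.arange(data.shape[0]))


class TestBaseline:
    def test_window_mean_zero(self, rng):
        ep = _epochs(rng.standard_normal((5, 3, 100)))
        out = pp.baseline_correct(ep, (-100, 0))
        sel = (out.times_ms >= -100) & (out.times_ms <= 0)
        assert np.allclose(out.data[:, :, sel].mean(axis=2), 0.0, atol=1e-10)
        assert out.baseline_window_ms == (-100.0, 0.0)

    def test_idempotent(self, rng):
        ep = _epochs(rng.standard_normal((4, 2, 80)))
        once = pp.baseline_correct(ep, (-100, -20))
        twice = pp.baseline_correct(once, (-100, -20))
        assert np.allclose(once.data, twice.data)

    def test_constant_offset_removed(self):
        ep = _epochs(np.full((2, 2, 50), 7.0))
        out = pp.baseline_correct(ep, (-100, 0))
        assert np.allclose(out.data, 0.0)

    def test_window_outside_epoch_rejected(self, rng):
        ep = _epochs(rng.standard_normal((2, 2, 50)))
        with pytest.raises(ValueError, match="outside"):
            pp.baseline_correct(ep, (-500, -200))


class TestRealign:
    def test_zero_offsets_identity(self, rng):
        ep = _epochs(rng.standard_normal((3, 2, 100)))
        out = pp.realign(ep, np.zeros(3), (-100, 100), "response")
        sel = (ep.times_ms >= -100) & (ep.times_ms <= 100)
        assert np.allclose(out.data, ep.data[:, :, sel])

    def test_sample_lands_at_new_zero(self, rng):
        ep = _epochs(rng.standard_normal((1, 2, 200)))
        out = pp.realign(ep, np.array([300.0]), (-100, 100), "response")
        i_old = ep.time_index(300.0)
        i_new = out.time_index(0.0)
        assert np.allclose(out.data[0, :, i_new], ep.data[0, :, i_old])

    def test_out_of_range_trials_dropped(self, rng):
        ep = _epochs(rng.standard_normal((3, 2, 100)))  # -100..296 ms
        out = pp.realign(ep, np.array([0.0, 200.0, 10000.0]), (-100, 90),
                         "response")
        assert list(out.trial_index) == [0, 1]

    def test_inverse_realignment_roundtrip(self, rng):
        ep = _epochs(rng.standard_normal((4, 2, 300)))  # -100..1096 ms
        offs = np.array([200.0, 240.0, 280.0, 320.0])
        fwd = pp.realign(ep, offs, (-100, 200), "response")
        back = pp.realign(fwd, -offs, (220, 300), "stimulus")
        sel = (ep.times_ms >= 220) & (ep.times_ms <= 300)
        assert np.allclose(back.data, ep.data[:, :, sel])

    def test_offgrid_offsets_rejected(self, rng):
        ep = _epochs(rng.standard_normal((1, 2, 100)))
        with pytest.raises(ValueError, match="multiples"):
            pp.realign(ep, np.array([301.7]), (-100, 100), "response")

    def test_missing_offsets_rejected(self, rng):
        ep = _epochs(rng.standard_normal((2, 2, 100)))
        with pytest.raises(ValueError, match="missing"):
            pp.realign(ep, np.array([0.0, np.nan]), (-50, 50), "response")


class TestRejectExtreme:
    def test_peak_beyond_threshold_rejected(self, rng):
        data = rng.standard_normal((2, 2, 50))
        data[1, 0, 10] = 250.0
        ep = _epochs(data)
        kept, mask = pp.reject_extreme(ep)
        assert list(kept.trial_index) == [0]
        assert mask.reason[1] == "extreme_value"

    def test_bounded_epochs_all_kept(self, rng):
        ep = _epochs(50.0 * np.tanh(rng.standard_normal((6, 3, 40))))
        kept, mask = pp.reject_extreme(ep)
        assert kept.n_trials == 6
        assert mask.keep.all()

    def test_spike_count(self, rng):
        data = rng.standard_normal((10, 4, 60))
        for i in (2, 5, 7):
            data[i, 1, 30] = 300.0
        kept, mask = pp.reject_extreme(_epochs(data))
        assert kept.n_trials == 7
        assert sorted(np.flatnonzero(~mask.keep)) == [2, 5, 7]

    def test_mask_is_pure_function_of_amplitudes(self, rng):
        data = rng.standard_normal((8, 3, 40))
        data[[1, 4], 0, 0] = 400.0
        perm = rng.permutation(8)
        _, m1 = pp.reject_extreme(_epochs(data))
        _, m2 = pp.reject_extreme(_epochs(data[perm]))
        assert (m2.keep == m1.keep[perm]).all()

    def test_all_rejected_is_error(self):
        with pytest.raises(ValueError, match="every trial"):
            pp.reject_extreme(_epochs(np.full((3, 2, 10), 500.0)))


class TestZScore:
    def test_hand_computed_two_value_block(self):
        t = pd.DataFrame({"participant": [0, 0], "block": [1, 1],
                          "confidence_abs": [10, 30]})
        out = pp.zscore_confidence(t)
        assert np.allclose(out["confidence_z"],
                           [-0.7071067811865475, 0.7071067811865475])

    def test_degenerate_block_flagged(self):
        t = pd.DataFrame({"participant": [0] * 3, "block": [1] * 3,
                          "confidence_abs": [20, 20, 20]})
        out = pp.zscore_confidence(t)
        assert (out["confidence_z"] == 0).all()
        assert (out["confidence_z_flag"] == "degenerate").all()


from hypothesis import given, settings
from hypothesis import strategies as st


class TestMedianSplit:
    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.integers(min_value=0, max_value=9), min_size=2,
                    max_size=120).filter(lambda v: len(set(v)) >= 2))
    def test_property_balance_and_side_assignment(self, values):
        v = np.asarray(values, float)
        s = pp.median_split(v)
        n_high = int((s.label == "high").sum())
        n_low = len(v) - n_high
        assert abs(n_high - n_low) <= max(1, int((v == s.split_value).sum()))
        assert (s.label[v > s.split_value] == "high").all()
        assert (s.label[v < s.split_value] == "low").all()

    def test_even_clean_split(self):
        s = pp.median_split([1, 2, 3, 4])
        assert list(s.label) == ["low", "low", "high", "high"]
        assert s.split_value == 2.5

    def test_ties_balanced(self):
        s = pp.median_split([1, 2, 2, 3])
        labels = list(s.label)
        assert labels.count("high") == 2 and labels.count("low") == 2
        assert s.split_value == 2.0

    def test_imbalance_bounded_by_tie_count(self, rng):
        v = rng.integers(0, 5, size=101).astype(float)
        s = pp.median_split(v)
        n_high = (s.label == "high").sum()
        assert abs(int(n_high) - (101 - int(n_high))) <= 1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            pp.median_split([3, 3, 3])
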