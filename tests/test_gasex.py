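"""Metabolic power, gross efficiency, V̇O₂max windows and work-interval energetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclephys.gasex import (
    GasSeries,
    InsufficientDataError,
    aerobic_energy,
    gross_efficiency,
    metabolic_power,
    po_vo2max,
    time_at_or_above,
    vo2max_from_series,
)


def _series(vo2, sample_period=5.0, segments=None, power=None, rer=None):
    vo2 = np.asarray(vo2, dtype=float)
    n = vo2.size
    return GasSeries(
        sample_period=sample_period,
        power=np.full(n, 200.0) if power is None else np.asarray(power, float),
        vo2=vo2,
        rer=np.full(n, 0.95) if rer is None else np.asarray(rer, float),
        hr=np.full(n, 150.0),
        segments=segments,
    )


class TestMetabolicPower:
    def test_printed_constants_at_unit_vo2(self):
        assert metabolic_power(1.0, 1.0) == pytest.approx(21730.0)

    def test_hand_evaluation(self):
        # 4 L/min = 1/15 L/s at RER 0.90
        assert metabolic_power(4.0 / 60.0, 0.90) == pytest.approx(21246.0 / 15.0)

    def test_zero_vo2(self):
        assert metabolic_power(0.0, 0.9) == 0.0

    def test_rer_above_one_clamped(self):
        assert metabolic_power(1.0, 1.15) == metabolic_power(1.0, 1.0)

    def test_negative_vo2_rejected(self):
        with pytest.raises(ValueError):
            metabolic_power(-0.1, 0.9)

    def test_non_physiological_rer_rejected(self):
        with pytest.raises(ValueError):
            metabolic_power(1.0, 1.4)

    @given(
        vo2=st.floats(min_value=0, max_value=0.2),
        r1=st.floats(min_value=0.6, max_value=1.0),
        r2=st.floats(min_value=0.6, max_value=1.0),
        scale=st.floats(min_value=0.1, max_value=5.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_linear_in_vo2_and_monotone_in_rer(self, vo2, r1, r2, scale):
        assert metabolic_power(scale * vo2, r1) == pytest.approx(
            scale * metabolic_power(vo2, r1)
        )
        lo, hi = sorted((r1, r2))
        assert metabolic_power(vo2, lo) <= metabolic_power(vo2, hi) + 1e-9


class TestGrossEfficiency:
    def test_exact_ratio(self):
        assert gross_efficiency(250.0, 1250.0) == pytest.approx(20.0)

    def test_from_metabolic_power_example(self):
        pi = metabolic_power(4.0 / 60.0, 0.90)
        assert gross_efficiency(280.0, pi) == pytest.approx(19.77, abs=0.005)

    def test_zero_power(self):
        assert gross_efficiency(0.0, 1000.0) == 0.0

    def test_invalid_pi(self):
        with pytest.raises(ValueError):
            gross_efficiency(250.0, 0.0)


class TestVo2maxWindow:
    def test_constant_series(self):
        assert vo2max_from_series(_series([4000.0] * 30)) == pytest.approx(4000.0)

    def test_embedded_plateau(self):
        vo2 = [4000.0] * 20 + [4500.0] * 12 + [4000.0] * 20
        assert vo2max_from_series(_series(vo2)) == pytest.approx(4500.0)

    def test_too_short_series(self):
        with pytest.raises(InsufficientDataError):
            vo2max_from_series(_series([4000.0] * 11))

    def test_window_defined_in_seconds_not_samples(self):
        # 10-s sampling: 60-s window = 6 samples
        vo2 = [3000.0] * 10 + [4200.0] * 6 + [3000.0] * 10
        assert vo2max_from_series(_series(vo2, sample_period=10.0)) == pytest.approx(4200.0)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_equals_exhaustive_window_scan(self, seed):
        rng = np.random.default_rng(seed)
        vo2 = rng.uniform(2000, 5000, size=200)
        windows = np.lib.stride_tricks.sliding_window_view(vo2, 12).mean(axis=1)
        assert vo2max_from_series(_series(vo2)) == pytest.approx(windows.max())


class TestPoVo2max:
    def test_mean_of_two_half_minutes(self):
        power = np.concatenate([np.full(60, 200.0), np.full(6, 250.0), np.full(6, 275.0)])
        assert po_vo2max(power, 5.0) == pytest.approx(262.5)

    def test_constant_trace(self):
        assert po_vo2max(np.full(20, 300.0), 5.0) == 300.0

    def test_empty_trace(self):
        with pytest.raises(InsufficientDataError):
            po_vo2max(np.array([]), 5.0)


class TestTimeAtOrAbove:
    def test_counting(self):
        vo2 = np.array([3000.0] * 3 + [4600.0] * 7)
        s = _series(vo2, sample_period=10.0, segments=["work-1"] * 10)
        assert time_at_or_above(s, 5000.0, 0.9) == 70.0

    def test_all_below(self):
        s = _series([3000.0] * 10, sample_period=10.0, segments=["work-1"] * 10)
        assert time_at_or_above(s, 5000.0, 0.9) == 0.0

    def test_recovery_samples_excluded(self):
        vo2 = np.array([4600.0] * 5 + [4600.0] * 5)
        segs = ["work-1"] * 5 + ["recovery-1"] * 5
        s = _series(vo2, sample_period=10.0, segments=segs)
        assert time_at_or_above(s, 5000.0, 0.9) == 50.0

    def test_no_work_segments_warns_and_returns_zero(self):
        s = _series([4600.0] * 5, segments=["warmup"] * 5)
        with pytest.warns(UserWarning):
            assert time_at_or_above(s, 5000.0, 0.9) == 0.0


class TestAerobicEnergy:
    def test_cohort_scale_energy_rate(self):
        # group-mean V̇O₂ 54.0 mL/min/kg at 70.8 kg over 72 work-minutes:
        # the printed 1.38 kJ/s is matched within 1% for an RER in [0.95, 1.0]
        n = 432  # 4320 s at 10-s sampling
        hits = []
        for rer in np.arange(0.95, 1.0001, 0.01):
            s = _series(
                np.full(n, 54.0 * 70.8), sample_period=10.0,
                segments=["work-1"] * n, rer=np.full(n, rer),
            )
            res = aerobic_energy(s)
            hits.append(abs(res.energy_rate - 1.38) <= 0.01 * 1.38)
            assert res.energy_total == pytest.approx(res.energy_rate * 4320.0)
        assert any(hits)

    def test_zero_vo2(self):
        s = _series(np.zeros(10), segments=["work-1"] * 10)
        res = aerobic_energy(s)
        assert res.energy_rate == 0.0 and res.energy_total == 0.0

    def test_missing_rer_rejected(self):
        s = _series(np.full(10, 3000.0), segments=["work-1"] * 10)
        s.rer[3] = np.nan
        with pytest.raises(ValueError, match="RER missing"):
            aerobic_energy(s)

    def test_duration_weighted_additivity_over_work_intervals(self):
        """Whole-session energy equals the sum over a partition of work intervals."""
        rng = np.random.default_rng(5)
        n1, n2 = 30, 90  # unequal interval lengths
        vo2 = rng.uniform(3000, 4500, n1 + n2)
        rer = rng.uniform(0.9, 1.0, n1 + n2)
        segs = ["work-1"] * n1 + ["work-2"] * n2
        whole = aerobic_energy(_series(vo2, 10.0, segs, rer=rer))
        part1 = aerobic_energy(_series(vo2[:n1], 10.0, ["work-1"] * n1, rer=rer[:n1]))
        part2 = aerobic_energy(_series(vo2[n1:], 10.0, ["work-2"] * n2, rer=rer[n1:]))
        # energy totals are additive; the whole-session *rate* is the
        # duration-weighted mean of the per-interval rates
        assert whole.energy_total == pytest.approx(
            part1.energy_total + part2.energy_total, rel=5e-3
        )
        weighted = (part1.energy_rate * n1 + part2.energy_rate * n2) / (n1 + n2)
        assert whole.energy_rate == pytest.approx(weighted, rel=5e-3)
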