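import dataclasses
import math
from fractions import Fraction

import numpy as np
import pytest

from twoprocess import (
    ConfigurationError,
    EntrainmentStatus,
    ModelParams,
    ParameterError,
    circle_map_step,
    classify_rotation,
    invert_natural_period,
    natural_periods,
    preset,
    rotation_number,
    simulate,
    sleeps_per_day,
    staircase,
    tongue_scan,
)

# fewer iterations than the library default keep the sweep-based tests
# fast; plateau-membership questions are insensitive to this choice
SCAN_ITER = dict(n_iter=240, transient_iter=60)


def plateau_runs(frame, min_len=2):
    """Consecutive runs of identical rational labels in a staircase frame."""
    runs = []
    current = None
    for _, row in frame.iterrows():
        if row["status"] != EntrainmentStatus.RATIONAL.value:
            current = None
            continue
        label = (int(row["n"]), int(row["m"]))
        if current is not None and current[0] == label:
            current[1].append(row["H0_plus"])
        else:
            current = [label, [row["H0_plus"]]]
            runs.append(current)
    return [(label, vals) for label, vals in runs if len(vals) >= min_len]


class TestCircleMapStep:
    def test_rigid_rotation_at_zero_amplitude(self, unforced_params):
        T_nat = natural_periods(unforced_params).T_nat
        expected_advance = T_nat / unforced_params.T_f
        for phase in (0.0, 0.2, 0.55, 0.9):
            nxt, adv = circle_map_step(phase, unforced_params)
            assert adv == pytest.approx(expected_advance, abs=1e-9)
            assert nxt == pytest.approx((phase + expected_advance) % 1.0, abs=1e-9)

    def test_monotone_lift_small_amplitude(self, unforced_params):
        p = dataclasses.replace(unforced_params, a=0.01)
        phases = np.linspace(0.0, 1.0, 128, endpoint=False)
        lifts = np.array([phi + circle_map_step(float(phi), p)[1] for phi in phases])
        assert np.all(np.diff(lifts) > -1e-9)
        advances = lifts - phases
        assert np.max(np.abs(np.diff(advances))) < 0.05


class TestRotationNumber:
    def test_zero_amplitude_equals_Tf_over_Tnat(self, unforced_params):
        T_nat = natural_periods(unforced_params).T_nat
        rho = rotation_number(unforced_params)
        assert rho == pytest.approx(unforced_params.T_f / T_nat, abs=1e-6)

    def test_fig1e_two_per_day(self):
        assert rotation_number(preset("fig1e")) == pytest.approx(2.0, abs=1e-6)

    def test_fig1c_three_per_four_days(self):
        # the locked orbit has period 3 in map iterations; with n_iter not
        # a multiple of 3 the lift-edge effect is O(1/n_iter), inside the
        # classification tolerance
        assert rotation_number(preset("fig1c")) == pytest.approx(0.75, abs=1e-3)
        assert rotation_number(preset("fig1c"), n_iter=402) == pytest.approx(
            0.75, abs=1e-9
        )

    def test_iteration_floor(self, std_params):
        with pytest.raises(ParameterError):
            rotation_number(std_params, n_iter=10)


class TestClassifyRotation:
    def test_near_three_quarters(self):
        cls = classify_rotation(0.750002)
        assert (cls.n, cls.m) == (3, 4)
        assert cls.status is EntrainmentStatus.RATIONAL

    def test_unity(self):
        cls = classify_rotation(1.0)
        assert (cls.n, cls.m) == (1, 1)

    def test_golden_mean_is_quasiperiodic(self):
        rho = 0.6180
        # oracle: exhaustive search over all fractions with m <= 12
        best = min(
            abs(rho - n / m) for m in range(1, 13) for n in range(0, 3 * m)
        )
        assert best >= 1e-3
        assert classify_rotation(rho).status is EntrainmentStatus.QUASIPERIODIC

    def test_lowest_denominator_wins(self):
        # 0.5 is also 2/4, 3/6... the coarsest label must be returned
        cls = classify_rotation(0.5000004)
        assert (cls.n, cls.m) == (1, 2)

    def test_fraction_reduced(self):
        cls = classify_rotation(2.0)
        assert (cls.n, cls.m) == (2, 1)
        assert math.gcd(cls.n, cls.m) == 1

    def test_invalid_rho(self):
        with pytest.raises(ParameterError):
            classify_rotation(float("nan"))


class TestSleepsPerDay:
    def test_fig1d_three_per_two_days(self):
        r = simulate(preset("fig1d"), horizon=150 * 24.0)
        assert sleeps_per_day(r) == pytest.approx(1.5, abs=1 / 50)

    def test_agrees_with_rotation_number(self, std_params):
        r = simulate(std_params, horizon=150 * 24.0)
        assert abs(sleeps_per_day(r) - rotation_number(std_params)) < 1 / 50

    def test_perpetual_wake_zero_with_flag(self):
        p = ModelParams(chi_w=18.2, chi_s=4.2, H0_plus=1.2, H0_minus=0.17, a=0.1)
        r = simulate(p, horizon=120 * 24.0)
        assert sleeps_per_day(r) == 0.0
        assert r.nonterminating

    def test_short_record_warns(self, std_params):
        r = simulate(std_params, horizon=60 * 24.0, transient=50 * 24.0)
        with pytest.warns(UserWarning, match="forcing periods"):
            sleeps_per_day(r)


class TestStaircase:
    def test_zero_amplitude_degenerate(self, unforced_params):
        values = np.linspace(0.4, 0.8, 9)
        frame = staircase(values, unforced_params, **SCAN_ITER)
        expected = [
            unforced_params.T_f / natural_periods(
                dataclasses.replace(unforced_params, H0_plus=v)
            ).T_nat
            for v in values
        ]
        assert np.allclose(frame["rho"], expected, atol=1e-6)
        assert np.all(np.diff(frame["rho"]) < 0)

    def test_monotone_non_increasing_at_fixed_amplitude(self):
        base = preset("fig8_base")
        frame = staircase(np.linspace(0.3, 0.9, 31), base, **SCAN_ITER)
        rho = frame["rho"].to_numpy()
        # finite-orbit truncation allows tiny upward wiggles only
        assert np.all(np.diff(rho) < 2.0 / SCAN_ITER["n_iter"])

    def test_Tnat_8h_sits_on_two_per_day_plateau(self):
        base = preset("fig8_base")
        h8 = invert_natural_period(8.0, base)
        p8 = dataclasses.replace(base, H0_plus=h8)
        cls = classify_rotation(rotation_number(p8))
        assert cls.status is EntrainmentStatus.RATIONAL
        assert (cls.n, cls.m) == (2, 1)

    def test_unsorted_values_rejected(self, std_params):
        with pytest.raises(ConfigurationError):
            staircase([0.6, 0.5], std_params)


@pytest.fixture(scope="module")
def small_amp_staircase():
    base = dataclasses.replace(preset("fig7_base"), a=0.04)
    return staircase(np.linspace(0.3, 0.92, 60), base, **SCAN_ITER)


class TestFareyStructure:
    def test_plateaus_ordered_by_fraction(self, small_amp_staircase):
        labels = [Fraction(n, m) for (n, m), _ in plateau_runs(small_amp_staircase)]
        assert len(labels) >= 3
        assert labels == sorted(labels, reverse=True)

    def test_intermediate_plateaus_are_mediant_or_finer(self, small_amp_staircase):
        runs = plateau_runs(small_amp_staircase)
        for ((n1, m1), v1), ((n2, m2), v2) in zip(runs, runs[1:]):
            if abs(n1 * m2 - n2 * m1) != 1:
                continue  # only Farey neighbours constrain the gap
            lo, hi = max(v1), min(v2)
            between = [
                (int(r["n"]), int(r["m"]))
                for _, r in small_amp_staircase.iterrows()
                if lo < r["H0_plus"] < hi
                and r["status"] == EntrainmentStatus.RATIONAL.value
            ]
            for n, m in between:
                if (n, m) in ((n1, m1), (n2, m2)):
                    continue
                assert m >= m1 + m2

    def test_plateau_width_grows_with_amplitude(self):
        base = preset("fig7_base")
        values = np.linspace(0.6, 0.8, 40)

        def width_11(amp):
            frame = staircase(values, dataclasses.replace(base, a=amp), **SCAN_ITER)
            cells = frame[
                (frame["status"] == EntrainmentStatus.RATIONAL.value)
                & (frame["n"] == 1)
                & (frame["m"] == 1)
            ]
            return len(cells)

        assert width_11(0.08) > width_11(0.02)


class TestPhaseRelationInsideTongue:
    def test_circadian_min_later_in_sleep_at_short_period_edge(self):
        base = preset("fig7_base")  # a = 0.08
        values = np.linspace(0.6, 0.8, 40)
        frame = staircase(values, base, **SCAN_ITER)
        locked = frame[
            (frame["status"] == EntrainmentStatus.RATIONAL.value)
            & (frame["n"] == 1)
            & (frame["m"] == 1)
        ]["H0_plus"].to_numpy()
        assert locked.size >= 6
        step = values[1] - values[0]
        h_short = locked.min() + step  # short natural period edge
        h_long = locked.max() - step  # long natural period edge

        def min_position(h0_plus):
            p = dataclasses.replace(base, H0_plus=h0_plus)
            r = simulate(p, horizon=60 * 24.0, transient=50 * 24.0)
            sleeps = [
                e for e in r.episodes
                if e.kind.value == "sleep" and e.t_start > r.transient_discarded
            ]
            e = sleeps[1]
            t_mid = 0.5 * (e.t_start + e.t_end)
            t_min = 12.0 + 24.0 * round((t_mid - 12.0) / 24.0)
            return (t_min - e.t_start) / e.duration

        assert min_position(h_short) > min_position(h_long)


class TestTongueScan:
    def test_small_grid_zero_amplitude_row_analytic(self, std_params):
        values = np.linspace(0.4, 0.9, 6)
        grid = tongue_scan("H0_plus", values, [0.0, 0.05], std_params, **SCAN_ITER)
        for j, v in enumerate(values):
            T_nat = natural_periods(
                dataclasses.replace(std_params, H0_plus=v)
            ).T_nat
            assert grid.T_nat_values[j] == pytest.approx(T_nat, abs=1e-12)
            assert grid.rho_matrix[0, j] == pytest.approx(
                std_params.T_f / T_nat, abs=1e-6
            )

    def test_invalid_sweep_values_skipped(self, std_params, caplog):
        # H0_plus below H0_minus violates ordering and must be skipped
        grid = tongue_scan(
            "H0_plus", [0.05, 0.6], [0.05], std_params, **SCAN_ITER
        )
        assert np.isnan(grid.rho_matrix[0, 0])
        assert grid.status_matrix[0, 0] is EntrainmentStatus.UNRESOLVED
        assert np.isfinite(grid.rho_matrix[0, 1])

    def test_unknown_sweep_param(self, std_params):
        with pytest.raises(ConfigurationError):
            tongue_scan("a", [0.1], [0.0], std_params)

    def test_long_frame_shape(self, std_params):
        grid = tongue_scan("H0_plus", [0.5, 0.7], [0.0, 0.05], std_params, **SCAN_ITER)
        frame = grid.to_long_frame()
        assert len(frame) == 4
        assert set(frame.columns) == {
            "sweep_param", "sweep_value", "T_nat_h", "amplitude", "rho", "status",
        }
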