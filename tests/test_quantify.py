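"""Band integration, dA ratios, internal-standard selection, calibration, run_mqa."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erf

from ramanmqa.core import AreaMap, HyperCube, PeakWindow, WavenumberAxis
from ramanmqa.errors import ConfigError, FitError, GridError, SelectionError, UsageError
from ramanmqa.phantom import (
    COMPARTMENTS,
    DEFAULT_CONCENTRATIONS,
    default_axis,
    make_cell_phantom,
)
from ramanmqa.quantify import (
    DEFAULT_METABOLITE_WINDOWS,
    INTERNAL_STANDARD_WINDOW,
    MqaConfig,
    compartment_stats,
    fit_calibration,
    integrate_peak,
    peak_area,
    ratio_map,
    run_mqa,
    select_internal_standard,
)


def gauss_area(center, sigma, lo, hi, amp=1.0):
    s = sigma * np.sqrt(2.0)
    return amp * sigma * np.sqrt(2 * np.pi) * 0.5 * (erf((hi - center) / s) - erf((lo - center) / s))


def _gauss_cube(center=484.0, sigma=3.0, amp=1.0, shape=(2, 2)):
    axis = default_axis()
    spec = amp * np.exp(-((axis.values - center) ** 2) / (2 * sigma**2))
    return HyperCube(axis, np.tile(spec, shape + (1,)))


class TestIntegratePeak:
    def test_gaussian_area_matches_erf_oracle(self):
        cube = _gauss_cube()
        amap = integrate_peak(cube, PeakWindow(484.0, 8.0))
        truth = gauss_area(484.0, 3.0, 476.0, 492.0)
        assert amap.values[0, 0] == pytest.approx(truth, rel=0.01)

    def test_zero_spectrum_has_zero_area(self):
        axis = default_axis()
        cube = HyperCube(axis, np.zeros((2, 2, len(axis))))
        amap = integrate_peak(cube, PeakWindow(1127.0, 8.0))
        assert not amap.values.any()

    def test_local_chord_baseline_removes_linear_background(self):
        axis = default_axis()
        x = axis.values
        peak = np.exp(-((x - 484.0) ** 2) / 18.0)
        line = 0.3 + 0.001 * x
        cube = HyperCube(axis, np.tile(peak + line, (1, 1, 1)))
        amap = integrate_peak(cube, PeakWindow(484.0, 8.0), local_baseline=True)
        # chord removes the linear background exactly, plus the peak's own
        # endpoint pedestal — include it in the closed form
        def g(v):
            return np.exp(-((v - 484.0) ** 2) / 18.0)

        truth = gauss_area(484.0, 3.0, 476.0, 492.0) - (g(476.0) + g(492.0)) / 2 * 16.0
        assert amap.values[0, 0] == pytest.approx(truth, rel=0.01)

    def test_window_outside_axis_is_a_config_error(self):
        cube = _gauss_cube()
        with pytest.raises(ConfigError):
            integrate_peak(cube, PeakWindow(3500.0, 8.0))

    def test_shipped_default_windows(self):
        centers = {name: w.center for name, w in DEFAULT_METABOLITE_WINDOWS.items()}
        assert centers == {
            "glycogen": 484.0,
            "nadh": 1114.0,
            "squalene": 1666.0,
            "lanosterol": 1643.0,
            "cholesterol": 1083.0,
            "glucose": 1127.0,
            "tryptophan": 1557.0,
        }
        assert all(w.half_width == 8.0 for w in DEFAULT_METABOLITE_WINDOWS.values())
        assert INTERNAL_STANDARD_WINDOW.center == 1341.0

    def test_peak_height_mode_reports_apex_intensity(self):
        cube = _gauss_cube(amp=2.5)
        amap = integrate_peak(cube, PeakWindow(484.0, 8.0), use_height=True)
        assert amap.values[0, 0] == pytest.approx(2.5, rel=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(min_value=-3.0, max_value=3.0),
        beta=st.floats(min_value=-3.0, max_value=3.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_integration_is_linear_in_intensity(self, alpha, beta, seed):
        axis = WavenumberAxis(np.arange(400.0, 600.0, 2.0))
        rng = np.random.default_rng(seed)
        a = rng.random((2, 2, len(axis)))
        b = rng.random((2, 2, len(axis)))
        window = PeakWindow(480.0, 8.0)
        area = lambda d: integrate_peak(HyperCube(axis, d), window).values
        np.testing.assert_allclose(
            area(alpha * a + beta * b), alpha * area(a) + beta * area(b),
            rtol=1e-9, atol=1e-12,
        )


class TestRatioMap:
    def _areas(self, num, den, valid=None):
        w = PeakWindow(1000.0, 8.0)
        v = np.ones(num.shape, bool) if valid is None else valid
        return AreaMap(w, num, v), AreaMap(w, den, v)

    def test_proportional_areas_give_constant_ratio(self):
        den = np.linspace(1, 5, 9).reshape(3, 3)
        num_map, den_map = self._areas(2 * den, den)
        rmap = ratio_map(num_map, den_map)
        np.testing.assert_allclose(rmap.values, 2.0)

    def test_per_pixel_gain_cancels_exactly(self, rng):
        axis = default_axis()
        base = rng.random((4, 4, len(axis))) + 0.5
        gain = rng.uniform(0.2, 5.0, size=(4, 4))
        w_num, w_den = PeakWindow(1127.0, 8.0), PeakWindow(1341.0, 8.0)

        def delta_a(data):
            return ratio_map(
                integrate_peak(HyperCube(axis, data), w_num),
                integrate_peak(HyperCube(axis, data), w_den),
            ).values

        np.testing.assert_allclose(
            delta_a(gain[..., None] * base), delta_a(base), rtol=1e-12
        )

    def test_zero_denominator_pixel_is_invalid(self):
        den = np.ones((2, 2))
        den[0, 1] = 0.0
        num_map, den_map = self._areas(np.ones((2, 2)), den)
        rmap = ratio_map(num_map, den_map)
        assert not rmap.valid[0, 1] and rmap.valid[0, 0]
        assert np.isnan(rmap.values[0, 1])

    def test_negative_numerator_is_valid_but_flagged(self):
        num = np.ones((2, 2))
        num[1, 0] = -0.5
        num_map, den_map = self._areas(num, np.ones((2, 2)))
        rmap = ratio_map(num_map, den_map)
        assert rmap.valid[1, 0] and rmap.negative[1, 0]
        assert rmap.values[1, 0] == -0.5

    def test_grid_mismatch_raises(self):
        a, _ = self._areas(np.ones((2, 2)), np.ones((2, 2)))
        _, b = self._areas(np.ones((3, 3)), np.ones((3, 3)))
        with pytest.raises(GridError):
            ratio_map(a, b)


class TestInternalStandardSelection:
    def test_uniform_candidates_tie_break_to_lowest_center(self):
        axis = default_axis()
        cube = HyperCube(axis, np.ones((3, 3, len(axis))))
        cands = [PeakWindow(900.0, 8.0, "b"), PeakWindow(600.0, 8.0, "a")]
        chosen, ranking = select_internal_standard(cube, cands)
        assert chosen.center == 600.0
        assert len(ranking) == 2

    def test_ranking_excludes_disqualified_candidates(self):
        axis = default_axis()
        data = np.ones((3, 3, len(axis)))
        sel = np.abs(axis.values - 700.0) <= 20
        data[..., sel] = -1.0  # negative mean area -> disqualified
        cube = HyperCube(axis, data)
        cands = [PeakWindow(700.0, 8.0, "neg"), PeakWindow(900.0, 8.0, "ok")]
        chosen, ranking = select_internal_standard(cube, cands)
        assert chosen.label == "ok"
        assert len(ranking) == 1

    def test_all_disqualified_raises(self):
        axis = default_axis()
        cube = HyperCube(axis, -np.ones((3, 3, len(axis))))
        with pytest.raises(SelectionError):
            select_internal_standard(cube, [PeakWindow(700.0, 8.0)])

    def test_constant_threonine_field_wins_on_the_phantom(self, preprocessed_phantom):
        cube, truth, _ = preprocessed_phantom
        candidates = [INTERNAL_STANDARD_WINDOW] + list(DEFAULT_METABOLITE_WINDOWS.values())
        chosen, ranking = select_internal_standard(cube, candidates, truth.cell_mask)
        assert chosen.center == 1341.0
        assert ranking.iloc[0]["cv"] < ranking.iloc[1]["cv"]


class TestCompartmentStats:
    def _ratio(self, values, valid=None):
        w = PeakWindow(1000.0, 8.0)
        v = np.ones(values.shape, bool) if valid is None else valid
        return __import__("ramanmqa").core.RatioMap(w, w, values, v)

    def test_constant_compartment_has_zero_sd(self):
        values = np.full((4, 4), 3.25)
        labels = np.zeros((4, 4), int)
        table = compartment_stats(self._ratio(values), labels, "g1")
        row = table.iloc[0]
        assert (row["mean"], row["sd"], row["n"], row["group"]) == (3.25, 0.0, 16, "g1")

    def test_gaussian_field_mean_matches_sampling_oracle(self, rng):
        mu, sigma, n = 2.0, 0.3, 100 * 100
        values = rng.normal(mu, sigma, size=(100, 100))
        table = compartment_stats(self._ratio(values), np.zeros((100, 100), int))
        assert abs(table.iloc[0]["mean"] - mu) < 3 * sigma / np.sqrt(n)

    def test_invalid_pixels_reduce_n_but_not_the_mean(self):
        values = np.array([[1.0, 1.0], [1.0, 99.0]])
        valid = np.array([[True, True], [True, False]])
        table = compartment_stats(self._ratio(values, valid), np.zeros((2, 2), int))
        assert table.iloc[0]["n"] == 3 and table.iloc[0]["mean"] == 1.0

    def test_empty_label_row_is_omitted_with_warning(self):
        values = np.ones((2, 2))
        valid = np.array([[True, True], [False, False]])
        labels = np.array([[0, 0], [1, 1]])
        with pytest.warns(UserWarning, match="no valid pixels"):
            table = compartment_stats(self._ratio(values, valid), labels)
        assert list(table["label"]) == [0]

    def test_boolean_mask_labels(self):
        values = np.arange(4.0).reshape(2, 2)
        mask = np.array([[True, False], [True, False]])
        table = compartment_stats(self._ratio(values), mask)
        assert table.iloc[0]["n"] == 2 and table.iloc[0]["mean"] == 1.0


class TestCalibrationFit:
    def test_exact_line_is_recovered(self):
        pairs = [(c, 0.5 * c + 0.1) for c in (1.0, 2.0, 3.0, 4.0, 5.0)]
        fit = fit_calibration(pairs)
        assert fit.slope == pytest.approx(0.5, rel=1e-12)
        assert fit.intercept == pytest.approx(0.1, rel=1e-10)
        assert fit.r_squared == 1.0
        assert fit.n_points == 5

    def test_single_distinct_concentration_raises(self):
        with pytest.raises(FitError):
            fit_calibration([(2.0, 1.0), (2.0, 1.1), (2.0, 0.9)])

    def test_too_few_points_raises(self):
        with pytest.raises(FitError):
            fit_calibration([(1.0, 1.0), (2.0, 2.0)])


class TestRunMqa:
    def test_compartment_means_track_concentration_ratios(self, default_phantom):
        """End-to-end semi-quantitative contract on the default phantom.

        For every quantified metabolite, per-compartment mean dA must match
        the true concentration-to-internal-standard ratios within 10% after
        fitting one global per-metabolite factor.
        """
        cube, truth = default_phantom
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = run_mqa(cube, MqaConfig(seed=42))
        lab_true, lab = truth.labels(), result.cluster.labels
        mapping = {}
        for cl in range(5):
            vals, cnt = np.unique(lab_true[(lab == cl) & (lab_true >= 0)], return_counts=True)
            mapping[cl] = COMPARTMENTS[vals[np.argmax(cnt)]]
        assert len(set(mapping.values())) == 5  # clusters == compartments
        for met in result.ratios:
            sub = result.stats[result.stats.metabolite == met]
            meas = {mapping[int(r.compartment)]: r.mean for r in sub.itertuples()}
            mv = np.array([meas[c] for c in COMPARTMENTS])
            tv = np.array(
                [
                    DEFAULT_CONCENTRATIONS[met][c] / DEFAULT_CONCENTRATIONS["threonine"][c]
                    for c in COMPARTMENTS
                ]
            )
            factor = (mv @ tv) / (tv @ tv)
            rel = np.abs(mv - factor * tv) / (factor * tv)
            assert rel.max() < 0.10, f"{met}: {rel}"

    def test_missing_windows_is_a_usage_error(self, small_phantom):
        cube, _ = small_phantom
        with pytest.raises(UsageError):
            run_mqa(cube, MqaConfig(windows={}))

    def test_group_tags_flow_into_cross_group_tables(self):
        import pandas as pd

        tables = []
        for tag, frac in (("InS", 1.0), ("D10w", 0.2)):
            cube, _ = make_cell_phantom(shape=(24, 24), seed=5, symbiont_fraction=frac)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = run_mqa(
                    cube,
                    MqaConfig(
                        windows={"cholesterol": DEFAULT_METABOLITE_WINDOWS["cholesterol"]},
                        k=5, seed=5, group_tag=tag,
                    ),
                )
            tables.append(res.stats)
        combined = pd.concat(tables, ignore_index=True)
        assert set(combined["group"]) == {"InS", "D10w"}

    def test_monotone_recovery_in_true_concentration(self):
        """Raising one compartment's true concentration never lowers its mean dA."""
        levels = (0.5, 1.0, 1.5, 2.0, 2.5)
        means = []
        for level in levels:
            conc = {met: dict(per) for met, per in DEFAULT_CONCENTRATIONS.items()}
            conc["glycogen"]["symbiont_a"] = level
            cube, truth = make_cell_phantom(
                shape=(32, 32), seed=11, snr=200.0, concentrations=conc,
                baseline_amplitude=0.0, n_spikes=0,
            )
            amap = integrate_peak(cube, DEFAULT_METABOLITE_WINDOWS["glycogen"])
            den = integrate_peak(cube, INTERNAL_STANDARD_WINDOW)
            rmap = ratio_map(amap, den)
            sel = truth.masks["symbiont_a"] & rmap.valid
            means.append(float(rmap.values[sel].mean()))
        assert all(b >= a for a, b in zip(means, means[1:]))
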