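"""Plate normalisation and log-logistic IC50 fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbsynergy import synthdata
from nbsynergy.doseresponse import (
    LogLogisticModel,
    NormalizedResponse,
    PlateError,
    ViabilityPlate,
    Well,
    estimate_ic50,
    fit_normalized_logistic,
    normalize_plate,
)


def plate_from(wells):
    return ViabilityPlate(wells=[Well(*w) for w in wells])


class TestNormalizePlate:
    @pytest.mark.parametrize(
        "wells, dose, expected",
        [
            # vehicle OD 1.0, treated 0.5, no blank -> 50%
            ([(0, 1.0, 0, "vehicle"), (10, 0.5, 0, "treated")], 10, 50.0),
            # treated equals vehicle -> 100%
            ([(0, 1.0, 0, "vehicle"), (10, 1.0, 0, "treated")], 10, 100.0),
            # blank subtraction: (0.7-0.2)/(1.2-0.2) -> 50%
            (
                [
                    (0, 1.2, 0, "vehicle"),
                    (0, 0.2, 0, "blank"),
                    (10, 0.7, 0, "treated"),
                ],
                10,
                50.0,
            ),
        ],
    )
    def test_ratio_definition(self, wells, dose, expected):
        points = normalize_plate(plate_from(wells))
        by_dose = {p.dose: p for p in points}
        assert by_dose[dose].response == pytest.approx(expected)

    def test_vehicle_anchor_is_exactly_100(self, clean_plate):
        points = normalize_plate(clean_plate)
        assert points[0].dose == 0.0
        assert points[0].response == 100.0

    def test_no_vehicle_is_hard_error(self):
        with pytest.raises(PlateError):
            normalize_plate(plate_from([(10, 0.5, 0, "treated")]))

    def test_degenerate_vehicle_below_blank(self):
        with pytest.raises(PlateError, match="degenerate"):
            normalize_plate(
                plate_from(
                    [(0, 0.1, 0, "vehicle"), (0, 0.5, 0, "blank"), (10, 0.3, 0, "treated")]
                )
            )

    def test_dose_zero_treated_wells_join_vehicle_pool(self):
        points = normalize_plate(
            plate_from(
                [(0, 1.0, 0, "vehicle"), (0, 1.2, 1, "treated"), (10, 0.55, 0, "treated")]
            )
        )
        # vehicle mean is (1.0 + 1.2)/2 = 1.1
        assert {p.dose: p.response for p in points}[10] == pytest.approx(50.0)

    def test_sem_over_replicates(self):
        points = normalize_plate(
            plate_from(
                [(0, 1.0, 0, "vehicle"), (10, 0.4, 0, "treated"), (10, 0.6, 1, "treated")]
            )
        )
        p10 = {p.dose: p for p in points}[10]
        assert p10.n_replicates == 2
        assert p10.sem == pytest.approx(np.std([40, 60], ddof=1) / np.sqrt(2))

    @given(scale=st.floats(min_value=0.01, max_value=100))
    @settings(deadline=None, max_examples=25)
    def test_scale_invariance(self, scale):
        wells = [(0, 1.0, 0, "vehicle"), (1, 0.8, 0, "treated"), (10, 0.3, 0, "treated")]
        base = normalize_plate(plate_from(wells))
        scaled = normalize_plate(
            plate_from([(d, od * scale, r, role) for d, od, r, role in wells])
        )
        for a, b in zip(base, scaled):
            assert b.response == pytest.approx(a.response, rel=1e-9)


def points_from_model(ic50, hill, doses):
    resp = 100.0 / (1.0 + (np.asarray(doses) / ic50) ** hill)
    pts = [NormalizedResponse(0.0, 100.0, 3, 0.0)]
    pts += [NormalizedResponse(d, r, 3, 0.0) for d, r in zip(doses, resp)]
    return pts


class TestLogisticFit:
    DOSES = 10 ** np.linspace(-0.5, 3.5, 7)

    @pytest.mark.parametrize("ic50, hill", [(100.0, 1.0), (50.0, 2.0), (200.0, 0.5)])
    def test_noiseless_recovery(self, ic50, hill):
        fit = fit_normalized_logistic(points_from_model(ic50, hill, self.DOSES))
        assert fit.converged
        assert fit.ic50 == pytest.approx(ic50, rel=1e-6)
        assert fit.hill_slope == pytest.approx(hill, rel=1e-6)

    def test_midpoint_response_is_50(self, clean_points):
        fit = fit_normalized_logistic(clean_points)
        assert fit.predict(fit.ic50) == pytest.approx(50.0, abs=1e-9)

    def test_fixed_slope_mode(self):
        fit = fit_normalized_logistic(
            points_from_model(100.0, 1.0, self.DOSES), variable_slope=False
        )
        assert fit.hill_slope == 1.0
        assert fit.ic50 == pytest.approx(100.0, rel=1e-6)

    def test_too_few_doses_is_hard_error(self):
        pts = points_from_model(100.0, 1.0, [10.0, 100.0, 1000.0])
        with pytest.raises(ValueError, match="distinct nonzero doses"):
            fit_normalized_logistic(pts, variable_slope=True)
        # three distinct doses are enough for the fixed-slope model
        assert fit_normalized_logistic(pts, variable_slope=False).converged

    def test_flat_responses_do_not_converge(self):
        pts = [NormalizedResponse(d, 80.0, 3, 0.0) for d in self.DOSES]
        fit = fit_normalized_logistic(pts)
        assert not fit.converged

    def test_sse_beats_grid_oracle(self):
        """Brute-force oracle: the optimiser's SSE is <= the best SSE on a
        dense parameter grid within the search bounds."""
        rng = np.random.default_rng(7)
        doses = self.DOSES
        resp = 100.0 / (1.0 + (doses / 80.0) ** 1.3) + rng.normal(0, 3, len(doses))
        pts = [NormalizedResponse(d, r, 1, 0.0) for d, r in zip(doses, resp)]
        fit = fit_normalized_logistic(pts)
        (llo, lhi), (hlo, hhi) = fit.bounds
        grid_l = np.linspace(llo, lhi, 200)
        grid_h = np.linspace(hlo, hhi, 200)
        u = 10.0 ** (
            (np.log10(doses)[None, None, :] - grid_l[:, None, None])
            * grid_h[None, :, None]
        )
        sse = (((100.0 / (1.0 + u)) - resp[None, None, :]) ** 2).sum(axis=2)
        assert fit.sse <= sse.min() + 1e-9

    def test_monotone_decreasing_for_positive_hill(self, clean_points):
        fit = fit_normalized_logistic(clean_points)
        doses = np.linspace(0.1, 5000, 500)
        pred = fit.predict(doses)
        assert np.all(np.diff(pred) < 0)

    def test_parameter_recovery_under_noise(self):
        """Median relative IC50 error < 5% over 100 noisy plates."""
        errors = []
        for i, hill in zip(range(100), [0.5, 1.0, 2.0] * 34):
            plate = synthdata.gen_viability_plate(
                seed=200 + i, ic50=100.0, hill=hill, noise_sd=2.0
            )
            res = LogLogisticModel.from_plate(plate).fit()
            errors.append(abs(res.ic50 - 100.0) / 100.0)
        assert np.median(errors) < 0.05


class TestEstimateIC50:
    def test_no_bootstrap_collapses_interval(self, clean_points):
        est = estimate_ic50(clean_points, n_boot=0, seed=0)
        assert est.ci_low == est.ic50 == est.ci_high

    def test_same_seed_identical_intervals(self):
        plate = synthdata.gen_viability_plate(seed=9, ic50=100.0, noise_sd=2.0)
        from nbsynergy.doseresponse import normalize_plate

        pts = normalize_plate(plate)
        a = estimate_ic50(pts, n_boot=200, seed=42)
        b = estimate_ic50(pts, n_boot=200, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_interval_brackets_point_estimate(self):
        plate = synthdata.gen_viability_plate(seed=10, ic50=100.0, noise_sd=3.0)
        from nbsynergy.doseresponse import normalize_plate

        est = estimate_ic50(normalize_plate(plate), n_boot=200, seed=0)
        assert est.ci_low <= est.ic50 <= est.ci_high

    def test_negative_n_boot_rejected(self, clean_points):
        with pytest.raises(ValueError):
            estimate_ic50(clean_points, n_boot=-1, seed=0)
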