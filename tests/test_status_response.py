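"""Status-response model: calibration-grid fidelity and parametric backend."""

import io
import warnings

import pytest
from hypothesis import given
from hypothesis import strategies as st

from vitd_rct import StatusResponseModel, UnsupportedDoseError, UnsupportedOperationError
from vitd_rct.status_response import (
    CALIBRATION_DOSES,
    DEFAULT_DECILE_BASELINES,
    CalibrationWarning,
    _DEFAULT_ACHIEVED_GRID,
)

GRID_CELLS = [
    (b, d, _DEFAULT_ACHIEVED_GRID[i][j])
    for i, b in enumerate(DEFAULT_DECILE_BASELINES)
    for j, d in enumerate(CALIBRATION_DOSES)
]


class TestCalibrationBackend:
    @pytest.mark.parametrize("baseline, dose, achieved", GRID_CELLS)
    def test_grid_fidelity_at_every_cell(self, calibration_model, baseline, dose, achieved):
        assert calibration_model.achieved(baseline, dose) == achieved

    def test_published_spot_checks(self, calibration_model):
        assert calibration_model.achieved(14, 2000) == 33
        assert calibration_model.achieved(11, 4000) == 45

    def test_zero_dose_identity(self, calibration_model):
        assert calibration_model.achieved(23.0, 0.0) == 23.0
        assert calibration_model.achieved(7.5, 0.0) == 7.5

    def test_bilinear_interpolation_between_grid_doses(self, calibration_model):
        # Halfway between 1000 IU/d (24) and 2000 IU/d (33) at baseline 14.
        assert calibration_model.achieved(14, 1500) == pytest.approx((24 + 33) / 2)
        # Halfway between baselines 14 and 17 at 2000 IU/d: (33 + 35) / 2.
        assert calibration_model.achieved(15.5, 2000) == pytest.approx(34.0)

    def test_flat_clamp_outside_grid(self, calibration_model):
        assert calibration_model.achieved(40, 8000) == calibration_model.achieved(40, 4000)
        assert calibration_model.achieved(60, 2000) == calibration_model.achieved(40, 2000)

    def test_off_grid_query_with_interpolation_disabled(self, calibration_model):
        with pytest.raises(UnsupportedDoseError):
            calibration_model.achieved(14, 1500, interpolate=False)
        assert calibration_model.achieved(14, 1000, interpolate=False) == 24

    def test_negative_dose_rejected(self, calibration_model):
        with pytest.raises(ValueError):
            calibration_model.achieved(14, -100)

    def test_increment_unsupported(self, calibration_model):
        with pytest.raises(UnsupportedOperationError):
            calibration_model.increment_per_1000IU(20.0)

    def test_non_monotone_grid_cell_warns(self):
        # The stored grid's 400 IU/d column drops from 25 (baseline 11)
        # to 18 (baseline 14); construction flags it but keeps it verbatim.
        with pytest.warns(CalibrationWarning, match="400"):
            model = StatusResponseModel()
        assert model.achieved(11, 400) == 25
        assert model.achieved(14, 400) == 18

    def test_csv_round_trip(self, calibration_model):
        buf = io.StringIO()
        calibration_model.to_csv(buf)
        buf.seek(0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CalibrationWarning)
            loaded = StatusResponseModel.from_csv(buf)
        assert loaded == calibration_model


class TestParametricBackend:
    @pytest.mark.parametrize("concentration, rise", [(0.0, 13.0), (28.0, 4.0), (140.0, 2.0)])
    def test_increment_passes_through_anchors(self, parametric_model, concentration, rise):
        assert parametric_model.increment_per_1000IU(concentration) == pytest.approx(
            rise, abs=1e-9
        )

    def test_increment_non_increasing(self, parametric_model):
        grid = [parametric_model.increment_per_1000IU(c) for c in range(0, 200, 5)]
        assert all(a >= b for a, b in zip(grid, grid[1:]))
        assert all(g > 0 for g in grid)

    def test_zero_dose_identity(self, parametric_model):
        assert parametric_model.achieved(23.0, 0.0) == 23.0

    @given(
        baseline=st.floats(min_value=1.0, max_value=60.0),
        dose=st.floats(min_value=0.0, max_value=6000.0),
        extra=st.floats(min_value=10.0, max_value=2000.0),
    )
    def test_achieved_increasing_in_dose_and_above_baseline(
        self, parametric_model, baseline, dose, extra
    ):
        a0 = parametric_model.achieved(baseline, dose)
        a1 = parametric_model.achieved(baseline, dose + extra)
        assert a0 >= baseline
        assert a1 > a0

    @given(
        b1=st.floats(min_value=1.0, max_value=50.0),
        gap=st.floats(min_value=0.5, max_value=30.0),
        dose=st.floats(min_value=0.0, max_value=5000.0),
    )
    def test_achieved_increasing_in_baseline(self, parametric_model, b1, gap, dose):
        assert parametric_model.achieved(b1 + gap, dose) > parametric_model.achieved(b1, dose)

    def test_sequential_dosing_is_additive(self, parametric_model):
        one_pass = parametric_model.achieved(14.0, 2000.0)
        midway = parametric_model.achieved(14.0, 1000.0)
        two_pass = parametric_model.achieved(midway, 1000.0)
        assert two_pass == pytest.approx(one_pass, abs=1e-6)

    def test_diminishing_increment_per_added_1000IU(self, parametric_model):
        # The rise from each additional 1000 IU/d shrinks as the
        # concentration climbs.
        levels = [parametric_model.achieved(14.0, d) for d in (0, 1000, 2000, 3000, 4000)]
        rises = [b - a for a, b in zip(levels, levels[1:])]
        assert all(r2 < r1 for r1, r2 in zip(rises, rises[1:]))

    def test_bad_anchor_sets_rejected(self):
        with pytest.raises(ValueError):
            StatusResponseModel(
                StatusResponseModel.PARAMETRIC, anchors=[(0, 13), (28, 4)]
            )
        with pytest.raises(ValueError):
            StatusResponseModel(
                StatusResponseModel.PARAMETRIC, anchors=[(0, 2), (28, 4), (140, 13)]
            )
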