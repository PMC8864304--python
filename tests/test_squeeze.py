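"""Squeezing algebra: residual floors, pro-rata scaling, crisis capping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from csmf519.predict import CSMFDraws
from csmf519.squeeze import (
    apply_crisis,
    residuals_from_vr,
    single_cause_fraction,
    squeeze_lri,
    squeeze_other_cmpn,
)
from csmf519.taxonomy import AgeSexGroup
from csmf519.types import ValidationError

G = AgeSexGroup.AGE_5_9


def _vr_frame(fractions_by_cause, group=G):
    rows = []
    for cause, values in fractions_by_cause.items():
        for i, v in enumerate(values):
            rows.append(
                {"iso_code": f"H{i}", "year": 2010, "group": group.value,
                 "cause": cause, "fraction": v}
            )
    return pd.DataFrame(rows)


class TestResiduals:
    def test_identical_fractions_give_that_value(self):
        vr = _vr_frame({"lri": [0.04] * 5, "other_cmpn": [0.1] * 5})
        res = residuals_from_vr(vr, G)
        assert res.residual_lri == 0.04
        assert res.residual_other_cmpn == 0.1

    def test_median_of_three(self):
        vr = _vr_frame({"lri": [0.01, 0.02, 0.03], "other_cmpn": [0.2, 0.1, 0.3]})
        res = residuals_from_vr(vr, G)
        assert res.residual_lri == 0.02
        assert res.residual_other_cmpn == 0.2

    def test_matches_sort_based_median_oracle(self, rng):
        vals = rng.uniform(0, 0.3, size=9)
        vr = _vr_frame({"lri": vals, "other_cmpn": vals})
        s = np.sort(vals)
        assert residuals_from_vr(vr, G).residual_lri == pytest.approx(s[4])

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValidationError):
            residuals_from_vr(_vr_frame({}), G)


class TestSingleCauseFraction:
    def test_basic_ratio(self):
        assert single_cause_fraction(50.0, 1000.0) == pytest.approx(0.05)

    def test_exceeding_envelope_truncates_to_one(self):
        assert single_cause_fraction(1200.0, 1000.0) == 1.0

    def test_zero_envelope_with_deaths_is_an_error(self):
        with pytest.raises(ValidationError):
            single_cause_fraction(5.0, 0.0)
        assert single_cause_fraction(0.0, 0.0) == 0.0


class TestSqueezeOtherCmpn:
    def test_room_available_passes_singles_unchanged(self):
        out = squeeze_other_cmpn(0.30, 0.05, 0.03, 0.02, 0.10)
        assert out["hiv"] == pytest.approx(0.05)
        assert out["measles_endemic"] == pytest.approx(0.03)
        assert out["tb_extrapulmonary"] == pytest.approx(0.02)
        assert out["other_cmpn_final"] == pytest.approx(0.20)

    def test_singles_scaled_pro_rata_when_room_exceeded(self):
        out = squeeze_other_cmpn(0.30, 0.15, 0.06, 0.04, 0.10)
        assert out["hiv"] == pytest.approx(0.12)
        assert out["measles_endemic"] == pytest.approx(0.048)
        assert out["tb_extrapulmonary"] == pytest.approx(0.032)
        assert out["other_cmpn_final"] == pytest.approx(0.10)

    def test_zero_singles_leave_composite_whole(self):
        out = squeeze_other_cmpn(0.25, 0.0, 0.0, 0.0, 0.1)
        assert out["other_cmpn_final"] == pytest.approx(0.25)

    def test_negative_input_is_an_error(self):
        with pytest.raises(ValidationError):
            squeeze_other_cmpn(0.3, -0.01, 0.0, 0.0, 0.1)

    @given(
        m=st.floats(min_value=0, max_value=1),
        h=st.floats(min_value=0, max_value=1),
        me=st.floats(min_value=0, max_value=1),
        tb=st.floats(min_value=0, max_value=1),
        res=st.floats(min_value=0, max_value=1),
    )
    def test_partition_sums_exactly_and_floor_holds(self, m, h, me, tb, res):
        out = squeeze_other_cmpn(m, h, me, tb, res)
        total = (
            out["hiv"] + out["measles_endemic"] + out["tb_extrapulmonary"]
            + out["other_cmpn_final"]
        )
        assert total == pytest.approx(m, abs=1e-12)
        assert out["other_cmpn_final"] >= min(res, m) - 1e-12


class TestSqueezeLri:
    def test_tb_fits_inside_available_room(self):
        out = squeeze_lri(0.10, 0.03, 0.04)
        assert out["tb_pulmonary"] == pytest.approx(0.03)
        assert out["lri_final"] == pytest.approx(0.07)

    def test_tb_truncated_to_available_room(self):
        out = squeeze_lri(0.10, 0.09, 0.04)
        assert out["tb_pulmonary"] == pytest.approx(0.06)
        assert out["lri_final"] == pytest.approx(0.04)

    def test_zero_tb_identity(self):
        assert squeeze_lri(0.10, 0.0, 0.04)["lri_final"] == pytest.approx(0.10)

    @given(
        m=st.floats(min_value=0, max_value=1),
        tb=st.floats(min_value=0, max_value=1),
        res=st.floats(min_value=0, max_value=1),
    )
    def test_partition_and_floor(self, m, tb, res):
        out = squeeze_lri(m, tb, res)
        assert out["tb_pulmonary"] + out["lri_final"] == pytest.approx(m, abs=1e-12)
        assert out["lri_final"] >= min(res, m) - 1e-12


class TestApplyCrisis:
    CAUSES = ("malaria", "collective_violence", "other_cmpn")

    def _cell(self, fractions):
        return CSMFDraws("X", 2014, G, self.CAUSES, np.atleast_2d(fractions))

    def test_raw_above_cap_is_capped_and_others_scaled(self):
        out, scale = apply_crisis(
            self._cell([0.5, 0.0, 0.5]), 0.9, 0.3, "collective_violence"
        )
        np.testing.assert_allclose(out.draws[0], [0.35, 0.3, 0.35], atol=1e-12)
        np.testing.assert_allclose(scale, 1.0)

    def test_zero_crisis_is_identity(self):
        out, scale = apply_crisis(
            self._cell([0.5, 0.0, 0.5]), 0.0, 0.3, "collective_violence"
        )
        np.testing.assert_allclose(out.draws[0], [0.5, 0.0, 0.5], atol=1e-15)

    def test_cap_above_raw_uses_raw(self):
        out, _ = apply_crisis(
            self._cell([0.5, 0.0, 0.5]), 0.1, 0.3, "collective_violence"
        )
        np.testing.assert_allclose(out.draws[0], [0.45, 0.1, 0.45], atol=1e-12)

    def test_unknown_nature_is_an_error(self):
        with pytest.raises(ValidationError, match="nature"):
            apply_crisis(self._cell([0.5, 0.0, 0.5]), 0.1, 0.3, "asteroid")

    def test_out_of_envelope_crisis_grows_envelope_and_keeps_simplex(self):
        out, scale = apply_crisis(
            self._cell([0.6, 0.0, 0.4]), 0.25, 0.5, "collective_violence",
            in_envelope=False,
        )
        np.testing.assert_allclose(scale, 1.25)
        np.testing.assert_allclose(out.draws.sum(axis=1), 1.0, atol=1e-12)
        # non-crisis causes keep their share of the *original* envelope
        np.testing.assert_allclose(out.draws[0][0] * 1.25, 0.6, atol=1e-12)
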