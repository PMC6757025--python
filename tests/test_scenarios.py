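"""Atrophy-schedule construction and evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atrophyfem.mechanics import DomainError
from atrophyfem.scenarios import (AtrophySchedule, RegionEntry, focal_schedule,
                                  generalized_schedule, upsilon_at,
                                  upsilon_field)


class TestGeneralized:
    def test_default_endpoints_exact(self):
        s = generalized_schedule()
        assert upsilon_at(s, 48.0, "gray") == pytest.approx(0.80, abs=1e-12)
        assert upsilon_at(s, 48.0, "white") == pytest.approx(0.90, abs=1e-12)

    def test_start_is_unity(self):
        s = generalized_schedule()
        assert upsilon_at(s, 0.0, "gray") == 1.0
        assert upsilon_at(s, 0.0, "white") == 1.0

    def test_rate_mode_linear_accumulation(self):
        s = generalized_schedule(stepping="rate")
        # −0.4 %/month over 48 months: 1 − 0.192 = 0.808 (≠ endpoint 0.80)
        assert upsilon_at(s, 48.0, "gray") == pytest.approx(0.808, abs=1e-12)
        assert upsilon_at(s, 48.0, "white") == pytest.approx(0.904, abs=1e-12)

    def test_geometric_midpoint(self):
        s = generalized_schedule()
        assert upsilon_at(s, 24.0, "gray") == pytest.approx(np.sqrt(0.80), abs=1e-12)

    def test_rate_reaching_zero_rejected(self):
        with pytest.raises(DomainError):
            generalized_schedule(stepping="rate", rate_gray=-0.03,
                                 duration=48.0)


class TestFocal:
    def test_focal_gray(self):
        s = focal_schedule("gray", -0.50)
        assert upsilon_at(s, 48.0, "gray") == pytest.approx(0.5)
        assert upsilon_at(s, 48.0, "white") == 1.0

    def test_focal_white(self):
        s = focal_schedule("white", -0.25)
        assert upsilon_at(s, 48.0, "white") == pytest.approx(0.75)
        assert upsilon_at(s, 48.0, "gray") == 1.0

    def test_zero_delta_constant(self):
        s = focal_schedule("gray", 0.0)
        for t in (0.0, 10.0, 48.0):
            assert upsilon_at(s, t, "gray") == 1.0

    def test_unknown_region_listed(self):
        with pytest.raises(KeyError, match="hippocampus"):
            focal_schedule("hippocampus", -0.3,
                           available_regions=("gray", "white", "deep-gray"))


class TestUpsilonAt:
    def test_outside_span_rejected(self):
        s = generalized_schedule()
        with pytest.raises(DomainError):
            upsilon_at(s, -1.0, "gray")
        with pytest.raises(DomainError):
            upsilon_at(s, 49.0, "gray")

    def test_unscheduled_region_defaults_to_one(self):
        s = focal_schedule("gray", -0.5)
        assert upsilon_at(s, 30.0, "callosal-band") == 1.0

    @settings(deadline=None, max_examples=50)
    @given(t1=st.floats(0.0, 48.0), t2=st.floats(0.0, 48.0),
           stepping=st.sampled_from(["endpoint", "rate"]))
    def test_monotone_non_increasing(self, t1, t2, stepping):
        s = generalized_schedule(stepping=stepping)
        lo, hi = min(t1, t2), max(t1, t2)
        for region in ("gray", "white"):
            assert upsilon_at(s, hi, region) <= upsilon_at(s, lo, region) + 1e-12

    @pytest.mark.parametrize("n", [1, 7, 48])
    def test_endpoint_invariant_to_increment_count(self, n):
        s = generalized_schedule(n_increments=n)
        assert s.times[-1] == pytest.approx(48.0)
        assert upsilon_at(s, s.times[-1], "gray") == pytest.approx(0.80, abs=1e-12)


class TestUpsilonField:
    def test_subregion_shadows_tissue(self, coronal_coarse):
        sched = AtrophySchedule(
            mode="focal", stepping="endpoint", duration=12.0, n_increments=4,
            entries=(RegionEntry("gray", endpoint=0.9),
                     RegionEntry("deep-gray", endpoint=0.6)))
        ups = upsilon_field(sched, coronal_coarse, 12.0)
        deep = coronal_coarse.element_subregion == "deep-gray"
        cortical = ((coronal_coarse.element_region == "gray") & ~deep)
        assert np.allclose(ups[deep], 0.6)
        assert np.allclose(ups[cortical], 0.9)
        assert np.allclose(ups[coronal_coarse.element_region == "white"], 1.0)

    def test_generalized_field_values(self, coronal_coarse):
        ups = upsilon_field(generalized_schedule(), coronal_coarse, 48.0)
        assert np.allclose(ups[coronal_coarse.element_region == "gray"], 0.80)
        assert np.allclose(ups[coronal_coarse.element_region == "white"], 0.90)


def test_schedule_validation():
    with pytest.raises(DomainError):
        AtrophySchedule("generalized", "endpoint", duration=-1.0, n_increments=4)
    with pytest.raises(DomainError):
        AtrophySchedule("generalized", "endpoint", duration=10.0, n_increments=0)
    with pytest.raises(DomainError):
        AtrophySchedule("generalized", "endpoint", duration=10.0, n_increments=2,
                        entries=(RegionEntry("gray", endpoint=1.5),))
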