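"""Partitioning of measured fractions into suspended/slow/fast pools."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mscflux import (
    AmbiguousTrayError,
    MissingMeasurementError,
    MSCGeometry,
    ValidationError,
    fast_concentration,
    partition,
    slow_concentration,
    suspended_concentration,
)
from mscflux import MSCDeployment
from mscflux.geometry import DEFAULT_GEOMETRY


def _dep(**overrides):
    """Module-level deployment factory for hypothesis-driven tests."""
    kwargs = dict(
        cruise="DY111", station="TS", occupation="1", deployment_id="TS-1-0001",
        depth_m=60.0, substance="POC", p_top=1.0, p_base=2.0, p_tray=10.0,
    )
    kwargs.update(overrides)
    return MSCDeployment(**kwargs)


class TestGeometry:
    def test_cross_section_derived_as_cylinder(self):
        assert DEFAULT_GEOMETRY.a_msc_m2 == pytest.approx(95 / 1580, rel=1e-12)

    def test_slow_flux_factor_reduces_to_height_over_settling_time(self, geom):
        assert geom.slow_flux_factor == pytest.approx(geom.h_m / geom.t_settle_d, rel=1e-12)

    @pytest.mark.parametrize(
        "bad",
        [
            {"v_msc_l": -1.0},
            {"v_base_l": 100.0},           # base larger than catcher
            {"v_tray_l": 9.0},             # tray larger than base
            {"a_msc_m2": 0.1},             # inconsistent with v_msc/h
            {"t_settle_h": 0.0},
        ],
    )
    def test_invalid_geometry_rejected(self, bad):
        with pytest.raises(ValidationError):
            MSCGeometry(**bad)

    def test_from_config_rejects_unknown_keys(self):
        with pytest.raises(ValidationError, match="unknown geometry"):
            MSCGeometry.from_config({"v_msc_litres": 95})


class TestSuspended:
    @pytest.mark.parametrize(
        "p_top, substance, expected",
        [(1.0, "POC", 1.0), (0.0, "POC", 0.0), (3.7, "BSI", 3.7)],
    )
    def test_identity_with_top_sample(self, make_deployment, p_top, substance, expected):
        dep = make_deployment(p_top=p_top, substance=substance)
        assert suspended_concentration(dep) == expected

    def test_missing_top_names_deployment(self, make_deployment):
        dep = make_deployment(p_top=None)
        with pytest.raises(MissingMeasurementError, match="TS-1-0001"):
            suspended_concentration(dep)


class TestSlow:
    @pytest.mark.parametrize(
        "p_top, p_base, expected",
        [
            (1.0, 2.0, 0.08421052631578947),   # (2-1)*8/95
            (5.0, 5.0, 0.0),
            (2.0, 1.5, -0.042105263157894736),  # signed: upward flux
        ],
    )
    def test_base_top_difference_scaled_by_volume_ratio(
        self, make_deployment, geom, p_top, p_base, expected
    ):
        dep = make_deployment(p_top=p_top, p_base=p_base)
        assert slow_concentration(dep, geom) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(
        p_top=st.floats(0, 100, allow_nan=False),
        p_base=st.floats(0, 100, allow_nan=False),
    )
    def test_antisymmetric_under_top_base_exchange(self, p_top, p_base):
        geom = DEFAULT_GEOMETRY
        forward = slow_concentration(_dep(p_top=p_top, p_base=p_base), geom)
        backward = slow_concentration(_dep(p_top=p_base, p_base=p_top), geom)
        assert forward == -backward

    def test_missing_inputs_raise(self, make_deployment, geom):
        with pytest.raises(MissingMeasurementError, match="p_base"):
            slow_concentration(make_deployment(p_base=None, p_tray=None), geom)


class TestFast:
    def test_direct_tray_path(self, make_deployment, geom):
        dep = make_deployment(p_tray=10.0, p_base=2.0)
        value, method = fast_concentration(dep, geom)
        assert value == pytest.approx(8 * 1 / (0.026 * 1.58 * 1000), rel=1e-12)
        assert method == "tray"

    def test_no_tray_enrichment_gives_zero(self, make_deployment, geom):
        value, _ = fast_concentration(make_deployment(p_tray=2.0, p_base=2.0), geom)
        assert value == 0.0

    def test_syphoned_tray_path(self, make_deployment, geom):
        dep = make_deployment(
            p_tray=None, p_tray_star=3.0, v_tray_star_l=9.5, p_base=2.0
        )
        value, method = fast_concentration(dep, geom)
        assert value == pytest.approx(1.0 * 9.5 / 95, rel=1e-12)
        assert method == "tray_star"

    def test_both_tray_variants_is_ambiguous(self, make_deployment, geom):
        dep = make_deployment(p_tray=10.0, p_tray_star=3.0, v_tray_star_l=9.5)
        with pytest.raises(AmbiguousTrayError):
            fast_concentration(dep, geom)

    def test_neither_tray_variant_is_missing(self, make_deployment, geom):
        with pytest.raises(MissingMeasurementError, match="tray"):
            fast_concentration(make_deployment(p_tray=None), geom)

    def test_tray_star_requires_volume_at_construction(self, make_deployment):
        with pytest.raises(ValidationError, match="v_tray_star_l"):
            make_deployment(p_tray=None, p_tray_star=3.0)


class TestPartition:
    def test_exactly_one_fast_path_recorded(self, make_deployment, geom):
        direct = partition(make_deployment(), geom)
        syphoned = partition(
            make_deployment(p_tray=None, p_tray_star=3.0, v_tray_star_l=9.5), geom
        )
        assert direct.method_fast == "tray"
        assert syphoned.method_fast == "tray_star"

    @settings(max_examples=50, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3, allow_nan=False))
    def test_partition_is_linear_in_measured_concentrations(self, scale):
        geom = DEFAULT_GEOMETRY
        base = partition(_dep(), geom)
        scaled = partition(
            _dep(p_top=1.0 * scale, p_base=2.0 * scale, p_tray=10.0 * scale), geom
        )
        assert scaled.p_susp == pytest.approx(base.p_susp * scale, rel=1e-9)
        assert scaled.p_slow == pytest.approx(base.p_slow * scale, rel=1e-9)
        assert scaled.p_fast == pytest.approx(base.p_fast * scale, rel=1e-9)

    def test_sd_propagation_quadrature_then_scaling(self, make_deployment, geom):
        dep = make_deployment(sd_top=0.3, sd_base=0.4, sd_tray=0.5)
        fs = partition(dep, geom)
        assert fs.sd_susp == 0.3
        # sqrt(0.3^2 + 0.4^2) = 0.5, then the volume-ratio factor 8/95
        assert fs.sd_slow == pytest.approx(0.5 * 8 / 95, rel=1e-12)
        assert fs.sd_fast == pytest.approx(
            math.hypot(0.5, 0.4) * 1 / (0.026 * 1.58 * 1000), rel=1e-12
        )

    def test_missing_sd_yields_none_not_zero(self, make_deployment, geom):
        fs = partition(make_deployment(sd_top=0.3), geom)
        assert fs.sd_slow is None and fs.sd_fast is None
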