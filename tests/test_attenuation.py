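"""Profile pooling, Martin-curve fitting and v_fast sensitivity."""

import numpy as np
import pytest

from mscflux import (
    DEFAULT_GEOMETRY,
    FluxProfile,
    FluxRecord,
    SubstanceTruth,
    SyntheticTruth,
    UnfittableProfileError,
    ValidationError,
    compute_fluxes,
    depth_split_b,
    fit_martin_b,
    fit_profiles,
    generate_campaign,
    pool_profiles,
    vfast_sensitivity,
)

from conftest import frame_to_deployments


def make_profile(depths, fluxes, z0=None, substance="POC"):
    return FluxProfile(
        group="TS", cruise="DY111", substance=substance,
        depths_m=tuple(depths), f_total=tuple(fluxes),
        sd_total=(None,) * len(depths),
        z0=z0 if z0 is not None else min(depths),
        fittable=sum(f > 0 for f in fluxes) >= 3,
    )


def make_record(**overrides):
    kwargs = dict(
        cruise="DY111", station="TS", occupation="1", deployment_id="d1",
        depth_m=60.0, substance="POC", f_slow=1.0, f_fast=4.0, f_total=5.0,
        v_fast_used=40.0,
    )
    kwargs.update(overrides)
    return FluxRecord(**kwargs)


class TestPooling:
    def _records(self):
        recs = []
        for occ in ("A", "B", "C"):
            for i, depth in enumerate((60, 160, 400, 700)):
                for substance in ("POC", "BSI"):
                    recs.append(
                        make_record(
                            occupation=occ, depth_m=float(depth), substance=substance,
                            deployment_id=f"{occ}-{i}", f_total=100.0 / (1 + i),
                        )
                    )
        return recs

    def test_station_rule_pools_occupations(self):
        profiles = pool_profiles(self._records(), "dy111")
        assert len(profiles) == 2  # one per substance
        assert all(p.n_points == 12 for p in profiles)

    def test_occupation_rule_splits_occupations(self):
        profiles = pool_profiles(self._records(), "dy086")
        assert len(profiles) == 6  # 3 occupations x 2 substances
        assert all(p.n_points == 4 for p in profiles)

    def test_substances_never_mix(self):
        for rule in ("dy086", "dy111"):
            for profile in pool_profiles(self._records(), rule):
                assert profile.substance in ("POC", "BSI")

    def test_every_record_lands_in_exactly_one_profile(self):
        records = self._records()
        profiles = pool_profiles(records, "dy111")
        assert sum(p.n_points for p in profiles) == len(records)

    def test_sparse_profile_flagged_unfittable(self):
        records = [make_record(deployment_id=f"d{i}", depth_m=60.0 + i) for i in range(2)]
        (profile,) = pool_profiles(records, "dy111")
        assert not profile.fittable
        with pytest.raises(UnfittableProfileError):
            fit_martin_b(profile)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValidationError):
            pool_profiles([], "dy999")


class TestMartinFit:
    def test_exact_power_law_recovered(self):
        depths = np.array([60.0, 110.0, 250.0, 500.0])
        fluxes = 200.0 * (depths / 60.0) ** -0.8
        fit = fit_martin_b(make_profile(depths, fluxes))
        assert fit.b == pytest.approx(0.8, abs=1e-10)
        assert fit.b_se == pytest.approx(0.0, abs=1e-8)
        assert fit.r_squared == 1.0

    def test_matches_independent_hand_ols(self):
        fit = fit_martin_b(make_profile([60, 110, 250, 500], [100, 60, 30, 15]))
        assert fit.b == pytest.approx(0.8890603717833631, rel=1e-9)
        assert fit.ln_f0 == pytest.approx(4.6253721348360735, rel=1e-9)
        assert fit.b_se > 0

    def test_scale_equivariance(self):
        base = fit_martin_b(make_profile([60, 110, 250, 500], [100, 60, 30, 15]))
        scaled = fit_martin_b(
            make_profile([60, 110, 250, 500], [1000, 600, 300, 150])
        )
        assert scaled.b == pytest.approx(base.b, rel=1e-12)
        assert scaled.ln_f0 == pytest.approx(base.ln_f0 + np.log(10), rel=1e-12)

    def test_nonpositive_fluxes_excluded_and_counted(self):
        fit = fit_martin_b(make_profile([60, 110, 250, 500, 700], [100, 60, 30, 15, -2]))
        assert fit.n_points == 4
        assert fit.n_excluded_nonpositive == 1

    def test_all_nonpositive_is_unfittable(self):
        with pytest.raises(UnfittableProfileError):
            fit_martin_b(make_profile([60, 110, 250, 500], [-1, -2, 0, -4]))

    def test_fitted_curve_evaluates_through_reference(self):
        fit = fit_martin_b(make_profile([60, 110, 250, 500], [100, 60, 30, 15]))
        assert fit.flux_at(fit.z0) == pytest.approx(fit.f0, rel=1e-12)

    def test_deterministic_repeat(self):
        profile = make_profile([60, 110, 250, 500], [100, 60, 30, 15])
        assert fit_martin_b(profile) == fit_martin_b(profile)


class TestVfastSensitivity:
    def _deployments(self, **truth_kwargs):
        truth = SyntheticTruth(noise_cv=0.0, seed=5, **truth_kwargs)
        frame, _ = generate_campaign(truth, n_profiles=1)
        return frame_to_deployments(frame)

    def test_all_slow_flux_profile_insensitive_to_grid(self):
        deployments = self._deployments(slow_fraction=1.0)
        fits = vfast_sensitivity(deployments, DEFAULT_GEOMETRY, (20, 40, 60, 100))
        for substance in ("BSI", "POC"):
            bs = [f.b for f in fits if f.substance == substance]
            assert np.ptp(bs) == pytest.approx(0.0, abs=1e-10)

    def test_depth_invariant_fast_fraction_insensitive_to_grid(self):
        # constant slow_fraction means the fast share of total flux does
        # not change with depth, so a uniform v_fast only rescales F(z)
        deployments = self._deployments(slow_fraction=0.3)
        fits = vfast_sensitivity(deployments, DEFAULT_GEOMETRY, (20, 40, 60, 100))
        for substance in ("BSI", "POC"):
            bs = [f.b for f in fits if f.substance == substance]
            assert np.ptp(bs) == pytest.approx(0.0, abs=1e-10)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            vfast_sensitivity([], DEFAULT_GEOMETRY, ())

    def test_velocity_recorded_on_fits(self):
        fits = vfast_sensitivity(self._deployments(), DEFAULT_GEOMETRY, (20.0, 100.0))
        assert sorted({f.v_fast for f in fits}) == [20.0, 100.0]


class TestDepthSplit:
    def _deployments(self, slow_fraction=0.3, depth_varying=False):
        # depth_varying uses two substances with different b so the fast
        # share still tracks total flux; the split matters once the fast
        # pool is non-zero because shallow/deep records get different v
        truth = SyntheticTruth(noise_cv=0.0, seed=6, slow_fraction=slow_fraction)
        frame, _ = generate_campaign(truth, n_profiles=1)
        return frame_to_deployments(frame)

    def test_zero_fast_pool_makes_schemes_identical(self):
        deployments = self._deployments(slow_fraction=1.0)
        uniform = fit_profiles(
            compute_fluxes(deployments, DEFAULT_GEOMETRY, vfast=40.0), "dy111"
        )
        minimized = depth_split_b(deployments, DEFAULT_GEOMETRY, "minimized")
        maximized = depth_split_b(deployments, DEFAULT_GEOMETRY, "maximized")
        for u, lo, hi in zip(uniform, minimized, maximized):
            assert lo.b == pytest.approx(u.b, abs=1e-10)
            assert hi.b == pytest.approx(u.b, abs=1e-10)

    def test_minimized_flattens_and_maximized_steepens(self):
        deployments = self._deployments()
        uniform = {
            f.substance: f.b
            for f in fit_profiles(
                compute_fluxes(deployments, DEFAULT_GEOMETRY, vfast=40.0), "dy111"
            )
        }
        minimized = {f.substance: f.b for f in depth_split_b(deployments, DEFAULT_GEOMETRY, "minimized")}
        maximized = {f.substance: f.b for f in depth_split_b(deployments, DEFAULT_GEOMETRY, "maximized")}
        for substance, b_uniform in uniform.items():
            assert minimized[substance] < b_uniform
            assert maximized[substance] > b_uniform

    def test_swapping_scheme_inverts_shift_direction(self):
        deployments = self._deployments()
        uniform = {
            f.substance: f.b
            for f in fit_profiles(
                compute_fluxes(deployments, DEFAULT_GEOMETRY, vfast=40.0), "dy111"
            )
        }
        minimized = {f.substance: f.b for f in depth_split_b(deployments, DEFAULT_GEOMETRY, "minimized")}
        maximized = {f.substance: f.b for f in depth_split_b(deployments, DEFAULT_GEOMETRY, "maximized")}
        for substance in uniform:
            assert np.sign(minimized[substance] - uniform[substance]) == -np.sign(
                maximized[substance] - uniform[substance]
            )

    def test_scheme_name_validated(self):
        with pytest.raises(ValidationError):
            depth_split_b(self._deployments(), DEFAULT_GEOMETRY, "median")
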