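"""Martin-curve flux attenuation: profile pooling, b-value fits and the
sinking-velocity sensitivity analyses.

Flux loss with depth is summarized by the power law::

    F(z) = F0 · (z / z0)^(-b)

with z0 the shallowest deployment depth of the profile and b the
attenuation exponent (larger b = faster loss). The fit is ordinary least
squares of ln F on ln(z/z0) — the "linear model" whose slope standard
error is reported alongside b. Non-positive total fluxes have no
logarithm; they are excluded and counted, never silently dropped.

Pooling follows the two cruise conventions: per-occupation profiles
(DY086-style: one profile per occupation of each station) or
per-station profiles (DY111-style: occupations of a station pooled).

Two sensitivity analyses probe the assumed bulk sinking velocity v_fast:
a grid of uniform velocities, and depth-split schemes that assign the
(40, 60) m d⁻¹ pair by depth — "minimized" b puts the faster velocity on
the deep deployments (inflating deep fluxes, flattening the fit) and
"maximized" does the opposite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import UnfittableProfileError, ValidationError
from .fluxes import (
    DEFAULT_DEPTH_SPLIT_PAIR,
    DEFAULT_SENSITIVITY_GRID,
    FluxRecord,
    VfastConfig,
    compute_fluxes,
)
from .geometry import MSCGeometry
from .partition import MSCDeployment

logger = logging.getLogger(__name__)

POOLING_RULES = ("dy086", "dy111")


@dataclass(frozen=True)
class FluxProfile:
    """Pooled (depth, total flux) points for one substance and one
    station/occupation group. ``z0`` is the shallowest depth present."""

    group: str
    cruise: str
    substance: str
    depths_m: tuple[float, ...]
    f_total: tuple[float, ...]
    sd_total: tuple[float | None, ...]
    z0: float
    fittable: bool

    @property
    def n_points(self) -> int:
        return len(self.depths_m)


@dataclass(frozen=True)
class AttenuationFit:
    """Result of one log-log Martin fit.

    ``b_se`` and ``ln_f0_se`` are the OLS standard errors; ``b_ci95`` is
    the Student-t 95% confidence interval on b (n−2 degrees of freedom,
    the honest small-sample interval for these 3–5 point profiles).
    """

    group: str
    substance: str
    b: float
    b_se: float
    ln_f0: float
    ln_f0_se: float
    z0: float
    n_points: int
    n_excluded_nonpositive: int
    r_squared: float
    scheme: str = "fixed_vfast"
    v_fast: float | None = None

    def __post_init__(self) -> None:
        if self.b_se < 0:
            raise ValidationError("b_se must be >= 0")

    @property
    def f0(self) -> float:
        return float(np.exp(self.ln_f0))

    @property
    def b_ci95(self) -> tuple[float, float]:
        df = self.n_points - 2
        half = stats.t.ppf(0.975, df) * self.b_se if df > 0 else float("inf")
        return (self.b - half, self.b + half)

    def flux_at(self, z: float | np.ndarray) -> float | np.ndarray:
        """Evaluate the fitted curve F0·(z/z0)^−b."""
        return self.f0 * (np.asarray(z, dtype=float) / self.z0) ** (-self.b)


def _profile_key(record: FluxRecord, pooling_rule: str) -> tuple:
    if pooling_rule == "dy086":
        return (record.cruise, record.station, record.occupation, record.substance)
    return (record.cruise, record.station, record.substance)


def pool_profiles(
    records: Iterable[FluxRecord], pooling_rule: str
) -> list[FluxProfile]:
    """Group flux records into fit-ready profiles.

    ``pooling_rule="dy086"`` makes one profile per station occupation;
    ``"dy111"`` pools all occupations of a station. Substances never
    mix. Every record lands in exactly one profile. Profiles with fewer
    than three positive-flux points are emitted with ``fittable=False``.
    """
    if pooling_rule not in POOLING_RULES:
        raise ValidationError(f"pooling_rule must be one of {POOLING_RULES}")
    groups: dict[tuple, list[FluxRecord]] = {}
    for rec in records:
        groups.setdefault(_profile_key(rec, pooling_rule), []).append(rec)
    profiles = []
    for key, recs in sorted(groups.items(), key=lambda kv: tuple(map(str, kv[0]))):
        recs = sorted(recs, key=lambda r: (r.depth_m, r.deployment_id))
        depths = tuple(r.depth_m for r in recs)
        n_positive = sum(1 for r in recs if r.f_total > 0)
        group = "/".join(str(k) for k in key[:-1] if k is not None)
        profiles.append(
            FluxProfile(
                group=group,
                cruise=recs[0].cruise,
                substance=key[-1],
                depths_m=depths,
                f_total=tuple(r.f_total for r in recs),
                sd_total=tuple(r.sd_total for r in recs),
                z0=min(depths),
                fittable=n_positive >= 3,
            )
        )
        if n_positive < 3:
            logger.warning(
                "pooling: profile %s %s has %d positive points; flagged unfittable",
                group, key[-1], n_positive,
            )
    return profiles


def fit_martin_b(profile: FluxProfile, weighted: bool = False) -> AttenuationFit:
    """OLS fit of ln F on ln(z/z0); b is the negated slope.

    ``weighted=True`` uses inverse-variance weights derived from the
    flux standard deviations (delta-method on the log scale); the
    default, matching the reported analysis, is unweighted.
    """
    z = np.asarray(profile.depths_m, dtype=float)
    f = np.asarray(profile.f_total, dtype=float)
    positive = f > 0
    n_excluded = int((~positive).sum())
    z, f = z[positive], f[positive]
    if len(f) < 3:
        raise UnfittableProfileError(
            f"profile {profile.group} {profile.substance}: "
            f"{len(f)} positive-flux points (< 3), cannot fit"
        )
    x = np.log(z / profile.z0)
    y = np.log(f)
    design = sm.add_constant(x)
    if weighted:
        sds = np.asarray(
            [sd for sd, keep in zip(profile.sd_total, positive) if keep], dtype=float
        )
        if np.any(np.isnan(sds)) or np.any(sds <= 0):
            raise ValidationError("weighted fit requires positive sd on every point")
        weights = (f / sds) ** 2  # var(ln F) ≈ (sd/F)²
        result = sm.WLS(y, design, weights=weights).fit()
    else:
        result = sm.OLS(y, design).fit()
    intercept, slope = result.params
    intercept_se, slope_se = result.bse
    # a perfect power law yields ~0/0 in the R² formula; report 1
    r2 = 1.0 if result.ssr < 1e-28 else float(result.rsquared)
    return AttenuationFit(
        group=profile.group,
        substance=profile.substance,
        b=float(-slope),
        b_se=float(slope_se),
        ln_f0=float(intercept),
        ln_f0_se=float(intercept_se),
        z0=profile.z0,
        n_points=int(len(f)),
        n_excluded_nonpositive=n_excluded,
        r_squared=r2,
    )


def fit_profiles(
    records: Iterable[FluxRecord],
    pooling_rule: str,
    weighted: bool = False,
    scheme: str = "fixed_vfast",
    v_fast: float | None = None,
) -> list[AttenuationFit]:
    """Pool records and fit every fittable profile."""
    fits = []
    for profile in pool_profiles(records, pooling_rule):
        if not profile.fittable:
            continue
        fit = fit_martin_b(profile, weighted=weighted)
        fits.append(replace(fit, scheme=scheme, v_fast=v_fast))
    return fits


def vfast_sensitivity(
    deployments: Sequence[MSCDeployment],
    geom: MSCGeometry,
    grid: Sequence[float] = DEFAULT_SENSITIVITY_GRID,
    pooling_rule: str = "dy111",
) -> list[AttenuationFit]:
    """Refit b for every profile with each uniform v_fast in ``grid``.

    v_fast only rescales the fast-pool flux, so profiles whose fast
    fraction is depth-invariant keep their b across the grid.
    """
    if not grid:
        raise ValidationError("sensitivity grid must be non-empty")
    fits: list[AttenuationFit] = []
    for v in grid:
        records = compute_fluxes(deployments, geom, vfast=float(v), on_error="skip")
        fits.extend(
            fit_profiles(records, pooling_rule, scheme="fixed_vfast", v_fast=float(v))
        )
    return fits


def depth_split_b(
    deployments: Sequence[MSCDeployment],
    geom: MSCGeometry,
    scheme: str,
    velocity_pair: tuple[float, float] = DEFAULT_DEPTH_SPLIT_PAIR,
    pooling_rule: str = "dy111",
) -> list[AttenuationFit]:
    """Fit b with a depth-dependent v_fast.

    The profile's depth range is split at the arithmetic midpoint of its
    shallowest and deepest deployment (deployments exactly at the
    midpoint count as shallow). ``scheme="minimized"`` assigns the
    slower velocity of ``velocity_pair`` to the shallow group and the
    faster one to the deep group, exaggerating deep fluxes and lowering
    the apparent attenuation; ``"maximized"`` does the opposite.
    """
    if scheme not in ("minimized", "maximized"):
        raise ValidationError("scheme must be 'minimized' or 'maximized'")
    slow_v, fast_v = sorted(velocity_pair)
    shallow_v, deep_v = (slow_v, fast_v) if scheme == "minimized" else (fast_v, slow_v)

    # group deployments the same way the records will pool, to find each
    # profile's depth midpoint before computing fluxes
    def key(dep: MSCDeployment) -> tuple:
        if pooling_rule == "dy086":
            return (dep.cruise, dep.station, dep.occupation, dep.substance)
        return (dep.cruise, dep.station, dep.substance)

    groups: dict[tuple, list[MSCDeployment]] = {}
    for dep in deployments:
        groups.setdefault(key(dep), []).append(dep)

    all_records = []
    for deps in groups.values():
        depths = [d.depth_m for d in deps]
        lo, hi = min(depths), max(depths)
        if lo == hi:
            raise ValidationError("depth-split needs a profile spanning >= 2 depths")
        midpoint = 0.5 * (lo + hi)
        shallow = [d for d in deps if d.depth_m <= midpoint]
        deep = [d for d in deps if d.depth_m > midpoint]
        all_records += compute_fluxes(shallow, geom, vfast=shallow_v, on_error="skip")
        all_records += compute_fluxes(deep, geom, vfast=deep_v, on_error="skip")
    return fit_profiles(all_records, pooling_rule, scheme=scheme)
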