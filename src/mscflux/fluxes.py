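"""Sinking fluxes from pool concentrations.

Slow-sinking flux divides the settled pool by the catcher footprint and
the settling time::

    F_slow = P_slow · V_MSC / (A_MSC · t · 1000)        [t in days]

which for a cylindrical catcher is just ``P_slow · h / t``. Fast-sinking
flux multiplies the fast-pool concentration by an assumed bulk sinking
velocity::

    F_fast = P_fast · v_fast

where 1 µg l⁻¹ ≡ 1 mg m⁻³ (and 1 µmol l⁻¹ ≡ 1 mmol m⁻³), so the product
of a concentration and a velocity in m d⁻¹ is directly a flux in
mg m⁻² d⁻¹ (or mmol m⁻² d⁻¹ for biogenic silica).

The choice of v_fast is the dominant structural uncertainty of the
method: the study defaults are 60 m d⁻¹ for cruise DY086 (in-situ and
polonium-derived velocities) and 40 m d⁻¹ for DY111 (thorium-derived
velocities and nutrient-budget closure), with a sensitivity grid of
{20, 40, 60, 100} m d⁻¹ and a depth-split (40, 60) scheme exercised by
the attenuation module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import MSCFluxError, ValidationError
from .geometry import MSCGeometry
from .partition import FLUX_UNITS, FractionSet, MSCDeployment, partition

logger = logging.getLogger(__name__)

#: Default bulk sinking velocity (m d⁻¹) per cruise.
DEFAULT_VFAST_BY_CRUISE: Mapping[str, float] = {"DY086": 60.0, "DY111": 40.0}

#: Default v_fast sensitivity grid (m d⁻¹).
DEFAULT_SENSITIVITY_GRID: tuple[float, ...] = (20.0, 40.0, 60.0, 100.0)

#: Default (shallow, deep) velocity pair for the depth-split schemes.
DEFAULT_DEPTH_SPLIT_PAIR: tuple[float, float] = (40.0, 60.0)


@dataclass(frozen=True)
class VfastConfig:
    """Bulk sinking velocity configuration.

    ``default_velocity_by_cruise`` supplies the per-cruise baseline;
    ``override`` (if set) forces a single velocity for every record and
    is what the sensitivity analysis uses; ``depth_split_pair`` is the
    (shallow, deep) velocity pair for the minimized/maximized schemes.
    """

    default_velocity_by_cruise: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VFAST_BY_CRUISE)
    )
    sensitivity_grid: tuple[float, ...] = DEFAULT_SENSITIVITY_GRID
    depth_split_pair: tuple[float, float] = DEFAULT_DEPTH_SPLIT_PAIR
    override: float | None = None

    def __post_init__(self) -> None:
        velocities = list(self.default_velocity_by_cruise.values())
        velocities += list(self.sensitivity_grid) + list(self.depth_split_pair)
        if self.override is not None:
            velocities.append(self.override)
        if any(not v > 0 for v in velocities):
            raise ValidationError("all sinking velocities must be > 0")

    def velocity_for(self, cruise: str) -> float:
        if self.override is not None:
            return self.override
        try:
            return self.default_velocity_by_cruise[cruise]
        except KeyError:
            raise ValidationError(
                f"no default v_fast for cruise {cruise!r}; "
                "supply an override or extend default_velocity_by_cruise"
            ) from None


@dataclass(frozen=True)
class FluxRecord:
    """Slow, fast and total sinking flux for one deployment/substance.

    ``f_total == f_slow + f_fast`` exactly; units are mg m⁻² d⁻¹ for
    CHL/POC and mmol m⁻² d⁻¹ for BSI. The velocity actually used is
    recorded for audit.
    """

    cruise: str
    station: str
    occupation: str | None
    deployment_id: str
    depth_m: float
    substance: str
    f_slow: float
    f_fast: float
    f_total: float
    v_fast_used: float
    sd_slow: float | None = None
    sd_fast: float | None = None
    sd_total: float | None = None
    method_fast: str = "tray"

    @property
    def units(self) -> str:
        return FLUX_UNITS[self.substance]


def slow_flux(p_slow: float, geom: MSCGeometry) -> float:
    """Slow-sinking flux from a slow-pool concentration; sign preserved."""
    return p_slow * geom.slow_flux_factor


def fast_flux(p_fast: float, v_fast: float) -> float:
    """Fast-sinking flux: concentration × bulk sinking velocity."""
    if not v_fast > 0:
        raise ValidationError(f"v_fast must be > 0, got {v_fast}")
    return p_fast * v_fast


def flux_from_fractions(
    fractions: FractionSet,
    geom: MSCGeometry,
    v_fast: float,
    clamp_negative_slow: bool = False,
) -> FluxRecord:
    """Build a :class:`FluxRecord` from a partitioned deployment.

    Negative slow fluxes (upward flux of material) are retained signed in
    the total by default; ``clamp_negative_slow=True`` zeroes them, for
    sensitivity checks only.
    """
    dep = fractions.deployment
    f_slow = slow_flux(fractions.p_slow, geom)
    sd_slow = None if fractions.sd_slow is None else fractions.sd_slow * geom.slow_flux_factor
    if clamp_negative_slow and f_slow < 0:
        f_slow = 0.0
        sd_slow = None if sd_slow is None else 0.0
    f_fast = fast_flux(fractions.p_fast, v_fast)
    sd_fast = None if fractions.sd_fast is None else fractions.sd_fast * v_fast
    sd_total = None
    if sd_slow is not None and sd_fast is not None:
        sd_total = math.hypot(sd_slow, sd_fast)
    return FluxRecord(
        cruise=dep.cruise,
        station=dep.station,
        occupation=dep.occupation,
        deployment_id=dep.deployment_id,
        depth_m=dep.depth_m,
        substance=dep.substance,
        f_slow=f_slow,
        f_fast=f_fast,
        f_total=f_slow + f_fast,
        v_fast_used=v_fast,
        sd_slow=sd_slow,
        sd_fast=sd_fast,
        sd_total=sd_total,
        method_fast=fractions.method_fast,
    )


def compute_fluxes(
    deployments: Iterable[MSCDeployment],
    geom: MSCGeometry,
    vfast: VfastConfig | float | None = None,
    clamp_negative_slow: bool = False,
    on_error: str = "raise",
) -> list[FluxRecord]:
    """Partition each deployment and convert it to fluxes.

    ``vfast`` may be a :class:`VfastConfig`, a single velocity applied to
    every record, or ``None`` for the per-cruise defaults.
    ``on_error="skip"`` logs and drops deployments whose pools cannot be
    computed (missing tray, missing top/base) instead of raising.
    """
    if vfast is None:
        vfast = VfastConfig()
    elif isinstance(vfast, (int, float)):
        vfast = VfastConfig(override=float(vfast))
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")

    records: list[FluxRecord] = []
    n_skipped = 0
    for dep in deployments:
        try:
            fractions = partition(dep, geom)
            records.append(
                flux_from_fractions(
                    fractions, geom, vfast.velocity_for(dep.cruise), clamp_negative_slow
                )
            )
        except MSCFluxError as exc:
            if on_error == "raise":
                raise
            n_skipped += 1
            logger.warning("flux: skipped %s: %s", dep.label(), exc)
    logger.info("flux: %d records computed, %d skipped", len(records), n_skipped)
    return records


def negative_slow_report(records: Sequence[FluxRecord]) -> dict[str, float]:
    """Summary of the signed-vs-clamped treatment of negative slow fluxes:
    how many records carry one and how much total flux would change if
    they were zeroed."""
    negatives = [r for r in records if r.f_slow < 0]
    return {
        "n_records": float(len(records)),
        "n_negative_slow": float(len(negatives)),
        "total_flux_signed": sum(r.f_total for r in records),
        "total_flux_clamped": sum(max(r.f_slow, 0.0) + r.f_fast for r in records),
    }
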