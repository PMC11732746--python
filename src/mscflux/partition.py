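"""Partitioning of measured MSC fraction concentrations into pools.

After the settling period, three water samples are drawn from the catcher
(plus an optional time-zero sample taken at closure):

* ``top``  — the upper section; defines the suspended pool,
* ``base`` — the detachable base section; its enrichment over the top
  defines the slow-sinking pool,
* ``tray`` — the particle collection tray at the very bottom; its
  enrichment over the base defines the fast-sinking pool. On some
  deployments a larger volume was syphoned from around the tray instead
  (the ``tray_star`` variant, with its own syphoned volume).

The derived pool concentrations are::

    P_susp = P_top
    P_slow = (P_base - P_top) · V_base / V_MSC
    P_fast = (P_tray - P_base) · V_tray / (A_tray · h · 1000)        (direct tray)
    P_fast = (P_tray* - P_base) · V_tray* / V_MSC                    (syphoned tray)

Negative slow or fast concentrations are *preserved* here — they indicate
an upward flux of material (or simply measurement noise) and downstream
modules decide how to treat them.

Standard deviations, where supplied, are propagated to first order
assuming independent errors: differences add in quadrature, constant
factors scale linearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import FrozenSet

from .errors import AmbiguousTrayError, MissingMeasurementError, ValidationError
from .geometry import L_PER_M3, MSCGeometry

#: Substance codes and the units their concentrations / fluxes carry.
#: Operations never convert between substances' unit systems silently;
#: note 1 µg l⁻¹ ≡ 1 mg m⁻³ and 1 µmol l⁻¹ ≡ 1 mmol m⁻³, which is why a
#: concentration times a velocity (m d⁻¹) is directly a flux.
CONCENTRATION_UNITS = {"CHL": "ug/l", "POC": "ug/l", "BSI": "umol/l"}
FLUX_UNITS = {"CHL": "mg/m2/d", "POC": "mg/m2/d", "BSI": "mmol/m2/d"}
SUBSTANCES = frozenset(CONCENTRATION_UNITS)


def _check_sd(name: str, sd: float | None) -> None:
    if sd is not None and sd < 0:
        raise ValidationError(f"{name} must be non-negative, got {sd}")


@dataclass(frozen=True)
class MSCDeployment:
    """Measured fraction concentrations for one substance from one
    catcher deployment.

    Concentrations are µg l⁻¹ for CHL/POC and µmol l⁻¹ for BSI; ``depth_m``
    is the deployment depth in metres. ``p_tray`` and ``p_tray_star`` are
    mutually exclusive; the syphoned variant requires its syphoned volume
    ``v_tray_star_l``.
    """

    cruise: str
    station: str
    occupation: str | None
    deployment_id: str
    depth_m: float
    substance: str
    p_top: float | None = None
    p_base: float | None = None
    p_t0: float | None = None
    p_tray: float | None = None
    p_tray_star: float | None = None
    v_tray_star_l: float | None = None
    sd_top: float | None = None
    sd_base: float | None = None
    sd_t0: float | None = None
    sd_tray: float | None = None
    sd_tray_star: float | None = None
    flags: FrozenSet[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.substance not in SUBSTANCES:
            raise ValidationError(
                f"unknown substance {self.substance!r} (expected one of {sorted(SUBSTANCES)})"
            )
        if not self.depth_m > 0:
            raise ValidationError(f"depth_m must be > 0, got {self.depth_m}")
        if self.p_tray_star is not None and self.v_tray_star_l is None:
            raise ValidationError(
                f"deployment {self.deployment_id}: p_tray_star requires v_tray_star_l"
            )
        if self.v_tray_star_l is not None and not self.v_tray_star_l > 0:
            raise ValidationError("v_tray_star_l must be > 0")
        for name in ("sd_top", "sd_base", "sd_t0", "sd_tray", "sd_tray_star"):
            _check_sd(name, getattr(self, name))
        object.__setattr__(self, "flags", frozenset(self.flags))

    @property
    def units(self) -> str:
        return CONCENTRATION_UNITS[self.substance]

    def label(self) -> str:
        return f"{self.cruise}/{self.station}/{self.deployment_id} {self.substance} @{self.depth_m:g} m"


@dataclass(frozen=True)
class FractionSet:
    """Derived suspended / slow-sinking / fast-sinking concentrations for
    one deployment, in the deployment's units, with propagated standard
    deviations where the inputs carried them.

    ``p_slow`` and ``p_fast`` keep their sign: negative values mean the
    lower fraction was *less* concentrated than the one above it.
    ``method_fast`` records whether the direct-tray or syphoned-tray
    equation produced ``p_fast``.
    """

    deployment: MSCDeployment
    p_susp: float
    p_slow: float
    p_fast: float
    sd_susp: float | None = None
    sd_slow: float | None = None
    sd_fast: float | None = None
    method_fast: str = "tray"  # "tray" | "tray_star"

    @property
    def substance(self) -> str:
        return self.deployment.substance

    @property
    def depth_m(self) -> float:
        return self.deployment.depth_m


def suspended_concentration(dep: MSCDeployment) -> float:
    """Suspended-pool concentration: identically the top-sample value."""
    if dep.p_top is None:
        raise MissingMeasurementError(f"{dep.label()}: p_top missing")
    return dep.p_top


def slow_concentration(dep: MSCDeployment, geom: MSCGeometry) -> float:
    """Slow-sinking concentration from the base/top difference, scaled by
    the base-to-catcher volume ratio. Sign preserved."""
    if dep.p_top is None or dep.p_base is None:
        missing = [n for n, v in (("p_top", dep.p_top), ("p_base", dep.p_base)) if v is None]
        raise MissingMeasurementError(f"{dep.label()}: {', '.join(missing)} missing")
    return (dep.p_base - dep.p_top) * geom.v_base_l / geom.v_msc_l


def fast_concentration(dep: MSCDeployment, geom: MSCGeometry) -> tuple[float, str]:
    """Fast-sinking concentration from the tray/base difference.

    Returns ``(value, method)`` where method is ``"tray"`` for the
    direct-tray equation or ``"tray_star"`` for the syphoned variant.
    Exactly one tray measurement must be present.
    """
    if dep.p_base is None:
        raise MissingMeasurementError(f"{dep.label()}: p_base missing")
    has_tray = dep.p_tray is not None
    has_star = dep.p_tray_star is not None
    if has_tray and has_star:
        raise AmbiguousTrayError(
            f"{dep.label()}: both p_tray and p_tray_star present; remove one"
        )
    if has_tray:
        value = (dep.p_tray - dep.p_base) * geom.v_tray_l / (
            geom.a_tray_m2 * geom.h_m * L_PER_M3
        )
        return value, "tray"
    if has_star:
        value = (dep.p_tray_star - dep.p_base) * dep.v_tray_star_l / geom.v_msc_l
        return value, "tray_star"
    raise MissingMeasurementError(f"{dep.label()}: no tray measurement (p_tray or p_tray_star)")


def partition(dep: MSCDeployment, geom: MSCGeometry) -> FractionSet:
    """Full partition of one deployment into suspended, slow and fast
    pools with first-order uncertainty propagation.

    A propagated sd is ``None`` whenever any contributing measurement
    lacks its own sd — missing uncertainties are never fabricated.
    """
    p_susp = suspended_concentration(dep)
    p_slow = slow_concentration(dep, geom)
    p_fast, method = fast_concentration(dep, geom)

    sd_susp = dep.sd_top
    sd_slow = None
    if dep.sd_top is not None and dep.sd_base is not None:
        sd_slow = math.hypot(dep.sd_top, dep.sd_base) * geom.v_base_l / geom.v_msc_l
    sd_fast = None
    if method == "tray":
        if dep.sd_tray is not None and dep.sd_base is not None:
            sd_fast = math.hypot(dep.sd_tray, dep.sd_base) * geom.v_tray_l / (
                geom.a_tray_m2 * geom.h_m * L_PER_M3
            )
    else:
        if dep.sd_tray_star is not None and dep.sd_base is not None:
            sd_fast = math.hypot(dep.sd_tray_star, dep.sd_base) * dep.v_tray_star_l / geom.v_msc_l

    return FractionSet(
        deployment=dep,
        p_susp=p_susp,
        p_slow=p_slow,
        p_fast=p_fast,
        sd_susp=sd_susp,
        sd_slow=sd_slow,
        sd_fast=sd_fast,
        method_fast=method,
    )
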