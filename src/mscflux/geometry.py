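"""Marine snow catcher (MSC) instrument geometry.

The marine snow catcher is a large (~95 l) closing water sampler. After
recovery it stands on deck for a fixed settling period; particles are then
operationally split into a *suspended* pool (still in the top section), a
*slow-sinking* pool (settled into the base section) and a *fast-sinking*
pool (settled all the way onto a collection tray at the bottom). All of
the partitioning and flux arithmetic is parameterized by the dimensions
collected here.

Units are litres, metres, square metres and hours; the settling time is
converted to days internally wherever a flux (per-day) is formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import ValidationError

#: litres per cubic metre — the unit bridge between concentrations
#: (per litre) and fluxes (per square metre).
L_PER_M3 = 1000.0

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class MSCGeometry:
    """Dimensions of one marine snow catcher.

    Parameters
    ----------
    v_msc_l
        Volume of the full catcher (l).
    v_base_l
        Volume of the detachable base section (l).
    v_tray_l
        Volume of the particle collection tray (l). The nominal value is
        approximate ("~1 l"), hence overridable.
    a_tray_m2
        Collection area of the tray (m²).
    h_m
        Height of the catcher (m).
    t_settle_h
        Settling period on deck (hours).
    a_msc_m2
        Cross-sectional area of the catcher (m²). Not usually supplied:
        it is derived as ``v_msc / (h × 1000 l m⁻³)``, i.e. assuming a
        vertical cylinder, giving 0.0601 m² for the default geometry.
    """

    v_msc_l: float = 95.0
    v_base_l: float = 8.0
    v_tray_l: float = 1.0
    a_tray_m2: float = 0.026
    h_m: float = 1.58
    t_settle_h: float = 2.0
    a_msc_m2: float | None = field(default=None)

    def __post_init__(self) -> None:
        derived = self.v_msc_l / (self.h_m * L_PER_M3)
        if self.a_msc_m2 is None:
            object.__setattr__(self, "a_msc_m2", derived)
        for name in ("v_msc_l", "v_base_l", "v_tray_l", "a_tray_m2",
                     "h_m", "t_settle_h", "a_msc_m2"):
            value = getattr(self, name)
            if not value > 0:
                raise ValidationError(f"MSCGeometry.{name} must be > 0, got {value!r}")
        if not self.v_base_l < self.v_msc_l:
            raise ValidationError("v_base_l must be smaller than v_msc_l")
        if not self.v_tray_l < self.v_base_l:
            raise ValidationError("v_tray_l must be smaller than v_base_l")
        if abs(self.a_msc_m2 - derived) > 1e-9 * derived:
            raise ValidationError(
                f"a_msc_m2={self.a_msc_m2} inconsistent with v_msc/h "
                f"(expected {derived:.6g} m² for a vertical cylinder)"
            )

    @property
    def t_settle_d(self) -> float:
        """Settling period in days (flux denominators are per day)."""
        return self.t_settle_h / HOURS_PER_DAY

    @property
    def slow_flux_factor(self) -> float:
        """Multiplier converting a slow-pool concentration (µg l⁻¹ or
        µmol l⁻¹) into a flux (mg m⁻² d⁻¹ or mmol m⁻² d⁻¹).

        Equal to ``v_msc / (a_msc × t × 1000)``; for a cylindrical
        catcher this reduces to ``h / t`` with t in days.
        """
        return self.v_msc_l / (self.a_msc_m2 * self.t_settle_d * L_PER_M3)

    @classmethod
    def from_config(cls, config: Mapping[str, float]) -> "MSCGeometry":
        """Build a geometry from config keys ``v_msc_l, v_base_l,
        v_tray_l, a_tray_m2, h_m, t_settle_h`` (missing keys keep their
        defaults; unknown keys are rejected)."""
        known = {"v_msc_l", "v_base_l", "v_tray_l", "a_tray_m2", "h_m",
                 "t_settle_h", "a_msc_m2"}
        unknown = set(config) - known
        if unknown:
            raise ValidationError(f"unknown geometry keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in config.items()})


#: Default instrument constants for the 95-litre catcher.
DEFAULT_GEOMETRY = MSCGeometry()
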