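"""Forward simulation of MSC campaigns with known truth.

The generator runs the measurement model *backwards*: it lays down a
power-law true flux profile per substance, splits it into slow- and
fast-sinking pools, inverts the partition and flux equations through the
catcher geometry to obtain exact fraction concentrations (top, base,
tray, time-zero), then corrupts each measured fraction with independent
multiplicative lognormal noise. Every pipeline stage can therefore be
checked against a truth ledger without any cruise data.

Default conditions emulate the sampling design of the field campaigns:
four deployment depths from just below the mixed layer (MLD + 10 m,
MLD + 110 m, 400 m, 700 m, with MLD = 50 m), attenuation exponents
b = 1.0 for biogenic silica and 0.4 for organic carbon, reference fluxes
of 5 mmol m⁻² d⁻¹ (BSi) and 200 mg m⁻² d⁻¹ (POC) at the shallowest
depth, 30% of sinking flux in the slow pool, a true bulk sinking
velocity of 40 m d⁻¹ and a 20% coefficient of variation on each
measured fraction.

Noise is lognormal and mean-preserving (log-scale mean −σ²/2), so
concentrations stay positive and the expected value of each noisy
fraction equals its true value. All randomness flows from a single
integer seed through one ``numpy.random.Generator``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .geometry import DEFAULT_GEOMETRY, L_PER_M3, MSCGeometry
from .io import CONCENTRATION_COLUMNS
from .partition import SUBSTANCES

TRUTH_COLUMNS = [
    "occupation", "deployment_id", "depth_m", "substance",
    "f_slow_true", "f_fast_true", "f_total_true",
    "b_true", "f0_true", "z0", "v_fast_true", "slow_fraction",
]

#: Default deployment depths: MLD + 10 m, MLD + 110 m, 400 m, 700 m
#: with a 50 m mixed layer.
def default_depths(mld_m: float = 50.0) -> tuple[float, ...]:
    return (mld_m + 10.0, mld_m + 110.0, 400.0, 700.0)


@dataclass(frozen=True)
class SubstanceTruth:
    """True attenuation curve and background for one substance.

    ``f0_true`` is the total sinking flux at the shallowest deployment
    depth (mg m⁻² d⁻¹, or mmol m⁻² d⁻¹ for BSI);
    ``suspended_background`` the suspended concentration in the
    substance's units.
    """

    b_true: float
    f0_true: float
    suspended_background: float

    def __post_init__(self) -> None:
        if not self.f0_true > 0:
            raise ValidationError("f0_true must be > 0")
        if not self.suspended_background >= 0:
            raise ValidationError("suspended_background must be >= 0")


DEFAULT_SUBSTANCE_TRUTH: Mapping[str, SubstanceTruth] = {
    "BSI": SubstanceTruth(b_true=1.0, f0_true=5.0, suspended_background=1.0),
    "POC": SubstanceTruth(b_true=0.4, f0_true=200.0, suspended_background=50.0),
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Full specification of one simulated campaign.

    ``slow_fraction`` is the fraction of total sinking flux carried by
    the slow pool; small negative values are permitted to emulate the
    occasional upward slow flux seen in real catchers (the fast pool
    then carries ``1 − slow_fraction`` so the total is unchanged).
    """

    substances: Mapping[str, SubstanceTruth] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTANCE_TRUTH)
    )
    depths_m: tuple[float, ...] = field(default_factory=default_depths)
    slow_fraction: float = 0.3
    noise_cv: float = 0.2
    v_fast_true: float = 40.0
    seed: int = 0
    cruise: str = "DY111"  # depth pattern and v_fast default emulate this cruise
    station: str = "S1"
    tray_star_every: int = 0  # 0 = never; k>0 = every k-th deployment syphoned
    v_tray_star_l: float = 10.0

    def __post_init__(self) -> None:
        unknown = set(self.substances) - SUBSTANCES
        if unknown:
            raise ValidationError(f"unknown substances {sorted(unknown)}")
        if not self.substances:
            raise ValidationError("at least one substance required")
        if not -0.5 <= self.slow_fraction <= 1.0:
            raise ValidationError("slow_fraction must be in [-0.5, 1]")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if not self.v_fast_true > 0:
            raise ValidationError("v_fast_true must be > 0")
        depths = self.depths_m
        if len(depths) < 2 or any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValidationError("depths_m must be strictly increasing, length >= 2")
        if depths[0] <= 0:
            raise ValidationError("depths_m must be positive")

    @property
    def z0(self) -> float:
        return self.depths_m[0]


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-preserving multiplicative noise: E[factor] = 1."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def generate_campaign(
    truth: SyntheticTruth,
    n_profiles: int = 1,
    geom: MSCGeometry = DEFAULT_GEOMETRY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``n_profiles`` replicate profiles of one station.

    Returns ``(concentrations, truth_ledger)``: the concentration table
    in the canonical long format (one row per measured fraction, ready
    for :func:`mscflux.io.read_concentrations` or a CSV round trip) and
    the per-deployment true fluxes for assertions. Replicate profiles
    are labelled as successive occupations, so per-occupation pooling
    fits each replicate separately and per-station pooling combines
    them.
    """
    if n_profiles < 1:
        raise ValidationError("n_profiles must be >= 1")
    rng = np.random.default_rng(truth.seed)
    sf = truth.slow_fraction

    conc_rows: list[dict] = []
    truth_rows: list[dict] = []
    dep_counter = 0
    for i_profile in range(n_profiles):
        occupation = f"OCC{i_profile + 1:03d}"
        for depth in truth.depths_m:
            dep_counter += 1
            dep_id = f"{truth.station}-{occupation}-{dep_counter:04d}"
            use_star = truth.tray_star_every > 0 and dep_counter % truth.tray_star_every == 0
            for substance in sorted(truth.substances):
                st = truth.substances[substance]
                f_total = st.f0_true * (depth / truth.z0) ** (-st.b_true)
                f_slow = sf * f_total
                f_fast = (1.0 - sf) * f_total

                p_slow = f_slow / geom.slow_flux_factor
                p_top = st.suspended_background
                p_base = p_top + p_slow * geom.v_msc_l / geom.v_base_l
                p_fast = f_fast / truth.v_fast_true
                if use_star:
                    p_tray = p_base + p_fast * geom.v_msc_l / truth.v_tray_star_l
                else:
                    p_tray = p_base + p_fast * geom.a_tray_m2 * geom.h_m * L_PER_M3 / geom.v_tray_l
                p_t0 = p_top + p_slow + p_fast
                if p_base <= 0 or p_tray <= 0:
                    raise ParameterError(
                        f"inversion infeasible at {depth:g} m for {substance}: "
                        f"p_base={p_base:.4g}, p_tray={p_tray:.4g}; raise "
                        "suspended_background or f0_true, or lower |slow_fraction|"
                    )

                fractions = {
                    "t0": p_t0,
                    "top": p_top,
                    "base": p_base,
                    ("tray_star" if use_star else "tray"): p_tray,
                }
                noise = _lognormal_factors(rng, truth.noise_cv, len(fractions))
                for (fraction, value), factor in zip(fractions.items(), noise):
                    conc_rows.append(
                        {
                            "cruise": truth.cruise,
                            "station": truth.station,
                            "occupation": occupation,
                            "deployment_id": dep_id,
                            "depth_m": depth,
                            "substance": substance,
                            "fraction": fraction,
                            "concentration": value * factor,
                            "concentration_sd": (
                                truth.noise_cv * value if truth.noise_cv > 0 else None
                            ),
                            "v_tray_star_l": (
                                truth.v_tray_star_l if fraction == "tray_star" else None
                            ),
                            "flags": "tray_star" if fraction == "tray_star" else "",
                        }
                    )
                truth_rows.append(
                    {
                        "occupation": occupation,
                        "deployment_id": dep_id,
                        "depth_m": depth,
                        "substance": substance,
                        "f_slow_true": f_slow,
                        "f_fast_true": f_fast,
                        "f_total_true": f_total,
                        "b_true": st.b_true,
                        "f0_true": st.f0_true,
                        "z0": truth.z0,
                        "v_fast_true": truth.v_fast_true,
                        "slow_fraction": sf,
                    }
                )
    concentrations = pd.DataFrame(conc_rows, columns=CONCENTRATION_COLUMNS)
    ledger = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return concentrations, ledger


def generate_ratio_profile_fixture(
    b_bsi: float = 1.2,
    b_poc: float = 0.5,
    depths_m: tuple[float, ...] | None = None,
    slow_fraction: float = 0.3,
) -> pd.DataFrame:
    """Deterministic noise-free fixture for molar-ratio trend tests.

    With ``b_bsi > b_poc`` the true total-sinking BSi:POC ratio strictly
    decreases with depth; a small *negative* ``slow_fraction`` adds the
    upward-slow-flux pathology that exercises the magnitude rule.
    """
    truth = SyntheticTruth(
        substances={
            "BSI": SubstanceTruth(b_true=b_bsi, f0_true=5.0, suspended_background=1.0),
            "POC": SubstanceTruth(b_true=b_poc, f0_true=200.0, suspended_background=50.0),
        },
        depths_m=depths_m or default_depths(),
        slow_fraction=slow_fraction,
        noise_cv=0.0,
        seed=0,
    )
    concentrations, _ = generate_campaign(truth)
    return concentrations
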