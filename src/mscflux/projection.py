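"""Deep-flux projection below the deepest measurement.

Measured profiles stop at ~750 m; to compare twilight-zone stoichiometry
with deep sediment-trap observations, fluxes are extended downward with
either the fitted Martin power law or an exponential decay anchored at
the deepest measured flux::

    power law:    F(z) = F_a · (z / z_a)^(-b)
    exponential:  F(z) = F_a · exp(-(z - z_a) / v)

where (z_a, F_a) is the anchor (depth, flux) and v the remineralization
length scale in metres. Depth in the exponential is measured below the
anchor so the projected curve is continuous with the measured one at
z_a; the literal absolute-depth exponent (``F_a · e^(−z/v)``, which
drops discontinuously at the anchor) is available behind a flag for
comparison.

The projected BSi:POC molar-ratio profile divides the BSi flux
(mmol m⁻² d⁻¹) by the POC flux converted from mg to mmol of carbon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .attenuation import AttenuationFit
from .errors import UndefinedRatioError, ValidationError
from .stoichiometry import CARBON_MOLAR_MASS


@dataclass(frozen=True)
class ProjectionParams:
    """Parameters of one deep-flux projection.

    ``model`` is ``"power_law"`` (requires ``b``) or ``"exponential"``
    (requires ``length_scale_m``); ``anchor_depth_m``/``anchor_flux``
    pin the curve, e.g. (750 m, F_750).
    """

    model: str
    anchor_depth_m: float
    anchor_flux: float
    b: float | None = None
    length_scale_m: float | None = None
    absolute_depth_exponent: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("power_law", "exponential"):
            raise ValidationError(f"unknown projection model {self.model!r}")
        if not self.anchor_flux > 0:
            raise ValidationError("anchor_flux must be > 0")
        if not self.anchor_depth_m > 0:
            raise ValidationError("anchor_depth_m must be > 0")
        if self.model == "power_law" and self.b is None:
            raise ValidationError("power_law projection requires b")
        if self.model == "exponential":
            if self.length_scale_m is None or not self.length_scale_m > 0:
                raise ValidationError("exponential projection requires length_scale_m > 0")

    @classmethod
    def from_fit(cls, fit: AttenuationFit, anchor_depth_m: float) -> "ProjectionParams":
        """Continue a fitted Martin curve below ``anchor_depth_m``,
        anchoring at the fitted flux there."""
        return cls(
            model="power_law",
            anchor_depth_m=anchor_depth_m,
            anchor_flux=float(fit.flux_at(anchor_depth_m)),
            b=fit.b,
        )


def project_flux(params: ProjectionParams, depths_m: Sequence[float]) -> np.ndarray:
    """Evaluate the projection at each depth (all ≥ the anchor depth)."""
    z = np.asarray(depths_m, dtype=float)
    if np.any(z < params.anchor_depth_m):
        raise ValidationError(
            f"projection depths must be >= anchor depth {params.anchor_depth_m} m"
        )
    if params.model == "power_law":
        return params.anchor_flux * (z / params.anchor_depth_m) ** (-params.b)
    if params.absolute_depth_exponent:
        return params.anchor_flux * np.exp(-z / params.length_scale_m)
    return params.anchor_flux * np.exp(-(z - params.anchor_depth_m) / params.length_scale_m)


def projected_ratio_profile(
    bsi_params: ProjectionParams,
    poc_params: ProjectionParams,
    depths_m: Sequence[float],
) -> pd.DataFrame:
    """BSi:POC molar ratio (mol mol⁻¹) of the projected fluxes.

    BSi fluxes are mmol m⁻² d⁻¹ already; POC fluxes (mg m⁻² d⁻¹) are
    divided by 12.011 first. Columns: depth_m, flux_bsi, flux_poc,
    ratio_mol_mol.
    """
    bsi = project_flux(bsi_params, depths_m)
    poc = project_flux(poc_params, depths_m)
    poc_mmol = poc / CARBON_MOLAR_MASS
    if np.any(poc_mmol == 0):
        bad = np.asarray(depths_m, dtype=float)[poc_mmol == 0]
        raise UndefinedRatioError(f"POC flux is zero at depths {bad.tolist()}")
    return pd.DataFrame(
        {
            "depth_m": np.asarray(depths_m, dtype=float),
            "flux_bsi": bsi,
            "flux_poc": poc,
            "ratio_mol_mol": bsi / poc_mmol,
        }
    )
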