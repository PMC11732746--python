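"""BSi:POC molar ratios of sinking material down a profile.

Uses the deterministic ratio fixture (BSi b = 1.0, POC b = 0.4): because
silica flux attenuates faster than carbon flux, the molar ratio of the
total sinking pool must decrease with depth.
"""

import io

from mscflux import (
    DEFAULT_GEOMETRY,
    aggregate_ratios,
    generate_ratio_profile_fixture,
    molar_ratio_records,
)
from mscflux.io import read_concentrations

frame = generate_ratio_profile_fixture(b_bsi=1.0, b_poc=0.4)
deployments, _ = read_concentrations(io.StringIO(frame.to_csv(index=False)))

records = molar_ratio_records(deployments, DEFAULT_GEOMETRY,
                              fractions=("total_sinking", "time_zero"))
print("depth (m)   fraction        BSi:POC (mol/mol)")
for rec in sorted(aggregate_ratios(records), key=lambda r: (r.fraction, r.depth_m)):
    print(f"{rec.depth_m:8.0f}   {rec.fraction:<14} {rec.ratio:8.3f}")
print(
    "\nThe total-sinking ratio falls from ~0.30 at the export depth to "
    "~0.07 at 700 m: sinking particles lose opal faster than organic carbon."
)
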