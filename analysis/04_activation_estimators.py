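#!/usr/bin/env python
"""Recover Km and the mechanistic IP6 EC50 from synthetic assay data.

Generates Michaelis-Menten rate data at the published peptide Km (925 uM)
with 5% noise and refits it; then produces the mechanistic IP6
dose-response (peripheral-site Kd 7 uM scaling the dimerization on-rate up
to 10-fold) and fits a four-parameter logistic for the apparent EC50.
"""

from btkact.pipeline import RunConfig, run

cfg = RunConfig(
    output_dir="results/assays",
    michaelis_menten={"Vmax_per_min": 60.0, "Km_uM": 925.0, "noise_fraction": 0.05},
    dose_response={"peripheral_kd_uM": 7.0, "onrate_ceiling": 10.0,
                   "readout_time_s": 600.0, "total0_uM": 2.0},
    seed=1,
)
run(cfg)

import json  # noqa: E402

mm = json.loads(open("results/assays/mm_fit.json").read())
print(f"Km recovered from 5%-noise data: {mm['Km_uM']:.0f} +/- {mm['Km_stderr_uM']:.0f} uM "
      f"(truth 925 uM)")

dr = json.loads(open("results/assays/dose_response_fit.json").read())
print(f"mechanistic IP6 dose-response: apparent EC50 = {dr['EC50_uM']:.1f} uM, "
      f"Hill = {dr['hill']:.2f}")
print("the endpoint readout at 600 s half-saturates where activation is only "
      "~4x accelerated, so the apparent EC50 falls below the 7 uM occupancy Kd; "
      "see docs/methods.md")
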