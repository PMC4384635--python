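#!/usr/bin/env python
"""Simulate Btk autophosphorylation with and without IP6.

Runs the four-reaction autocatalytic scheme at 1 uM Btk for both scenarios
(IP6 raises the dimerization on-rates 10-fold), writes the progress curves
and a summary with the activation half-times, and prints what changed.
"""

from btkact.pipeline import RunConfig, run

cfg = RunConfig(
    output_dir="results/kinetics",
    kinetics={"scenarios": ["no_IP6", "with_IP6"], "total0_uM": 1.0,
              "t_max_s": 1e4, "n_points": 501},
)
manifest = run(cfg)

import json  # noqa: E402

summary = json.loads(open("results/kinetics/kinetics_summary.json").read())
t_no = summary["no_IP6"]["t50_s"]
t_ip6 = summary["with_IP6"]["t50_s"]
print(f"dimer Kd without IP6: {summary['no_IP6']['dimer_Kd_M']*1e3:.1f} mM, "
      f"with IP6: {summary['with_IP6']['dimer_Kd_M']*1e6:.0f} uM")
print(f"half-activation time: {t_no:.0f} s without IP6, {t_ip6:.0f} s with IP6")
print(f"ratio {t_ip6/t_no:.3f} — activation speeds up ~{t_no/t_ip6:.0f}-fold even "
      "though at 1 uM both dimer Kd values (2 mM, 200 uM) leave the dimer a "
      "trace species")
print("outputs:", ", ".join(sorted(manifest["outputs"])))
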