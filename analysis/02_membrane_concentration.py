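#!/usr/bin/env python
"""Estimate the effective Btk concentration on a PIP3-containing vesicle.

Evaluates C = f/(A0*L*Na) for 5% PIP3, 60 A^2 per headgroup and a 100 A
membrane-proximal shell, and compares it with the ~2 uM bulk concentration
of the solution assays.
"""

from btkact.pipeline import MembraneStage, RunConfig, run

cfg = RunConfig(output_dir="results/membrane", membrane=MembraneStage(bulk_conc_uM=2.0))
run(cfg)

import json  # noqa: E402

rec = json.loads(open("results/membrane/membrane_concentration.json").read())
print(f"local concentration in the membrane shell: {rec['local_concentration_mM']:.1f} mM")
print(f"vs {rec['bulk_concentration_uM']:.0f} uM bulk: "
      f"{rec['enhancement_factor']:.0f}-fold enhancement")
print("millimolar local concentration exceeds even the 2 mM dimer Kd, so "
      "membrane recruitment alone drives transient dimerization")
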