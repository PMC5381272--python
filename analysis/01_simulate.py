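#!/usr/bin/env python
"""Generate the synthetic study inputs.

Two scalar clamshell-coordinate ensembles (a "glycosylated" condition with
equilibrium closed fraction 0.65 and a "non-glycosylated" one at 0.50, both
with a 333 ns relaxation time, 262/196 trajectories x 2000 frames at
0.2 ns), a toy two-lobe glycoprotein multi-model PDB with a tethered
pseudo-glycan, and 12 replicate glycine dose-response curves per genotype
(EC50 2.28 uM wild-type, 3.43 uM N440Q mutant, 3% noise).

Small outputs go to results/; the full per-frame series (tens of MB) go to
scratch/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SCRATCH, SEED, get_results

results = get_results(stages=("simulate",))

for name, (spec, ens) in sorted(results["ensembles"].items()):
    print(
        f"{name}: {ens.n_traj} trajectories x {len(ens.d[0])} frames, "
        f"closed fraction {spec.closed_fraction:.3f}, relaxation {spec.relaxation_time:.0f} ns"
    )
    ens.to_tsv(SCRATCH / f"series_{name}.tsv")

print(f"toy glycoprotein: {len(results['toy_trajectory'])} models -> {RESULTS}/toy_glycoprotein.pdb")
n = sum(len(v) for v in results["doseresponse_curves"].values())
print(f"dose-response: {n} curves -> {RESULTS}/doseresponse_*.tsv")
print(f"raw per-frame series -> {SCRATCH}/ (seed {SEED})")
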