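"""Positional diagnostics: triplet periodicity and start-proximal depletion.

Footprint midpoints inside coding regions phase with the reading frame;
genes flagged for upstream-ORF-style depletion lose coverage 15-20 nt
before the start codon, quantified by the depletion score (window mean /
5'UTR background mean) and a within-gene permutation p-value.
"""

import numpy as np

from ribostruct import SimulationConfig
from ribostruct.footprints import (
    depletion_score, occupancy_profile, periodicity_profile,
)
from ribostruct.synthetic import simulate_footprints, simulate_transcriptome

cfg = SimulationConfig(n_genes=60, seed=3, depletion_genes=20,
                       utr5_footprints_per_gene=1500)
models, _, truth = simulate_transcriptome(cfg)
fps = simulate_footprints(models, truth, cfg)

prof = periodicity_profile(fps, models)
print(f"{prof.n_reads} in-CDS midpoints; frame fractions: "
      + ", ".join(f"{f:.3f}" for f in prof.frame_fractions))
print("(a frame-0 excess is the signature of genuine translating ribosomes)")
print()

rng = np.random.default_rng(3)
scores = {"flagged": [], "uniform": []}
for g, m in models.items():
    res = depletion_score(occupancy_profile(m, fps[fps["reference"] == g]),
                          m.cds_start_tx, rng=rng)
    if res.score is not None:
        scores["flagged" if truth.at[g, "depleted"] else "uniform"].append(res.score)
for kind, vals in scores.items():
    print(f"{kind} genes (n={len(vals)}): median depletion score "
          f"{np.median(vals):.2f}")
print()
print("A score near 1 means the pre-start window matches the 5'UTR")
print("background; a score near 0.1 reproduces the planted 10x depletion.")
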