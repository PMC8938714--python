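"""Simulate a multi-study case-control cohort with LD-blocked genotypes.

Builds a small synthetic consortium (two training studies, a prospective
study, an external study), prints the realized case/control bookkeeping
and the adjacent-SNV LD, and shows the causal truth record that later
stages try to recover.
"""

import numpy as np

from finerisk import SimConfig, synthio

cfg = SimConfig(seed=7)
panel, truth = synthio.simulate_panel(cfg)
cohort = synthio.simulate_cohort(panel, truth, cfg)

print("study composition (cases/controls):")
for study, grp in cohort.groupby("study"):
    print(f"  {study:10s} {int((grp['status'] == 1).sum()):5d} / "
          f"{int((grp['status'] == 0).sum()):5d}")

first_locus = panel.snvs[panel.snvs["locus"] == "locus01"].index
dos = panel.dosages[:, panel.snvs.index.get_indexer(first_locus)]
adj = np.diag(np.corrcoef(dos, rowvar=False), 1)
print(f"\nadjacent-SNV correlation in locus 1: mean {adj.mean():.3f} "
      f"(configured ld_decay={cfg.ld_decay})")

print(f"\n{len(truth)} causal SNVs (log-OR effects the GWAS should recover):")
print(truth[["locus", "log_or", "maf"]].round(3).to_string())
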