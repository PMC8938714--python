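"""Fine-map one locus from summary statistics plus an LD reference.

Plants two causal SNVs in a 50-SNV autoregressive locus, runs a marginal
GWAS, then recovers the independent signals by stepwise conditional
selection at p < 1e-5 — the same engine used genome-wide in the pipeline.
"""

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from finerisk import assoc, cojo, synthio
from finerisk.containers import DosageMatrix

n, m, beta = 20_000, 50, 0.3
rng = np.random.default_rng(7)
g = synthio._simulate_locus_dosages(n, np.full(m, 0.3), 0.5, rng).astype(float)
snvs = pd.DataFrame({"chrom": "1", "pos": 10_000 + np.arange(m) * 5_000,
                     "effect_allele": "A", "other_allele": "G"},
                    index=pd.Index([f"rs{j + 1:03d}" for j in range(m)], name="snv"))
panel = DosageMatrix(pd.Index([f"I{i}" for i in range(n)]), snvs, g)

causal = [10, 35]
lp = (g[:, causal] - g[:, causal].mean(0)) @ [beta, beta]
alpha = brentq(lambda a: expit(a + lp).mean() - 0.5, -10, 10)
status = (rng.uniform(size=n) < expit(alpha + lp)).astype(int)
cohort = pd.DataFrame({"status": status, "study": "sim"}, index=panel.samples)

stats = assoc.single_snv_assoc(panel, cohort)
ld = cojo.build_ld_reference(panel)
res = cojo.stepwise_select(stats, ld, p_threshold=1e-5)

print(f"planted causal SNVs: {[snvs.index[j] for j in causal]} (log-OR {beta})")
print(f"{(stats.table['p'] < 1e-5).sum()} of {m} SNVs reach p<1e-5 marginally (LD shadows)")
print(f"stepwise selection keeps {len(res.selected)}: {res.selected}")
print(res.joint.round(4).to_string())
print("joint p-values stay below the threshold; shadows are conditioned away")
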