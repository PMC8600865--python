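"""Stratify patients on a gene panel and compare radiotherapy benefit.

Builds a cohort in which a correlated block of prognosis-erasing genes
confines the radiotherapy benefit to the high-expressing patients, clusters
patients on those genes (z-scored, Euclidean, complete linkage), and runs a
within-cluster log-rank of treated vs untreated survival.  Exactly one
cluster showing significant benefit marks it as the radio-sensitive group.
"""

import math

from radscreen import (
    RunConfig,
    apply_eligibility,
    cluster_patients,
    compare_cluster_survival,
    generate_cohort,
)
from radscreen.synthetic import GeneEffectSpec, SyntheticConfig

genes = tuple(GeneEffectSpec.type2(f"B{i}", math.log(1.6)) for i in range(5))
sim = SyntheticConfig(
    n_patients=1200, gene_specs=genes, type2_block_rho=0.9,
    clinical_covariates=(), rt_intercept=0.0, beta_rt=0.0,
    center_carriers=False, seed=4,
)
expr, clin, _ = generate_cohort(sim)
cohort = apply_eligibility(expr, clin, RunConfig(seed=4), sim.schema)

clusters = cluster_patients(cohort, list(expr.index), k=2)
print("cluster sizes:", clusters.sizes)

out = compare_cluster_survival(cohort, clusters, RunConfig(seed=4))
for r in out["per_cluster"]:
    print(f"cluster {r.cluster}: RT-vs-NRT log-rank chi2 {r.statistic:.1f}, "
          f"p {r.p:.3g}")
print("radio-sensitive cluster:", out["rs_cluster"])
# The high-block cluster alone should show a significant treatment benefit;
# the other cluster's treated and untreated curves coincide.
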