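"""Minimum representative subsampling depth and the cohort common depth.

For each of three simulated samples: draw the 100%-to-1% rarefaction curve
(30 replicates per depth), find where the normalized-Gini decline steepens
past gradient 1.1, and take the first qualifying run's largest percent + 1
as the sample's floor.  The cohort depth then maximizes how many samples fit
between their floor and their total reads.
"""

from tcrrecon import (
    RarefactionConfig,
    cohort_common_depth,
    minimum_representative_depth,
    post_transplant_params,
    rarefaction_curve,
    simulate_repertoire,
)

config = RarefactionConfig(replicates=30, master_seed=7)
results = []
for i, total in enumerate((8000, 20000, 5000)):
    sample = simulate_repertoire(
        post_transplant_params(seed=i, total_reads=total), sample_id=f"s{i}"
    )
    curve = rarefaction_curve(sample, config)
    res = minimum_representative_depth(curve, config)
    results.append(res)
    runs = ";".join(f"{r[0]}-{r[-1]}" for r in res.runs) or "none"
    print(
        f"{res.sample_id}: total={res.total_reads:>6}  qualifying runs={runs:<12} "
        f"min {res.min_percent}% = {res.min_depth_reads} reads"
    )

cohort = cohort_common_depth(results)
print(
    f"\ncohort common depth: {cohort.common_depth_reads} reads, "
    f"including {len(cohort.included_sample_ids)}/{len(results)} samples"
)
print(
    "Samples rarefied below their floor would misreport diversity; the common\n"
    "depth is the largest depth that keeps the most samples comparable."
)
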