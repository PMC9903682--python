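"""Per-sample HMM training and Viterbi CNV calling, scored against truth.

A 3-state HMM (loss / neutral / gain, Gaussian emissions on log2 ratios) is
trained per sample on its reference members' mismatched ratios and decoded on
the sample's matched ratios; consecutive non-neutral states become calls.
"""
import pandas as pd

from cnkit.merge import reciprocal_overlap
from cnkit.simulate import default_config, simulate_cohort, true_calls
from cnkit.workflows import call_all, normalize

cohort = simulate_cohort(default_config(seed=7, n_samples=100))
norm = normalize(cohort.coverage, cohort.bait_map, reference_n=30)
calls, models = call_all(norm, max_train_rows=12, max_iter=20, tol=1e-3)

print(f"{len(calls)} calls across {calls['sample_id'].nunique()} samples "
      f"({(calls['state'] == 'loss').sum()} losses, "
      f"{(calls['state'] == 'gain').sum()} gains)")
print(calls.head(5).to_string(index=False))

truth = true_calls(cohort)
hits = 0
groups = {k: g for k, g in calls.groupby(["sample_id", "chrom", "state"])}
for _, row in truth.iterrows():
    g = groups.get((row["sample_id"], row["chrom"], row["state"]))
    if g is not None and any(
        min(reciprocal_overlap((row["start"], row["end"]), (s, e))) >= 0.5
        for s, e in zip(g["start"], g["end"])
    ):
        hits += 1
print(f"recall vs injected truth at 50% reciprocal overlap: "
      f"{hits}/{len(truth)} = {hits / len(truth):.2%}")
m = models[cohort.coverage.sample_ids[0]]
print(f"one trained model: self-transitions {m.A.diagonal().round(4).tolist()}, "
      f"emission sds {m.sds.round(3).tolist()}")
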