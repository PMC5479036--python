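"""Run a whole family as a batch and summarize the predictions.

Batch mode runs each gene independently, then the post-analyses ask two
questions: do predictions made from different starting genes agree (group
merging), and how deep into each genome's e-value ranking do predicted
orthologs reach (rank distribution)?
"""

from orthored import merge_groups, rank_distribution, run_batch, simulate_family

family = simulate_family(seed=7, ancient_duplication=True)
dataset = family.to_dataset()

batch = run_batch(list(dataset), dataset)

report = merge_groups(batch.orthosets)
print(f"queries                : {len(batch.orthosets)}")
print(f"merged groups          : {len(report.groups)}")
print(f"% groups identical to  : {report.pct_identical:.1f}")
print("  a per-query prediction")
print(f"% queries rescued      : {report.pct_genes_rescued:.1f}")

table = rank_distribution(batch.orthosets, batch.initial_hits, dataset)
print("\ne-value rank distribution of predicted orthologs:")
print(table[table["count"] > 0][["rank", "count", "percent"]].to_string(index=False))

# With an ancient duplication the family splits into two merged groups (the
# two copies); each predicted ortholog is its genome's rank-1 hit because
# within-copy similarity beats between-copy similarity.
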