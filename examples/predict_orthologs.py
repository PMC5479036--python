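"""Predict the orthologs of one gene in a family with an ancient duplication.

The simulated family has two gene copies per species, separated by a
duplication older than the species radiation. Similarity ranking alone
cannot tell the copies apart reliably; the gene tree can. The script runs
the full pipeline for one query and compares the prediction with the
simulation's truth oracle.
"""

from orthored import RunConfig, run_single_query, simulate_family

family = simulate_family(seed=42, ancient_duplication=True)
dataset = family.to_dataset()
query = list(dataset)[0]

oset, artifacts = run_single_query(query, dataset, RunConfig())

print(f"query gene          : {query.seq_id}")
print(f"family size         : {len(dataset)} genes in {len(dataset.species())} species")
print(f"initial search hits : {len(artifacts.hits)}")
print(f"cluster of interest : {len(artifacts.cluster)} sequences")
print(f"predicted orthologs : {sorted(oset.orthologs)}")
print(f"true orthologs      : {sorted(family.true_orthologs(query.seq_id))}")

# The prediction should contain exactly the query's own copy: one gene per
# species, and none of the paralogous second copy.
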