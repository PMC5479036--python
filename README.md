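# orthored

Tree-based orthology prediction from per-query reduced datasets.

Orthologs — genes in different species that descend from a common ancestor
through speciation events only — are the currency of comparative genomics:
they anchor phylogenies and point to functionally equivalent genes across
species. Similarity-based shortcuts (e.g. bidirectional best hits) confuse
orthologs with paralogs whenever gene duplication is common. Tree-based
prediction is more faithful to the definition but usually demands cluster-scale
computing. This package takes the middle road: it predicts orthologs for
**one gene of interest at a time**, shrinking the problem to a small
*reduced dataset* so that a full gene-tree analysis runs in seconds on a
laptop.

## The pipeline

For a query gene *q* against a species-labeled protein dataset:

1. **Search** — protein similarity search of *q* against the dataset
   (internal Smith–Waterman engine with BLOSUM62, gap open 11 / extend 1,
   Karlin–Altschul e-values `E = K·m·n·e^(−λS)`; optional `blastp` adapter).
2. **Screen** — keep hits with `E < 10⁻³` that pass a length-dependent
   identity threshold (the twilight-zone curve
   `480·L^(−0.32(1+e^(−L/1000)))`), then at most *n* best genes per species
   (default *n* = 4, all kept on an e-value tie), one isoform per gene.
3. **All-vs-all** — e-value matrix over the reduced dataset; pairs without a
   significant hit are filled with `E = 0.9` so the matrix is total.
4. **Cluster** — Markov clustering on `max(0, −log₁₀E)` weights at the
   deliberately lax inflation 1.2; keep the query's cluster.
5. **Tree** — multiple alignment (center-star internally, `mafft` adapter
   with accuracy-oriented settings below 200 sequences and speed-oriented
   at 200+), then a gene tree: neighbor joining for topology, non-negative
   least-squares branch lengths. The tree is rooted by the outgroup gene
   that maximizes the ingroup-species count of the outgroup-free subtree
   containing *q* (most distant candidate on ties), or at midpoint when no
   outgroup gene is present.
6. **Prune** — branches longer than 2 substitutions/site are cut and the
   query's component kept.
7. **Extract** — each internal node is a *duplication* if its child clades
   share a species, a *speciation* otherwise (single-species clades count
   as one gene with isoforms); speciation ancestors of any duplication are
   overwritten to duplications. The orthologs of *q* are the leaves of the
   daughter clade under the most recent duplication on *q*'s root-ward
   path — the whole tree if there is none. Isoforms of predicted members
   are reintroduced at output.

A synthetic-data module simulates gene families along a species tree with
duplication/loss birth–death events and per-site protein evolution, so the
whole pipeline can be validated against an exact, algorithm-independent
truth oracle (pairwise speciation-MRCA orthology on the true gene tree).

## Worked example

```sh
python examples/predict_orthologs.py
```

```
query gene          : S01|g001
family size         : 10 genes in 5 species
initial search hits : 10
cluster of interest : 10 sequences
predicted orthologs : ['S01|g001', 'S02|g002', 'S03|g003', 'S04|g004', 'S05|g005']
true orthologs      : ['S01|g001', 'S02|g002', 'S03|g003', 'S04|g004', 'S05|g005']
```

The simulated family carries a duplication older than the species
radiation, so every species has two copies of the gene. All ten sequences
are similar enough to end up in the query's cluster — similarity ranking
alone cannot split them — but the gene tree places the duplication at the
root, and the daughter clade containing the query holds exactly the five
true orthologs (one per species, none from the paralogous copy).

`examples/batch_postanalysis.py` runs a whole family as a batch and prints
the group-merging summary and the e-value rank distribution;
`examples/translate_and_screen.py` shows CDS translation and the
similarity screen.

The same functionality is available from a shell:

```sh
orthored simulate --seed 42 --ancient-duplication -o family/
orthored run -d family/family.faa -q query.faa -o out/
orthored compare groups_a.tsv groups_b.tsv
orthored merge groups.tsv
```

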