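# Methods

This note records the models, parameter choices, and numerical decisions
behind the package, and what the validation on synthetic data does and
does not demonstrate.

## Similarity search and statistics

The internal engine computes optimal Smith–Waterman local alignments with
BLOSUM62 and affine gaps (first gap residue −11, each further residue −1,
via Biopython's `PairwiseAligner`; an independent full-table Gotoh
implementation in the test suite confirms the scores). E-values follow
Karlin–Altschul statistics, `E = K·m·n·e^(−λS)`, with the standard gapped
BLOSUM62 parameters K = 0.041 and λ = 0.267, where *m* is the query length
and *n* the total residue count of the database. These e-values are
comparable and strictly monotone in score — which is all the screening,
clustering, and ranking steps consume — but they are not BLAST's exact
numbers: composition-based statistics and low-complexity (SEG) masking are
not implemented. The `blastp` adapter therefore also omits database soft
masking, which would require a separate masking pass when the database is
built; its remaining flags (word size 3, threshold 11, Smith–Waterman
traceback) are the adapter defaults.

In the all-vs-all matrix each unordered pair is aligned once (the local
score is symmetric) and the two directional e-values differ only through
the query length. Directional values are kept as computed; symmetrization
happens only when the clustering graph is built, by taking the better
direction. Pairs that miss the e-value cutoff in a direction carry the
fill value 0.9 in that direction, so the matrix is total.

## Screening

The screen runs in pipeline order: e-value cutoff (default 10⁻³), then
the similarity rule, then per-species top-*n*, then isoform collapse. The
default similarity rule is the length-dependent identity threshold
`480·L^(−0.32(1+e^(−L/1000)))` — 100% for alignments of 11 residues or
fewer, constant beyond L = 450 (≈19.5%) — with L the number of alignment
columns. The curve is the standard device for separating homology from
the twilight zone at short alignment lengths; a user can substitute plain
minimum-length/minimum-identity thresholds.

Top-*n* keeps, per species, every subject whose e-value is at or below
the *n*-th smallest e-value for that species, so an exact tie at the
boundary retains all tied genes and the per-species count can exceed *n*
only through such ties. Isoform collapse keeps the isoform with the best
e-value per gene; an exact tie goes to the alphanumerically smallest
sequence ID. The query's own record is always placed in the reduced
dataset, since downstream steps need the gene of interest in the tree.

## Markov clustering

Edge weights are `max(0, −log₁₀E)` of the better direction; each node
gets a self-loop equal to its maximum incident weight (1.0 for isolated
nodes), the usual MCL regularization. The iteration is dense: column
normalization, matrix squaring (expansion 2), entrywise power (inflation,
default 1.2) with re-normalization, pruning of entries below 10⁻⁸, until
the largest entry change is below 10⁻⁶ or 200 iterations. Clusters are
attractor systems (attractors with positive diagonal, connected through
each other's rows) plus the nodes they attract; a node attracted to
several systems is assigned to the one with the larger total attraction,
ties to the system whose smallest attractor ID sorts first. Inflation 1.2
is deliberately the laxest practical setting: the gene tree, not the
clustering, is the arbiter of orthology, so the clustering should only
remove clear outliers.

## Alignment and tree inference

The internal aligner is deterministic center-star: the center is the
sequence with the highest total pairwise score (ties to the smallest ID),
every other sequence is aligned to it semi-globally (free end gaps), and
the pairwise gap patterns are merged into one master insertion pattern.
The `mafft` adapter switches from accuracy-oriented settings
(`--localpair --retree 2 --maxiterate 1000`) to speed-oriented ones
(`--6merpair --retree 2 --maxiterate 1000`) at 200 sequences; the internal
aligner has a single behavior, so the mode only matters for the adapter.

Tree inference is two-pass, mirroring topology-then-lengths workflows:
neighbor joining (scikit-bio, negative estimates clamped to zero) fixes
the topology, then all branch lengths are re-fit by non-negative least
squares against the distance matrix over all leaf pairs. Distances are
computed from direct pairwise **global** alignments (end gaps penalized):
the mismatch fraction *p* over residue-residue columns is corrected by
the 20-state Poisson formula `d = −(19/20)·ln(1 − (20/19)p)` and capped
at 10 substitutions/site near saturation (also used when a pair shares no
aligned columns, with a warning). Distances are taken pairwise rather
than from the multiple alignment because a center-star MSA anchored in
one subfamily can misalign members of another, and strict global
alignment prevents two unrelated sequences from scoring as close via a
tiny high-identity overlap. Clusters of four or more sequences get a
tree; smaller clusters are reported directly as the prediction (a
singleton cluster yields just the query), with a warning flag.

## Rooting, pruning, labeling

With an outgroup species declared and at least one of its genes in the
tree, rooting follows the subtree-maximization rule: for each outgroup
gene, root on its pendant branch and measure the largest query-containing
subtree free of outgroup genes; the candidate giving the most ingroup
species wins, ties go to the candidate most distant from the query by
path length (the reference point is the query leaf), remaining ties to
the alphanumerically smallest ID. Otherwise the tree is rooted at the
midpoint of the longest leaf-to-leaf path; if every branch is zero-length
the midpoint is undefined and the parent of the alphanumerically smallest
leaf is used, with a warning.

Long-branch pruning cuts every branch above 2 substitutions/site and
keeps the query's connected component. Cutting operates on the unrooted
topology and iterates to a fixpoint: splicing out the degree-2 junctions
left by a cut concatenates branch lengths, which can itself create an
over-long branch. The fixpoint makes pruning idempotent and independent
of where the root happens to sit. If the cuts removed the original root,
the retained subtree is re-rooted (outgroup rule first, midpoint
otherwise).

Event labeling computes species sets bottom-up. An internal node whose
subtree spans one species is a *single-species gene* — treated as one
gene with unlabeled isoforms, never a duplication, contributing a single
species upward. Any other node is a *duplication* when at least two child
clades share a species (the pairwise test generalizes the binary case to
the multifurcations pruning can create) and a *speciation* otherwise.
Every speciation ancestor of a duplication is then overwritten to a
duplication, which makes the duplication set upward-closed — so "the most
recent duplication experienced by the query" and "the first duplication
on the query's root-ward path" coincide; the equivalence is asserted by
an exhaustive oracle test rather than assumed. Extraction returns the
leaves of the daughter clade under that node (the whole tree when no
duplication lies on the path), reports members at gene level, flags
surviving outgroup genes, and reintroduces every isoform of each member.

## Post-analyses

Set identity between two predictions for the same query is the Jaccard
fraction ×100, computed after removing outgroup genes (the tree is rooted
by the outgroup, so its genes are not legitimate predictions); a
comparison where both sets are empty after removal is undefined and
excluded from averages rather than scored zero. Rank distributions count,
for each predicted ortholog, the number of same-species genes with a
strictly better initial-search e-value (exact ties share the best rank);
gene-level e-values are the best over a gene's isoforms, and members
absent from the query's hit list fall in an "unranked" row. Group merging
unions per-query sets that share members (transitively, via graph
connected components) and reports the fraction of merged groups identical
to at least one input set and the fraction of queries inside such groups.

## Synthetic families

The generator grows a gene family along a species tree (default: five
species, ultrametric, tip depth 0.15 expected substitutions/site at unit
rate). Duplication and loss are a birth–death process per lineage with
rates expressed per unit branch length; surviving lineages speciate at
species-tree nodes, and every internal node of the resulting gene tree
records its true event. A random root protein (default 200 residues)
evolves by per-site replacement — a site hit on a branch of length *t*
with probability `1 − e^(−rate·t)` draws a uniform different residue — with
no rate heterogeneity across sites and no indels in the core sequence.
Optional isoforms are near-identical copies with up to 5% point edits and
an occasional short internal deletion. The `ancient_duplication` switch
plants one duplication above the species root with stems of 0.3 per copy,
making inter-copy divergence (≥0.9) at least three times the maximal
intra-copy divergence (0.3) — the regime where a correct tree, not
similarity ranking, is what separates orthologs from paralogs.

The truth oracle is the field-standard pairwise definition — two genes
are orthologs iff their MRCA in the true gene tree is a speciation —
computed from the simulation record, independent of anything the pipeline
does.

What passing these simulations shows: the pipeline's logic (screening,
clustering, tree, rooting, labeling, extraction) is internally correct
and recovers known histories in clean and in adversarially duplicated
families. What it does not show: robustness to the messiness of real
proteomes — domain shuffling, partial genes, heterogeneous rates,
alignment-hostile low-complexity regions, assembly artifacts — none of
which the generator emulates.

## Problem sizes and determinism

Validation runs use five-species families (5 or 10 genes, 200 residues),
50 families per scenario in the test suite and 30 per scenario in the
acceptance script, with oracle batteries of 100–1000 random instances per
property; these sizes make the full validation run in about two minutes
on one CPU while keeping every property exercised at meaningful scale.
All randomness flows through explicit seeds (`numpy.random.default_rng`);
the internal engines contain no unseeded nondeterminism, so identical
inputs and configuration reproduce identical outputs byte for byte.

## Known limitations

* E-values are internally consistent, not BLAST-identical; screening
  outcomes can differ from a BLAST-based run near the cutoff.
* Center-star alignment is crude compared to progressive aligners; the
  pairwise-distance tree engine compensates, but users wanting
  publication-quality alignments should use the mafft adapter.
* Neighbor joining with least-squares lengths is not maximum likelihood;
  for very deep or rate-heterogeneous families an external ML tree is
  preferable.
* Midpoint rooting can mis-orient the tree when the query's family is
  asymmetric in rate; declaring an outgroup species is strongly
  recommended, and queries from the outgroup species itself are refused.
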