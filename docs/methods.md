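# Methods

This note documents the models, assumptions, parameter choices and
numerical details behind `personet`, and what the synthetic study
conditions do and do not establish about real data.

## The analysis in brief

The pipeline asks how genes that are *variably transcribed* across three
personality profiles relate to genes already known to be
personality-associated from genomic studies, given that the two gene sets
need not overlap directly.  The link is made in three moves: (i) find
coherent subject × gene biclusters in the transcriptome; (ii) find the
brain regions in which a bicluster's genes and a genomic-environmental
(GE) gene set are both significantly over-expressed, pairing them into
GET subsets; (iii) build multi-layer interaction networks around each GET
subset's genes, reduce each to its minimum connectivity skeleton, and
study the genes the skeletons share — the control hub — and everything
that hub directly regulates (the temperament-character molecular
integration network, TCMIN).

## Expression preprocessing and group statistics

Expression is handled on the log2 scale throughout; the synthetic
generator emits post-normalization values directly, because every
downstream stage consumes normalized data (raw-intensity simulation and
background correction are out of scope).

*Quantile normalization* maps every subject's value vector onto the
across-subject mean quantile vector; tied values receive the average of
the reference quantiles they span (linear interpolation on average
ranks).  The operation is idempotent to 1e-9.

*Variable-gene selection* ranks genes by variance across all subjects
pooled (ties broken by ascending identifier).  A between-profile variant
(variance of per-profile means) is available behind a flag; pooled
variance is the default reading of "most variable across the three
profiles".

*Bootstrap profile ANOVA*: per replicate, subjects are resampled with
replacement within each profile; each gene's within-profile mean is
computed; a one-way ANOVA is run with genes as observations and profiles
as groups.  This unit-of-analysis choice (genes as observations after
within-profile averaging) is an interpretation, exposed in the API and
recorded here.  Two consequences matter.  First, the per-gene baseline
level is common to all groups, so gene means are highly correlated across
profiles and the F statistic under the null falls *below* the nominal
F distribution's mean; the tests therefore compare planted-versus-null
behaviour against the nominal critical value rather than asserting a
specific null mean.  Second, a profile shift applied to *all* genes would
be removed exactly by quantile normalization (a rank-preserving row
shift), so the generator plants the profile effect on a responsive subset
(1500 genes by default) inside a larger gene pool — which is also the
realistic structure: most transcripts do not respond to the phenotype.

Pairwise effect sizes are point-biserial Pearson correlations between a
0/1 group indicator and the values, with the first-named group coded 0;
negative r therefore means the first group expresses higher.  On the
conventional scale, |r| of 0.20 / 0.50 / 0.80 reads as small / medium /
large.

## Fuzzy NMF biclustering

The biclustering stage factorizes X ≈ WH (W, H ≥ 0) by standard
multiplicative updates minimizing the Frobenius reconstruction error,
from a seeded uniform random initialization, stopping when the relative
objective decrease falls below `tol` (default 1e-6) or at `max_iter`.
The objective trace is monotone non-increasing (asserted to 1e-8 per
step in the tests).  Fuzzy memberships are obtained by normalizing the
rows of W (subjects) and the columns of H (genes) to sum to one over the
k factors; a bicluster keeps the members whose normalized membership
reaches the threshold, default 1/k (exceeding a uniform spread).
Subjects and genes may belong to several biclusters.

Two numerical choices:

- Inputs containing negative values are shifted by the global minimum
  (recorded on the result) to satisfy non-negativity.
- Before factorization the pipeline removes each gene's mean across
  subjects (`bicluster.center_expression`).  Absolute log2 intensity is
  dominated by a per-gene baseline that otherwise soaks up factor
  capacity; centering leaves the subject × gene co-variation that
  biclusters are made of.  On planted data with block effect equal to
  twice the noise standard deviation, mean gene-assignment adjusted Rand
  index over 10 seeds is ≥ 0.8 with centering (≈ 0.65 without).

An optional consensus mode averages memberships over several seeded runs
(factors aligned by gene-membership correlation) before thresholding; the
default is a single seeded run, which is auditable and deterministic.
Model-order selection is out of scope; k is fixed (default 7).

## Brain-region colocalization

For a gene set, the score in a region is the arithmetic mean of the
set's atlas rows.  Significance of over-expression is assessed one-sided
by permutation: `n_perm` random gene sets of identical size are drawn
from the atlas without replacement, and
p = (1 + #{null mean ≥ observed}) / (1 + n_perm), floored at
1/(n_perm+1).  Correction across regions is Bonferroni by default
(Benjamini-Hochberg available), and adjusted p never falls below the
empirical p.  Under a null atlas the empirical p-values are uniform
(Kolmogorov-Smirnov check in the acceptance suite).  The upstream tool
this stage emulates does not publish its exact normalization and
significance machinery; the permutation scheme here is a stated
stand-in.  Optional per-gene z-scoring across regions is off by default
(the input atlas is assumed already normalized).

A GET subset is emitted for every (bicluster, GE-set) pair whose
significant regions intersect; its gene payload is the union of the
pair's genes with provenance retained.  The gene sets themselves may be
disjoint — that is the point of the construction.

## Networks, minimum networks, and the hub

Interaction tables carry typed edges on three layers (`ppi`, `tf_gene`,
`mirna_gene`); self-loops are dropped, duplicate (source, target, layer)
rows collapsed, and miRNA-gene edges must have a miRNA endpoint.  Edges
are undirected for connectivity; regulatory direction is metadata only.

`build_network` is strictly first-order: seeds, nodes adjacent to a
seed on the requested layers, and all edges among the included nodes.
Seeds missing from the interaction universe are kept as isolated seed
nodes with a warning.

`minimum_network` prunes non-seed nodes greedily: iterate non-seed nodes
in ascending degree (ties: ascending betweenness centrality, then
ascending identifier) and delete a node whenever its removal does not
increase the number of connected components containing at least one
seed; repeat to a fixed point.  The rule is deterministic, conserves
seeds, and on every graph small enough for exhaustive subset
enumeration (≤ 12 nodes in the test suite) the retained connector set is
minimal — removing any single retained connector would split a seed
component.  The upstream service's internal algorithm is unpublished;
this greedy rule is the package's determinism contract, bounded by the
brute-force oracle.

`merge_networks` takes node/edge unions (seed status is sticky,
conflicting biotypes are an error, provenance lists contributing
networks) and is associative and commutative on node/edge sets.
`shared_hub` partitions the node intersection of two networks by
biotype.  The pipeline refines this for hub detection: the control hub
is the shared *connectors* of the two minimum networks, because fuzzy
biclusters share seed genes by construction (overlapping memberships),
whereas the hub of interest is the set of genes that network analysis
introduced into both.

## TCMIN: hub expansion, modules, analytics

`expand_hub` collects all direct interactors of the hub on the
miRNA-gene and PPI layers.  By default only hub-interactor and hub-hub
edges are kept (a hub-centric star), matching an expansion that queries
only hub interactions; a flag retains the full induced subgraph.

Regulator-signature modules: with hub miRNAs ordered (m1, m2, m3),
M1 = {m1,m2}, M2 = {m2,m3}, M3 = {m1,m3}, M4 = {m1,m2,m3},
M5 = {m2}, M6 = {m3}, M7 = {m1}; each non-hub gene goes to the module
matching exactly its set of hub-miRNA regulators, so M1–M7 partition the
miRNA-targeted genes.  M8–M10 collect the miRNAs attached to each hub
protein in hub order; a miRNA attached to several hub proteins is
assigned to all of them and flagged (the source analysis does not
address this case).  Genes with neither a miRNA signature nor a
hub-protein edge are reported as unassigned, not an error — in the
replication universe these are the 17 PPI-only partners of the hub
proteins.

Eigenvector centrality is computed by power iteration on A + I within
the largest connected component, normalized to max = 1; the diagonal
shift makes the dominant eigenvalue strictly largest in magnitude on
bipartite graphs (hub-centric stars are bipartite) while leaving the
eigenvectors unchanged.  Agreement with a dense eigendecomposition is
1e-6 on 50-node graphs.  Nodes outside the largest component score 0 and
are flagged.  Clustering coefficients and Louvain community detection
(seeded, with modularity Q) come from networkx.

`extend_with_lncrna` walks the lncRNA interaction layer breadth-first
from the personality-associated lncRNAs and adds every reachable
non-lncRNA gene; the lncRNAs themselves act as the linking layer and are
not counted as network genes (consistent with an extended composition
that lists no lncRNA biotype).  The number of interactions reported is
the count of edges incident to a personality lncRNA.

## Enrichment statistics

Annotation enrichment uses the 2×2 table
[[in-member, not-in-member], [in-background, not-in-background]] with a
Pearson chi-square without continuity correction plus a two-sided Fisher
exact test.  The background for LLPS enrichment defaults to the
configured genome universe (61,035 in the replication profile) rather
than the expression-array universe; both modes are available.
Percentages are reported raw and rounded the way headline figures are
printed (integer for large fractions such as 39%, one decimal for 15.7%
or 59.0%, two decimals for 0.12%).

## Synthetic study conditions

Defaults of `SynthConfig` are the replication conditions: 459 subjects
split 125 creative / 241 organized / 93 unregulated; 34,602 genes with
1500 responsive; k = 7 biclusters (150 genes × 150 subjects each,
disjoint in genes, overlapping in subjects); profile shifts 0.6 / 0.3 /
0.0 log2 units on responsive genes; noise sd 0.5 log2 units (typical
residual variability for normalized microarray data); bicluster effect
1.0 (twice the noise sd).  The interaction universe plants a hub of
3 miRNAs (mir-A/B/C) + 3 proteins (prot-A/B/C) whose signature targets
number 122/80/67/8/2413/577/708 (M1–M7), with the 38 pseudogenes and 35
other ncRNAs allocated inside the M5 block and 17 PPI-only protein
partners, giving 4190 direct interactors of which 3919 are
protein-coding; protein-attached miRNA clusters of 65/64/69; a
personality-lncRNA layer of 20 lncRNAs, 102 interactions and 186
extension genes reaching 4376; 129 of 972 personality genes planted
among the targets, with 5 of 6 switch genes in M5 and one in M1.
Identifiers are plain synthetic symbols; no claim of real gene identity
is made.  The atlas is gamma(4, 1) expression over 30 regions with
planted per-set region shifts.

The `small` fixture profile (60 subjects, 400 genes, 12 regions) is a
minutes-scale version of the same structure for end-to-end runs; its
region-enrichment shift is 3.5 so that 10-gene sets remain family-wise
significant across 12 regions at n_perm = 500 (the generator's
construction contract: planted enrichment must be detectable).  The
`paper_scale` profile writes the interaction-universe fixtures and the
459-subject labels; the full-size expression matrix is generated in
memory through the API when needed rather than serialized, since no
network-scale stage consumes it from disk.

What the synthetic conditions do *not* emulate: probe-level microarray
noise, batch effects, sex-chromosome structure, realistic gene-gene
correlation beyond the planted blocks, database-derived interaction
topology (degree distributions are by construction hub-centric), and
real brain-region covariance.  Passing tests therefore demonstrate that
the algorithms recover the structures they are designed for under
controlled conditions — not that the biological findings would replicate
on new cohort data, which remain access-restricted.

## Problem sizes used in tests and the acceptance script

Stochastic components are exercised at reduced but statistically
meaningful sizes chosen by the package: bicluster recovery on 90 × 210
matrices over 10 seeds; permutation-uniformity at 200 replicate gene
sets × 300 permutations; the bootstrap ANOVA on a 459-subject,
6000-gene cohort with 1500 responsive genes and 20 bootstrap
replicates; minimum-network enumeration on graphs of ≤ 12 nodes.  The
network-scale arithmetic (82/6/4190/4376 and the module sizes) runs at
full replication scale, where it takes well under a minute.

## Known limitations

- The FNMF stage is a single seeded run by default; consensus over
  restarts is available but not the default, and no model-order search
  is performed.
- The permutation colocalization is a documented stand-in for the
  unpublished upstream significance machinery.
- The greedy minimum-network rule is one deterministic realization of
  "essential non-seed genes"; other minimal connector sets can exist
  (the oracle asserts minimality, not uniqueness).
- The bootstrap ANOVA's genes-as-observations design yields conservative
  null behaviour (F below nominal) because gene means share baselines
  across profiles.
- Multi-protein miRNAs are multi-assigned across M8–M10 with a flag
  rather than resolved.
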