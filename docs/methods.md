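# Methods

## Correlation graphs

The similarity between two genes is the Pearson correlation of their
log-ratio profiles over *pairwise-complete* samples (samples where both
genes were measured). By default the absolute value |r| is used, since
strongly anti-correlated genes are as biologically linked as correlated
ones; `signed=True` keeps the sign for methods that need it. Two rules
guard against spurious similarity:

- pairs sharing `min_shared` (default 5) or fewer measurements are set
  to 0 — a correlation estimated from five points is noise;
- pairs where either gene has zero variance on the shared samples are
  set to 0 rather than NaN, so constant genes simply never form edges.

Hard thresholding at *t* ∈ (0, 1] keeps edge (i, j), i ≠ j, iff
corr[i, j] > *t*. The strict inequality is a convention (configurable via
`strict=False`); self-correlations are never edges, so threshold graphs
are simple. Edge sets are nested: raising *t* can only remove edges.

## Clique machinery

**Maximal cliques** are enumerated with Bron–Kerbosch using degeneracy
ordering for the outer loop and pivoting inside. On hard-thresholded
correlation graphs — sparse globally, dense within modules — this keeps
recursion depth bounded by the degeneracy. All vertex scans are in sorted
order and the output is sorted lexicographically by membership, so
results are reproducible across runs and platforms. Because the number of
maximal cliques can grow exponentially, enumeration carries a cap
(default 10^6); exceeding it raises `CliqueCapExceeded` rather than
silently truncating.

**Maximum clique** is selected from the maximal cliques, breaking size
ties by the lexicographically least sorted membership. The tie-break is
not cosmetic: paraclique's output depends on which core is chosen, and a
fixed rule makes it deterministic.

**Paraclique** semantics are pinned down as follows: take the maximum
clique of the working graph as the core; scan non-members in
lexicographic order and admit the first vertex with at most `glom`
non-neighbours among the *current* members; restart the scan after each
admission; stop at fixpoint; emit, delete the members, and repeat while
the residual maximum clique has at least `min_core` (default 3) vertices.
Successive paracliques are therefore vertex-disjoint. Two consequences
worth knowing: (a) admission is judged against the member set at
admission time, so an early member may end up missing more than `glom`
edges to the final set — the invariant that *does* hold, and that the
tests assert, is that every member misses at most `glom` edges to the
round's core, since the core is a subset of the member set at every
admission; (b) with `glom = 0` the rule admits only vertices adjacent to
every member, i.e. the paraclique stays a clique.

**k-clique communities** are computed from maximal cliques: every maximal
clique of size ≥ k seeds a union–find, cliques merge when they share
≥ k−1 vertices, and each component contributes the union of its cliques.
This is equivalent to percolating over individual k-cliques (adjacent iff
they share k−1 vertices): any two overlapping k-cliques lie inside
maximal cliques whose intersection is at least as large, and conversely a
maximal clique of size ≥ k is itself a percolation-connected set of
k-cliques. The test suite verifies the equivalence against a direct
k-clique oracle and against networkx's independent implementation. A k
above the maximum clique size yields an empty clustering, not an error;
k = 2 (a debug mode behind `_debug_min_k`) reduces to connected
components.

## QT Clust and CAST

QT Clust operates on a dissimilarity matrix, by default 1 − |r| so the
"diameter" parameter lives on the familiar correlation scale. For every
seed gene a candidate cluster grows by adding the gene with the smallest
maximum dissimilarity to current members (lowest index on ties) while the
cluster diameter stays within `max_diameter`; the largest candidate is
emitted (earliest seed on ties), its genes removed, and the process
repeats. The output is a partition; trailing singletons are legitimate.

CAST uses summed |r| affinities. A cluster opens with the unassigned gene
of maximum total affinity to the other unassigned genes; the loop then
alternates adding the highest-affinity unassigned gene while its affinity
is ≥ t·|C| and removing the lowest-affinity member while its affinity to
the *other* members is < t·(|C|−1); a member's own self-similarity never
counts. Ties go to the lowest gene index. The add/remove loop can in
principle oscillate; a generous iteration cap (200·n) closes the cluster
in that case. These micro-choices (seeding, self-exclusion, tie order)
are fixed for determinism — published CAST implementations differ here,
so agreement with other software is expected at the score level, not the
membership level.

k-means (10 restarts, seeded) and the hierarchical agglomerations (Ward,
average, complete, McQuitty = weighted linkage) are thin adapters over
scikit-learn and scipy on Euclidean distances of mean-imputed expression
rows; their internals are deliberately not reimplemented. No
self-organising-map backend is available, so the SOM adapter raises a
capability error; SOM results can still be scored via
`import_membership`.

## Scoring and comparison

Per cluster, every category of each annotation source is examined:
categories sharing fewer than `min_match` (default 2) genes with the
cluster are skipped (a single shared gene is not evidence of anything),
and cluster genes outside the source's universe are ignored. For a
qualifying category, TP = shared genes, FN = annotated genes missing
from the cluster (counted genome-wide within the source), FP =
universe-restricted cluster genes without the annotation, and the score
is TP/(TP+FP+FN) — the Jaccard similarity of the restricted cluster and
the category. The best category wins (lexicographic tie-break; when
several sources are scored, the earlier-listed source wins exact ties).
No multiple-testing correction is applied: these are descriptive
similarity scores, not enrichment p-values.

Clusters are stratified by size — small 3–10, medium 11–100, large
101–1000 genes; clusters outside all bins are not scored (bins are
configurable via `--bins`). AT5 is the mean of the top five Jaccard
scores in a bin for one parameter setting; with fewer than five clusters
the available scores are averaged and flagged as under-filled, and an
empty bin yields an absent value rendered 0.0 in summary tables. BAT5 is
the maximum AT5 over the sweep (first parameter wins ties). Quartile
ranks use competition ranking (ties share the better rank) and
q = ceil(4·rank/M) for M ranked methods; a method's average quartile is
taken over the bins it populated, so a method that never produces large
clusters is not penalised in the average for the empty cell. Note the
formula's small-M edge: with two methods the better one lands in
quartile 2.

The prominent-annotation consensus selects every category that was some
cluster's best match with Jaccard strictly above `cutoff` (default 0.25)
in any run, then averages each method's best score per selected category
(0 when the method never matched it).

Variation of information is computed from the joint membership
contingency table with natural logarithms (nats): VI = H(A) + H(B) −
2·I(A;B). It requires disjoint clusterings (overlapping methods raise a
"not applicable" error) and is evaluated over the intersection of the two
covered gene sets; `include_unclustered=True` instead pools each
clustering's uncovered genes into a pseudo-cluster over the union.
Values within 10⁻¹² of zero are snapped to exactly 0.0 so identical
partitions compare equal to 0.00.

## Synthetic data

Each planted module shares one latent standard-normal per-sample profile;
member genes are latent + N(0, σ²) noise, giving expected within-module
correlation 1/(1+σ²). The generator takes a target `within_module_corr`
r and derives σ = sqrt((1−r)/r), or accepts σ directly. Background genes
are independent noise; entries are masked missing uniformly at random
(never an entire gene). Annotation categories mirror the modules, with
`annotation_noise` controlling the fraction of each category's genes
swapped for background genes. The latent-factor construction scales as
O(genes·samples), unlike an explicit covariance draw.

What the generator does *not* emulate: correlated noise between modules,
sample-level structure (strains, time courses, batch effects), heavier
tails of real log-ratios, or the exponential size distribution of real
annotation databases. Passing the planted-module recovery tests therefore
shows the algorithms are implemented correctly and are sensitive under
idealised co-expression; it does not certify performance on real
compendia.

Default study conditions: 250 genes × 52 samples with modules of 8, 40
and 120 genes (one per evaluation bin) at r ≈ 0.9 and 2% missingness.
The bundled worked fixture is smaller — 60 genes × 12 samples, modules of
5/15/30 — and uses r = 0.95: with only 12 samples the sampling spread of
r around 0.9 is wide enough that a threshold-0.8 graph would
unpredictably lose within-module edges, whereas at 0.95 the fixture's
recovery is stable across the whole 0.75–0.85 threshold sweep. The
fixture is regenerated deterministically from a frozen spec (seed
20120625) on every call.

## Sweeps, reports, determinism

Default grids: CAST thresholds 0.50–0.975 in steps of 0.025 (20 values);
QT diameters 0.05–1.00 in steps of 0.05; maximal clique at 21 thresholds
0.80–0.90; paraclique thresholds {0.5, 0.6, 0.7, 0.8} × glom
{1, 3, 5, 7, 9}; k-clique communities at thresholds {0.80, 0.85, 0.90}
with eight k values spread between 3 and each threshold graph's maximum
clique size; cluster-count methods at average sizes spanning 10–100 and
100–500. The sweep driver writes one cluster-list file per setting plus a
manifest (method, parameters, input content hash, seed, timestamp) and
skips already-computed settings on re-runs unless forced.

Everything downstream of a fixed seed is deterministic: cluster lists and
report tables regenerate byte-identically. Report tables are plain TSV
with fixed float formatting; the VI table states its units (nats) in its
column names.

## Known limitations

- Exact clique enumeration is exponential in the worst case; the clique
  cap turns blow-ups into errors, but very dense graphs (low thresholds
  on large gene sets) remain out of reach by design.
- The pairwise join over maximal cliques in clique percolation is
  quadratic in the number of cliques; fine at threshold-graph densities,
  wasteful far below them.
- QT Clust is O(n³)–O(n⁴) as specified (a candidate cluster per seed per
  round); it is vectorised but not algorithmically accelerated.
- CAST membership output is sensitive to its tie rules; compare CAST runs
  across implementations by score, not by membership.
- Paraclique's minimum core size and stopping rule are set to
  `min_core = 3`; published paraclique outputs using other conventions
  will differ.
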