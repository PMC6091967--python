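# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `coidiet`. It is the reference for *why* the pipeline
behaves the way it does; the README covers *how* to run it.

## Preprocessing

**Primer trimming and length filter.** The forward primer (default: the
26-bp universal COI minibarcode forward primer, IUPAC codes honored)
must match the 5′ end of a read with at most one mismatch; matched reads
are clipped, unmatched reads are dropped rather than passed through
untrimmed, on the grounds that a read without a recognizable primer is
unlikely to be a clean amplicon. Reads shorter than `min_trimmed_len`
(default 124 bp) after clipping are discarded. Quality scores are parsed
but not used: the protocol this pipeline models controls error by
abundance (clustering + cluster-size floor), not by per-base quality.

**Divergence measure.** Two sequences' divergence is the Hamming
distance over their common prefix plus their length difference.
Minibarcode amplicons are near-fixed-length, so an ungapped comparison
with a length penalty is an adequate stand-in for alignment-aware
distance; whether indels should count toward the divergence budget is
genuinely underdetermined at this locus, and the convention here is the
simplest deterministic one.

**Greedy clustering.** Unique sequences are visited in order of
duplicate multiplicity (descending), ties by first occurrence; each
joins the first-founded cluster whose *representative* (founding
sequence) is within `max_cluster_div` (default 3) mismatches, else
founds a new cluster. This "first matching cluster wins" rule plus the
fixed visiting order makes the output a pure function of the input —
there is no randomness anywhere in the analysis path. Clusters of fewer
than `min_cluster_reads` (default 11, i.e. ≤ 10 reads dropped) are
removed before anything else sees them.

**Chimera (bimera) detection.** Clusters from all samples are pooled —
samples amplified together can form cross-sample chimeras — and
candidates are tested in ascending abundance. A candidate C may be
explained by parents P with `n_reads ≥ 2 × C.n_reads` (abundance skew
2.0). C is flagged iff some ordered parent pair and breakpoint (both
segments ≥ 20 bp) yields a spliced model that (a) beats the best
single-parent divergence by ≥ 3 mismatches and (b) is itself within the
clustering divergence (3) of C. Condition (b) matters: a true bimera
differs from its spliced model only by sequencing error, and without the
cap, optimizing the breakpoint over many unrelated abundant parents
will, by chance, "explain" genuinely divergent clusters (contaminants,
rare prey) and delete real signal. The parameter values follow the
spirit of the standard de novo chimera detector's defaults. Flagged
clusters are kept in reports but excluded from identification.

## Reference database

The reference consists of a fixed-column alignment, a rooted tree with
branch lengths in expected substitutions/site whose leaves match the
alignment rows, and a species → (genus, family, order, phylum) taxonomy.
On load, rows without taxonomy and rows whose label is an untagged
"Genus sp." placeholder are dropped and pruned from the tree (tagged
labels such as "Habroleptoides sp. SC2014" are species-level and kept).
Any leaf-set mismatch that survives reconciliation is an error naming
the offenders, not a warning.

**Outlier threshold.** The identification threshold is an empirical
quantile (default q = 0.999) of the terminal branch-length distribution
of the reference tree, computed by linear interpolation between order
statistics (the type-7 estimator; the estimator is configurable since
published quantiles rarely state one). The logic: a query that truly
belongs to a taxon in the tree should attach with a pendant branch no
longer than the longest terminal branches already present; queries
beyond the 99.9% quantile look like nothing in the reference.
`flag_long_branches` reports reference leaves above a threshold as
curation candidates but never prunes automatically.

**Query alignment.** Queries are aligned against a per-column
nucleotide profile of the reference with the reference columns frozen
(global dynamic programming; match score 2f−1 for column frequency f, N
scoring 0; skipping a column costs in proportion to its occupancy;
query bases with no column — insertions relative to the reference — are
discarded and counted). Freezing the columns keeps the tree and
alignment coordinates valid for placement, avoiding the whole-dataset
realignment a general aligner would do. A query is *unalignable* only
when it is uninformative (under 50% A/C/G/T) or scores below what a
random nucleotide string would (−0.6 per informative base): divergent
homologs must pass, because judging them is the pendant-length filter's
job, not the aligner's.

## Placement model

**Substitution model.** JC69 by default; GTR (6 exchangeabilities +
base frequencies, eigendecomposition of the π-symmetrized rate matrix,
branch lengths normalized to expected substitutions/site) is available.
At 124–130 bp and with a fixed guide tree, the model choice moves
placements negligibly, so the simpler model is the default. Gaps, N and
other ambiguity codes are missing data (marginalized).

**Likelihood machinery.** Standard pruning (inside) conditionals toward
the leaves and outside conditionals away from each edge are precomputed
once per reference with per-site rescaling. For an edge split into a
distal part d_v and remainder d_u, the per-site likelihood of the tree
with a query q attached by a pendant branch t is

    L_s = Σ_x π_x [P(d_v) D_v]_sx [P(d_u) A_v]_sx [P(t) q]_sx

(time-reversibility lets the root move to the attachment point), so each
query costs one 4-vector product per edge per likelihood evaluation.

**Optimization.** The attachment point sits at the edge midpoint by
default (the fast heuristic used by placement tools); full
(pendant, distal) optimization is behind `optimize_distal`. The pendant
length is maximized by bounded scalar optimization on [0, 5]
substitutions/site (beyond saturation for a 4-state model) to an x-tol
of 1e−6, with the boundary value t = 0 checked explicitly. Per-edge
log-likelihoods are normalized into like-weight ratios (softmax), which
sum to 1 per query by construction. Ties sort by smallest edge number.
Reference branch lengths are trusted as given — no re-estimation —
matching the fixed-guide-tree design. jplace output reports entries in
LWR-descending order until the accumulated LWR reaches 0.999; the
`distal_length` field is the distance from the attachment point to the
edge's child (distal) node.

## Identification

The verdict is three-way: *identified* iff the best placement's pendant
is strictly below the threshold ("shorter than"; a pendant exactly at
the threshold is an outlier), *outlier* otherwise, *unalignable* when
no placement exists. The filter deliberately uses pendant length rather
than LWR: a short pendant says the query belongs somewhere in the tree
even when the exact edge is uncertain, which is the right acceptance
criterion when results are interpreted as OTUs rather than confirmed
species. The OTU label is the leaf closest to the attachment point by
patristic distance (the pendant edge itself is ignored; exact ties
break lexicographically). Queries whose reported placements' nearest
leaves span more than one taxonomic order are flagged, but only the
best placement is used downstream.

The ID score compares the tree label with two database labels: each of
the three unordered pairs scores 6 / 5 / 3 / 1 for same species / genus
/ order / phylum, else 0; the ladder skips the family rank, so
congeners-in-law (same family, different genus) score 3. Absent labels
score 0 in their pairs, keeping the 0–18 range interpretable with fewer
than three identifications. A label missing from the taxonomy still
scores at genus level via its first token (logged). Database hit
filtering keeps hits with percent identity ≥ the cutoff (97 or 98 in
the motivating study), inclusive at the boundary.

## Diversity statistics

OTU tables sum the read counts of identified clusters per sample and
label; outliers contribute nothing. "% target" divides identified-read
totals by the sample's total read count before any filtering. Shannon
H′ uses natural log by default (configurable to log2/log10): the index
is conventionally cited without a base, and the choice is documented
rather than inferred. Jaccard on presence sets is undefined (reported
missing) only when both sets are empty. Group comparisons report
per-group means, medians and Tukey box-plot statistics, with a
two-sided Mann–Whitney rank-sum P-value (normal approximation, tie
correction, no continuity correction); the motivating study never names
its test, so these P-values are descriptive, not a reproduction.
Composition tables group OTUs by order, with Chironomidae split out of
Diptera as is conventional for freshwater diet data.

## Synthetic data

The generator emulates the study's inputs at desk scale:

- **Reference**: a Yule tree (birth rate 10.0/unit by default, giving
  root-to-tip heights near 0.4 substitutions/site for 50 species —
  congener-to-ordinal divergences comparable to a real COI minibarcode
  reference); since the constant-rate generator stops at the n-th
  speciation, every tip is extended by the waiting time to the next
  (discarded) speciation so terminal branches stay positive. Sequences
  evolve by JC69 from a uniform-random root; any two species that end
  up with identical minibarcodes are nudged apart by single-site edits,
  because a curated species-level reference is diagnosable by
  construction. Taxonomy derives from clades: orders are the deepest
  ~n/12 clades, genera are shallow clades of ≤ 3 leaves, families pair
  genera.
- **Samples** (defaults: 1000 reads, 0.5% per-base substitution error,
  10% contaminants, 5% chimeras): target reads are multinomial draws
  from the species mixture; contaminants evolve from an outgroup 1.5
  substitutions/site beyond the reference root — generated
  phylogenetically rather than as random strings so they stress the
  pendant filter the way real decomposer/eDNA sequences do; chimeras
  splice two reference templates at a random interior breakpoint. The
  forward primer is prepended so trimming applies. Every read carries a
  truth record (origin and source), and all generators are
  deterministic given their seed.

What the simulation does *not* model: quality-score error profiles,
indel sequencing errors, PCR abundance bias, and the taxonomic
patchiness of real reference databases. Passing the recovery tests
therefore demonstrates correctness of the algorithms under clean
substitution-only noise, not field performance on real fecal libraries.

## Validation problem sizes

The test suite validates against independent oracles at sizes chosen to
make brute force exact: clustering against a plain-loop restatement
(30 reads), bimera flags against exhaustive parent-pair × breakpoint
search (50 clusters), placement against an exhaustive
edge × pendant-grid search with an independently coded pruning
likelihood (4 taxa, 200 columns, grid step 0.001), nearest-leaf labels
against Dijkstra on the tree graph, and quantiles against R's type-7
estimator. End-to-end recovery runs 50-species references with
1000-read samples over three seeds, requiring ≥ 95% correct-genus
identification of target clusters, ≥ 90% contaminant rejection, and
Spearman ρ > 0.8 between estimated and true mixture compositions.

## Known limitations

- Placement evaluates every edge; no candidate-edge preselection, so
  very large reference trees (10⁴+ leaves) would need batching.
- The pendant filter inherits the reference's coverage: prey absent
  from the tree are rejected as outliers, not discovered.
- Midpoint attachment slightly underestimates the likelihood relative
  to full 2-D optimization; the flag exists where the difference
  matters.
- The profile aligner assumes globally colinear queries (no
  rearrangements), which is safe for a 130-bp amplicon.
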