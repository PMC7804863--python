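# Methods

This note documents the models and procedures implemented in `gcfkit`,
the parameters that matter, the numerical conventions, and what the
synthetic data generator does and does not emulate.

## Feature model

A BGC is represented as a sparse integer vector over a fixed global
column order: all biosynthetic (including core) model names in
lexicographic order, followed by all sub-Pfam model names in
lexicographic order.  The column order is frozen when a model store is
created and serialized with it; query-time vectors are projected onto
the stored columns, and columns unknown to the store are dropped with a
warning rather than silently shifting the space.

**Biosynthetic presence columns.**  CDS translations are scanned with
pyhmmer against every biosynthetic/core profile.  Hits are filtered at
the profile's gathering cutoff (sequence and domain level, exactly as
HMMER applies bit-cutoff filtering); a model's column is 255 if it hits
anywhere in the BGC and 0 otherwise.  Copy number is deliberately not
encoded — two BGCs with one and five ketosynthase domains look the same
in this block.  This is a known representational limitation: families
whose chemistry is driven by domain copy-number variation (common among
NRPS loci) or by precursor-peptide sequence variation (most RiPPs)
carry few informative columns and tend to aggregate.

**Sub-Pfam fingerprint columns.**  Each core-domain hit instance spans
a protein subsequence (its envelope); that subsequence — not the whole
protein — is scanned against only the sub-Pfam models of that core
domain.  All hits with positive bitscore are candidates.  Within an
instance, hits are sorted by descending bitscore (ties broken by model
name for determinism), and the first `top_k` (default 3) receive the
value `round(255·(K−r+1)/K)` for 1-based rank `r`; for K = 3 the
attainable values are exactly {255, 170, 85}.  Instances within a BGC
combine by column-wise maximum.  Values are stored as integers, and no
scaling or normalization is applied before distance computation: all
distances in this package are plain Euclidean distances on the raw
0–255 values, which is what makes thresholds in the hundreds
meaningful.

The encoding is order-free: permuting a BGC's genes leaves its vector
unchanged.  Gene synteny is intentionally not represented.

## Sub-Pfam model construction

`build_subpfam_models` splits an aligned core-domain family into clade
profiles: pairwise distance = 1 − fraction of identical residues over
mutually non-gap alignment columns, average-linkage hierarchical
clustering, tree cut to exactly `n_clades` clades (every clade, even a
singleton, yields a profile built from its sub-alignment).  The clade
count is a user parameter; for real domain families something in the
range of 10–100 clades per core domain is sensible, while toy libraries
use whatever the test calls for.  Average linkage was chosen to match
the package's other tree analyses (the atlas phylogram); the identity
distance is the simplest alignment-respecting metric and is also what
the clade-recovery tests verify against by brute force.

## Threshold calibration

`calibrate_threshold` estimates the clustering threshold *T* as the
mean, over `n_batches` = 100 batches, of the *X*th percentile (default
*X* = 1) of all pairwise Euclidean distances within a batch of
`batch_size` = 1000 rows.  Sampling is without replacement within a
batch (the whole matrix when it is smaller than the batch size) and
independent across batches, so rows may recur between batches; the
original sampling scheme's replacement convention is not documented
anywhere, so this choice is recorded here rather than asserted as
canonical.  Percentiles use numpy's default linear interpolation.

A consequence worth knowing at small scale: when more than *X*% of all
pairwise distances are zero (e.g. planted families of feature-identical
members), the calibrated *T* is exactly 0, and clustering degenerates
to exact-duplicate grouping.  That is the regime the parameter-recovery
tests run in; with larger, noisier collections the percentile lands in
the low tail of the within-family distance distribution, which is the
intended operating point.

## GCF model construction (flat-tree BIRCH)

Rows are scanned once, in lexicographic bgc_id order (the algorithm is
order-dependent, so a fixed order is required for determinism; the
choice of lexicographic order is this package's convention).  Each
subcluster keeps the BIRCH clustering features (count, linear sum,
squared norm sum).  For each incoming row the nearest subcluster by
centroid distance is found by exhaustive linear scan — the "flat tree"
with branching factor ≥ n_samples — and the row is absorbed iff the
subcluster's RMS radius after absorption,
`sqrt(SS/n − ‖mean‖²)`, stays ≤ *T*; otherwise the row seeds a new
subcluster.  Centroids are exact member means in double precision.
There is no node splitting, no rebuilding, and no global refinement
pass.  The admission rule is by radius (not diameter); scikit-learn's
BIRCH implements the same rule and is used as an independent
cross-check in the tests, never as the implementation.

BGCs whose vectors are all zero (no recognized domains) are kept and
clustered like any other row — they co-locate in one low-information
GCF — and a warning lists them.  Training on an empty matrix (e.g.
everything was filtered as fragmented) raises immediately.

## Membership and categories

`assign_membership` computes Euclidean distances from every BGC to
every centroid and keeps the *N* smallest (default 3), ties broken by
gcf_id.  The best-hit distance is categorized boundary-inclusively:
core (d ≤ T), putative (T < d ≤ 2T), orphan (d > 2T); these three
intervals partition [0, ∞) exactly.  Query mode re-featurizes new
GenBank input with the stored library (verified by a checksum over the
model list and profile emissions), projects onto the stored column
order and persists the result as a query run in the same database.

## Evaluation

The V-measure is implemented from the contingency table with
natural-log entropies: homogeneity h = 1 − H(ref|pred)/H(ref),
completeness c = 1 − H(pred|ref)/H(pred), v = 2hc/(h+c).  The cited
definition leaves degenerate cases to the implementer; here h (resp. c)
is defined as 1 when H(ref) (resp. H(pred)) is 0, and v = 0 when
h + c = 0.  ΔGCF is the predicted-cluster count minus the
reference-group count, with singletons counted individually unless the
confusion matrix is asked to collapse them into one column.  The
implementation is verified against an exhaustive entropy oracle on all
partition pairs of up to 6 items and against scikit-learn's
`homogeneity_completeness_v_measure`.

## Atlas analyses

*Binning*: K-means (k-means++ under the given seed, 10 restarts, best
inertia kept) over GCF centroids, followed by a second pass assigning
every BGC feature row to its nearest bin centroid.  *Phylogram*:
average-linkage Euclidean dendrogram over bin centroids; an all-zero
dummy vector is appended as a leaf before linkage, the tree is
re-rooted on that leaf's attachment edge and the dummy pruned, so the
root sits where a feature-less BGC would attach.  *Novelty*: per-GCF
minimum distance to any reference feature row, classified related
(d ≤ T) or distant.  *Richness*: per species with ≥ `min_genomes`
(default 4) genomes, the number of distinct GCFs with rank-1 *core*
assignments, and per GCF the fraction of the species' genomes carrying
it, histogrammed in 20%-wide bins.  Counting only core-category rank-1
assignments is a deliberate choice: putative hits are too uncertain to
claim family presence in a genome.

## Synthetic data

`make_toy_hmm_library` builds profiles from ungapped synthetic
alignments (10 sequences per model, 5% per-residue noise around a
random consensus of 40 aa) through the same pyhmmer builder used for
real alignments, so toy models are scannable and self-consistent
without any Pfam download.  Biosynthetic/core models carry a gathering
cutoff of 20 bits — high enough that random 60–80 aa sequences
essentially never score, low enough that mutated motif copies always
do.  Sub-Pfam clades are built around consensus copies diverged at 35%
per residue.  The first `n_core` of the biosynthetic models are flagged
core, mirroring the fact that core domains are a subset of the
biosynthetic collection.

`simulate_bgc_set` plants each GCF as a characteristic subset of
biosynthetic motifs plus one clade of one core motif; members carry
point-mutated copies of those motifs as CDSs (back-translated with a
fixed codon table so files carry consistent /translation qualifiers and
coordinates on both strands), plus random filler genes, shuffled in
order.  A chosen fraction of BGCs is emitted as fragments: contig-edge
qualifier set and a random gene suffix deleted.  Output parses under
the package's own GenBank reader, and generation is byte-reproducible
under a seed (profile DATE headers are pinned).

The default within-family mutation rate is 2% per residue: within a
family, domain architecture is identical and sub-Pfam rank fingerprints
are stable, while sequences still differ — families are separated in
feature space by construction.  At noticeably higher rates the
fingerprint ranks of sibling clades (whose bitscores are close by
construction) begin to flip, which makes a planted "family" no longer a
family at the feature level.  Tests that need exact parameter recovery
use a rate of 0, where members are provably feature-identical; tests of
fragment handling and distance separation run at the noisy default.

What the generator does **not** emulate: realistic Pfam domain
architecture statistics, gene synteny signal, inter-family domain
sharing gradients, taxon abundance distributions, or assembly artifacts
beyond the suffix-truncation fragment model.  Passing tests therefore
demonstrate the correctness of the machinery (parsing, scanning,
encoding, clustering, storage, scoring) and its behavior on idealized
family structure — not clustering quality on real genomic data, where
family boundaries are fuzzier and single-threshold spherical clustering
is a known compromise.

## Problem sizes

The test suite and acceptance script run on toy libraries (6
biosynthetic models, 2 cores × 3 clades) and collections of 18–200
vectors/BGCs; the oracle-equivalence suites use ≤200 rows and 20 random
seeds.  These sizes exercise every code path (the algorithms are the
same at any scale) while keeping the whole suite under a minute of
scanning time.

## Known limitations

- Single global threshold: families with heterogeneous internal radii
  cannot all be captured at one *T* (the sweep utilities exist to make
  this visible).
- Presence-only encoding: copy-number and synteny signal is invisible.
- Fragments: Euclidean distance on full columns penalizes truncated
  BGCs; a shared-column ("glocal") distance is out of scope here.
- BIRCH order dependence: results are deterministic for a fixed input
  order but can differ between orderings; insertion order is pinned to
  lexicographic bgc_id.
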