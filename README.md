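# gcfkit

Near-linear clustering of biosynthetic gene clusters (BGCs) into gene
cluster families (GCFs), driven by profile-HMM domain fingerprints.

## The problem

Genome mining predicts secondary-metabolite BGCs at a scale (hundreds of
thousands to millions of loci across genomes and MAGs) where pairwise
network approaches to BGC grouping become infeasible: comparing every
pair of BGCs is quadratic in the number of clusters.  `gcfkit` instead
embeds every BGC in a fixed Euclidean feature space and groups them with
a single-pass, centroid-based clustering, so the whole analysis scales
near-linearly.  It is aimed at microbial genome miners who want to
dereplicate large BGC collections into families, place newly sequenced
BGCs into an existing family atlas, and chart which parts of
biosynthetic space are far from anything characterized.

## The method

**Feature encoding.** Each BGC's CDS translations are scanned (via
pyhmmer) against a curated pHMM library with two tiers:

- *biosynthetic* domain models, filtered at each model's gathering
  threshold, contribute Boolean presence columns — 255 if the model hits
  anywhere in the BGC, else 0;
- *sub-Pfam* models — clade-level sub-profiles of a core biosynthetic
  domain, built by hierarchically clustering an alignment of that
  domain's sequences — are scanned against the protein subsequence
  spanned by each core-domain hit.  Per instance, hits are ranked by
  bitscore and the top *K* (default 3) receive descending values
  `round(255·(K−r+1)/K)` for rank *r*; e.g. for K = 3 the ranks map to
  255, 170, 85.  Multiple instances combine by column-wise maximum.

**Clustering.** A threshold *T* is calibrated as the average *X*th
percentile (default *X* = 1) of Euclidean pairwise distances within 100
randomly sampled batches of 1,000 feature rows.  GCF models are then
built by flat-tree BIRCH: rows are scanned incrementally and absorbed
into the nearest subcluster whenever the subcluster's RMS radius after
absorption stays ≤ *T*; centroids are member means.  Optionally only
non-fragmented BGCs (contig-edge flag false/absent) train the models.

**Membership.** Every BGC is matched with its top-*N* (default 3)
nearest centroids; the best-hit distance *d* categorizes it as *core*
(d ≤ T), *putative* (T < d ≤ 2T) or *orphan* (d > 2T).

Everything is persisted in one SQLite database that doubles as the
model store for query mode and supports cross-cutting SQL analytics
(domain-content × taxonomy protein queries, sub-Pfam clade diversity).
Downstream, `gcfkit.atlas` bins GCF centroids with K-means, exports an
average-linkage phylogram (Newick, rooted on an all-zero dummy vector),
computes per-GCF nearest-reference novelty distances, and per-species
GCF richness/sharedness tables.  Clustering agreement against curated
groupings is scored with the V-measure (`gcfkit.evaluate`).

## Worked example

No external data is needed: `gcfkit.synthetic` generates a toy pHMM
library and region GenBank files with planted family structure.

```sh
python examples/01_cluster_simulated_bgcs.py
```

```
calibrated threshold T = 0.00
GCF models built       = 5
V-score vs planted     = 1.000 (homogeneity 1.000, completeness 1.000)
```

Five planted families of eight noise-free BGCs each yield five GCF
models; the V-score of 1.0 against the planted truth means each family
was recovered exactly (members of one family share identical feature
vectors, so the calibrated percentile threshold is 0 and every distinct
architecture seeds its own centroid).  `examples/02_query_new_bgcs.py`
shows query mode placing truncated BGC fragments back onto their source
families, `examples/03_atlas_and_novelty.py` the binning/phylogram/
novelty/richness views, and `examples/04_sql_analytics.py` the SQL
analytics.  A thin CLI wraps the same pipeline:

```sh
gcfkit cluster BGC_DIR --model-list models.tsv --hmm-dir hmms/ --output run.db
gcfkit query NEW.gbk --database run.db --model-list models.tsv --hmm-dir hmms/
```

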