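"""Global-map views: GCF bins, phylogram, novelty distance, richness.

After clustering, the GCF centroids are compressed into K-means bins,
arranged on an average-linkage phylogram (rooted on an all-zero dummy
vector), measured against a reference collection for novelty, and
summarized per species.
"""

import tempfile
from pathlib import Path

from gcfkit.atlas import (
    bin_gcfs,
    export_bin_phylogram,
    gcf_richness,
    nearest_reference_distance,
)
from gcfkit.genbank import load_taxonomy
from gcfkit.pipeline import run_clustering
from gcfkit.synthetic import make_toy_hmm_library, simulate_bgc_set

workdir = Path(tempfile.mkdtemp(prefix="gcfkit_example_"))
library = make_toy_hmm_library(workdir / "library", seed=1)
simulated = simulate_bgc_set(workdir / "bgcs", library, n_gcfs=5, bgcs_per_gcf=8,
                             within_mutation_rate=0.0, seed=2)
result = run_clustering(
    [simulated.bgc_dir],
    model_list=library.model_list_path,
    hmm_dir=library.hmm_dir,
    db_path=workdir / "models.db",
    taxonomy_path=simulated.taxonomy_path,
    seed=3,
)

bins, assignment = bin_gcfs(result.models, n_bins=3, seed=0,
                            bgc_matrix=result.matrix,
                            bgc_datasets={b: "simulated" for b in result.matrix.bgc_ids})
print("bin sizes (GCFs):", [len(b.member_gcf_ids) for b in bins])
print("phylogram:", export_bin_phylogram(bins))

# novelty: distance of each GCF to the closest "reference" BGC — here
# the first planted family doubles as the characterized reference set
refs = result.matrix.subset(sorted(simulated.truth.bgc_id)[:8])
novelty = nearest_reference_distance(result.models, refs, T=result.T + 100)
print(novelty.to_string(index=False))

richness = gcf_richness(
    result.memberships,
    {b: b.split(".")[0] for b in result.matrix.bgc_ids},
    load_taxonomy(simulated.taxonomy_path),
    min_genomes=4,
)
print(richness.to_string(index=False))
# "related" GCFs sit within T of a reference BGC; "distant" ones are the
# candidate-novelty families.  The richness table counts distinct core
# GCFs per species and how widely each is shared across its genomes.
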