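"""Cross-cutting SQL analytics on the pipeline database.

Everything a run produces lands in one SQLite file; this example pulls
protein sequences by domain content and taxon, and charts sub-Pfam
clade diversity per dataset.
"""

import tempfile
from pathlib import Path

from gcfkit import store as db
from gcfkit.pipeline import run_clustering
from gcfkit.synthetic import make_toy_hmm_library, simulate_bgc_set

workdir = Path(tempfile.mkdtemp(prefix="gcfkit_example_"))
library = make_toy_hmm_library(workdir / "library", seed=1)
simulated = simulate_bgc_set(workdir / "bgcs", library, n_gcfs=4, bgcs_per_gcf=6, seed=2)
run_clustering(
    [simulated.bgc_dir],
    model_list=library.model_list_path,
    hmm_dir=library.hmm_dir,
    db_path=workdir / "models.db",
    taxonomy_path=simulated.taxonomy_path,
    seed=3,
)

conn = db.connect(workdir / "models.db")
core = library.core_names[0]

cds = db.query_cds_by_domain_and_taxon(conn, core, min_hits=1, taxon=("genus", "GenusA"))
print(f"CDSs with >=1 {core} hit in GenusA: {len(cds)}")
print(cds[["cds_id", "genome_id", "n_hits"]].head().to_string(index=False))

diversity = db.subpfam_diversity_report(conn, core, group_by="phylum")
print(diversity.to_string(index=False))
conn.close()
# each proportion row is the share of core-domain instances whose
# best-scoring sub-Pfam clade is `clade`, within that phylum — a quick
# view of how one enzyme family diversifies across taxa.
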