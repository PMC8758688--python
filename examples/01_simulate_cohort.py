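"""Generate the default synthetic cohort and write it to disk.

Builds the desk-scale NSCLC stand-in: ~2900 cells across 12 cell types
with malignant AT2/basal subclones carrying chromosome-scale dosage
events, plus 100 bulk samples mixed from composition archetypes.
"""

from pathlib import Path

import lungcomp as lc
from lungcomp import io as lcio

catalog = lc.generate_gene_catalog(n_chromosomes=5, genes_per_chromosome=400,
                                   seed=1)
design = lc.default_design(seed=1)
adata, truth = lc.simulate_single_cells(catalog, design)
profiles = lc.expected_profiles(catalog, design)
bulk, bulk_truth = lc.simulate_bulk(catalog, profiles, design)
truth.bulk_composition = bulk_truth.bulk_composition
truth.bulk_group = bulk_truth.bulk_group

out = Path("scratch/cohort")
lcio.write_cohort(out, adata, catalog, bulk=bulk, truth=truth)

print(f"cells x genes: {adata.shape}")
print(f"cell types: {sorted(adata.obs['cell_type'].unique())}")
print(f"malignant cells: {int(adata.obs['malignant'].sum())} "
      f"in subclones {sorted(set(truth.cell_subclone) - {-1})}")
print(f"bulk samples: {bulk.shape[1]} in groups "
      f"{sorted(bulk_truth.bulk_group.unique())}")
print(f"written to {out}/ (MTX + TSV + BED + truth JSON)")
# The counts matrix, metadata and ground truth fully determine every
# downstream analysis; re-running with the same seed reproduces them.
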