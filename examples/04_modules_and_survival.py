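"""Discover composition modules, validate with an SVM, test survival.

Runs the full chain for one seed: simulate -> signature -> deconvolve ->
cluster samples into named groups -> contrast the poor-prognosis group
against the rest with a log-rank test.
"""

import lungcomp as lc

res = lc.composition_survival_chain(seed=1, cells_per_type=80, k=5)

print("discovered groups:")
for gid, name in res.groups.names.items():
    n = int((res.groups.group == gid).sum())
    print(f"  group {gid}: {name} ({n} samples)")

print(f"contrast: group {res.contrast_group_id} "
      f"({res.groups.names[res.contrast_group_id]}) vs rest")
print(f"log-rank chi-square = {res.survival.chi_square:.2f}, "
      f"p = {res.survival.p_value:.2e}")

comp = lc.CompositionMatrix(weights=res.composition)
rep = lc.classify_subtypes(comp, res.truth_group, n_repeats=10, seed=1)
print(f"SVM archetype classification: mean AUC {rep.mean_auc:.3f} "
      f"(SD {rep.sd_auc:.3f})")
# A small p means the group enriched for the planted high-hazard archetype
# (Fib-high) separates in survival, mirroring a poor-prognosis patient
# module; AUC near 1 means compositions alone identify the archetypes.
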