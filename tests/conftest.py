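"""Shared fixtures: cached synthetic cohorts and CNV profiles.

The default desk-scale cohort is expensive enough (~3000 cells x 2000
genes) that tests share seeded instances through a session-scoped cache.
"""

from __future__ import annotations

from functools import lru_cache

import pytest

import lungcomp as lc

IMMUNE = ["B", "CD4", "CD8", "Mph"]


@lru_cache(maxsize=8)
def _cohort(seed: int, cells_per_type: int = 240):
    catalog = lc.generate_gene_catalog(5, 400, seed=seed)
    design = lc.default_design(seed=seed, cells_per_type=cells_per_type)
    adata, truth = lc.simulate_single_cells(catalog, design)
    return catalog, design, adata, truth


@lru_cache(maxsize=8)
def _profile(seed: int, cells_per_type: int = 240):
    catalog, design, adata, truth = _cohort(seed, cells_per_type)
    reference = adata.obs_names[adata.obs["cell_type"].isin(IMMUNE)]
    profile = lc.compute_cnv_profile(adata, catalog, reference)
    return profile, reference


@pytest.fixture(scope="session")
def cohort_factory():
    return _cohort


@pytest.fixture(scope="session")
def profile_factory():
    return _profile


@pytest.fixture(scope="session")
def default_cohort():
    return _cohort(1)


@pytest.fixture(scope="session")
def default_profile():
    return _profile(1)
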