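"""Seeded synthetic single-cell and bulk cohorts with full ground truth.

The generator emulates the statistical structure of an NSCLC single-cell +
bulk atlas at desk scale: a dozen cell types with disjoint marker-gene sets,
malignant subpopulations carrying contiguous chromosomal dosage events
(amplifications/deletions per subclone), bulk samples drawn as noisy mixtures
of cell-type profiles from group-specific composition archetypes (e.g. a
"Fib-high" patient group), and exponential survival with group-dependent
hazards. Every output is a pure function of (design, seed).

Counts are negative binomial with mean ``mu`` and size (inverse-dispersion)
``r`` so that ``var = mu + mu^2 / r``; ``r = inf`` gives the Poisson limit.
Marker genes of a cell's own type have their mean multiplied by
``marker_fold``; malignant cells additionally have the means of genes inside
their subclone's CNV events multiplied by the event dosage (expression
proportional to copy number).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CnvEvent",
    "Population",
    "CohortDesign",
    "SyntheticTruth",
    "generate_gene_catalog",
    "default_design",
    "simulate_single_cells",
    "expected_profiles",
    "simulate_bulk",
    "simulate_survival",
]

NON_IMMUNE_TYPES = ["AT1", "AT2", "Basal", "Cilia", "Club", "EC", "Fib", "NE"]
IMMUNE_TYPES = ["B", "CD4", "CD8", "Mph"]


@dataclass(frozen=True)
class CnvEvent:
    """A contiguous dosage event carried by one subclone.

    ``first_gene``/``last_gene`` are inclusive ``order_index`` positions on
    ``chromosome``; ``multiplier`` > 1 is an amplification, < 1 a deletion.
    """

    chromosome: str
    first_gene: int
    last_gene: int
    multiplier: float
    subclone_id: int

    def __post_init__(self):
        if self.last_gene < self.first_gene:
            raise ValueError(
                f"empty CNV event range [{self.first_gene}, {self.last_gene}]"
            )
        if self.multiplier <= 0:
            raise ValueError("CNV multiplier must be positive")


@dataclass(frozen=True)
class Population:
    """A homogeneous block of cells: one (sample, cell type) group.

    ``subclone`` is None for non-malignant cells; an integer id marks the
    cells malignant and applies the matching CnvEvents.
    """

    sample: str
    cell_type: str
    n_cells: int
    subclone: int | None = None


@dataclass
class CohortDesign:
    """Everything the simulators need, besides the gene catalog and seed."""

    cell_types: dict[str, int]                 # type -> number of marker genes
    populations: list[Population]
    sample_conditions: dict[str, str]          # sample -> LUAD/LUSC/adjacent/normal
    sample_stages: dict[str, str]              # sample -> I/II/III/IV
    cnv_events: list[CnvEvent] = field(default_factory=list)
    marker_fold: float = 8.0
    base_mean_log_mu: float = math.log(1.0)
    base_mean_log_sigma: float = 1.0
    dispersion: float = 0.5                    # NB size r; np.inf -> Poisson
    library_sigma: float = 0.2                 # log-normal library-size spread
    bulk_archetypes: dict[str, dict[str, float]] = field(default_factory=dict)
    n_bulk_per_group: int = 20
    bulk_noise_sigma: float = 0.2
    hazards: dict[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if any(n <= 0 for n in self.cell_types.values()):
            raise ValueError("marker-gene counts must be positive")
        if any(p.n_cells < 0 for p in self.populations):
            raise ValueError("population cell counts must be non-negative")
        for g, conc in self.bulk_archetypes.items():
            if any(a <= 0 for a in conc.values()):
                raise ValueError(f"Dirichlet concentrations must be positive ({g})")
        if any(h <= 0 for h in self.hazards.values()):
            raise ValueError("hazards must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring rate must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside simulated data."""

    cell_malignant: pd.Series | None = None          # bool per cell
    cell_subclone: pd.Series | None = None           # int per cell (-1 = none)
    markers: dict[str, list[str]] = field(default_factory=dict)
    cnv_events: list[CnvEvent] = field(default_factory=list)
    bulk_composition: pd.DataFrame | None = None     # samples x cell types
    bulk_group: pd.Series | None = None


def generate_gene_catalog(
    n_chromosomes: int, genes_per_chromosome: int, seed: int
) -> pd.DataFrame:
    """Ordered gene coordinates: ``gene_id, chromosome, start, order_index``.

    Starts are strictly increasing within each chromosome (0-based, bp-like);
    ``order_index`` is the rank within the chromosome and is the unit in
    which CNV windows and events are expressed.
    """
    if n_chromosomes < 1 or genes_per_chromosome < 1:
        raise ValueError("catalog dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(1, n_chromosomes + 1):
        gaps = rng.integers(1_000, 100_000, size=genes_per_chromosome)
        starts = np.cumsum(gaps) - gaps[0]
        for i, s in enumerate(starts):
            rows.append((f"chr{c}_g{i:04d}", f"chr{c}", int(s), i))
    cat = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "order_index"])
    return cat


def default_design(seed: int = 0, cells_per_type: int = 240) -> CohortDesign:
    """The package's reference desk-scale cohort.

    12 cell types (8 non-immune + 4 immune), ~12 x ``cells_per_type`` cells,
    25 markers per type, malignant AT2 (LUAD) and basal (LUSC) populations
    each split into two subclones carrying multiplier-2 amplifications and
    0.5 deletions over 200-300 gene stretches, four LUAD composition
    archetypes (AT2/AT1/NE/Fib-high plus none being "hybrid" by default),
    and a poor-prognosis Fib-high hazard.
    """
    types = {t: 25 for t in NON_IMMUNE_TYPES + IMMUNE_TYPES}
    half = cells_per_type // 2
    quarter = cells_per_type // 4
    pops: list[Population] = []
    for t in types:
        if t == "AT2":
            pops.append(Population("ADJ_1", t, half))
            pops.append(Population("LUAD_1", t, quarter, subclone=1))
            pops.append(Population("LUAD_2", t, quarter, subclone=2))
        elif t == "Basal":
            pops.append(Population("ADJ_2", t, half))
            pops.append(Population("LUSC_1", t, quarter, subclone=3))
            pops.append(Population("LUSC_2", t, quarter, subclone=4))
        else:
            pops.append(Population("LUAD_1", t, half))
            pops.append(Population("ADJ_1", t, half))
    conditions = {
        "LUAD_1": "LUAD", "LUAD_2": "LUAD",
        "LUSC_1": "LUSC", "LUSC_2": "LUSC",
        "ADJ_1": "adjacent", "ADJ_2": "adjacent",
    }
    stages = {
        "LUAD_1": "I", "LUAD_2": "III",
        "LUSC_1": "I", "LUSC_2": "II",
        "ADJ_1": "I", "ADJ_2": "I",
    }
    # chromosome-scale events, mirroring the whole-chromosome amplification
    # pattern typical of NSCLC epithelial malignancies
    events = [
        CnvEvent("chr1", 0, 399, 2.0, subclone_id=1),
        CnvEvent("chr2", 100, 349, 0.5, subclone_id=1),
        CnvEvent("chr1", 0, 399, 2.0, subclone_id=2),
        CnvEvent("chr3", 0, 249, 2.0, subclone_id=2),
        CnvEvent("chr4", 0, 399, 2.0, subclone_id=3),
        CnvEvent("chr5", 150, 399, 0.5, subclone_id=3),
        CnvEvent("chr4", 0, 399, 2.0, subclone_id=4),
        CnvEvent("chr2", 0, 249, 2.0, subclone_id=4),
    ]
    archetypes = {}
    for dom in ["AT2", "AT1", "NE", "Fib"]:
        conc = {t: 1.0 for t in types}
        conc[dom] = 50.0
        archetypes[f"{dom}-high"] = conc
    archetypes["mixed"] = {t: 3.0 for t in types}
    hazards = {g: 0.25 for g in archetypes}
    hazards["Fib-high"] = 1.0
    return CohortDesign(
        cell_types=types,
        populations=pops,
        sample_conditions=conditions,
        sample_stages=stages,
        cnv_events=events,
        bulk_archetypes=archetypes,
        hazards=hazards,
        seed=seed,
    )


def _assign_markers(
    catalog: pd.DataFrame, cell_types: dict[str, int], rng: np.random.Generator
) -> dict[str, list[str]]:
    """Disjoint marker sets, scattered uniformly over the genome.

    Scattering (rather than contiguous blocks) keeps cell-type identity
    signals from imitating contiguous CNV segments in windowed profiles.
    """
    total = sum(cell_types.values())
    if total > len(catalog):
        raise ValueError("more marker genes requested than genes in catalog")
    picks = rng.choice(len(catalog), size=total, replace=False)
    markers: dict[str, list[str]] = {}
    offset = 0
    for t, n in cell_types.items():
        idx = picks[offset:offset + n]
        markers[t] = catalog["gene_id"].to_numpy()[idx].tolist()
        offset += n
    return markers


def _event_multipliers(
    catalog: pd.DataFrame, events: list[CnvEvent]
) -> dict[int, np.ndarray]:
    """Per-subclone gene-wise dosage vectors, validated against the catalog."""
    chrom_sizes = catalog.groupby("chromosome")["order_index"].max()
    mult: dict[int, np.ndarray] = {}
    for ev in events:
        if ev.chromosome not in chrom_sizes.index:
            raise ValueError(f"CNV event on unknown chromosome {ev.chromosome}")
        if ev.first_gene < 0 or ev.last_gene > chrom_sizes[ev.chromosome]:
            raise ValueError(
                f"CNV event [{ev.first_gene}, {ev.last_gene}] out of range "
                f"for {ev.chromosome}"
            )
        vec = mult.setdefault(ev.subclone_id, np.ones(len(catalog)))
        mask = (
            (catalog["chromosome"] == ev.chromosome)
            & (catalog["order_index"] >= ev.first_gene)
            & (catalog["order_index"] <= ev.last_gene)
        ).to_numpy()
        vec[mask] *= ev.multiplier
    return mult


def _base_means(catalog: pd.DataFrame, design: CohortDesign) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 11]))
    return rng.lognormal(
        design.base_mean_log_mu, design.base_mean_log_sigma, size=len(catalog)
    )


def _type_mean_matrix(
    catalog: pd.DataFrame, design: CohortDesign, markers: dict[str, list[str]]
) -> pd.DataFrame:
    base = _base_means(catalog, design)
    gene_pos = pd.Series(np.arange(len(catalog)), index=catalog["gene_id"])
    cols = {}
    for t in design.cell_types:
        mean = base.copy()
        mean[gene_pos[markers[t]].to_numpy()] *= design.marker_fold
        cols[t] = mean
    return pd.DataFrame(cols, index=catalog["gene_id"])


def simulate_single_cells(
    catalog: pd.DataFrame, design: CohortDesign
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Draw the single-cell counts matrix and its ground truth.

    Returns an AnnData (cells x genes, sparse integer counts) whose ``obs``
    carries sample, cell_type, condition, stage, and the truth columns
    ``malignant`` and ``subclone`` (-1 for non-malignant), and whose ``var``
    is the gene catalog.
    """
    markers = _assign_markers(
        catalog, design.cell_types,
        np.random.default_rng(np.random.SeedSequence([design.seed, 7])),
    )
    seen: set[str] = set()
    for t, ms in markers.items():
        if seen & set(ms):
            raise ValueError(f"marker sets overlap at type {t}")
        seen |= set(ms)
    type_means = _type_mean_matrix(catalog, design, markers)
    sub_mult = _event_multipliers(catalog, design.cnv_events)
    for p in design.populations:
        if p.subclone is not None and p.subclone not in sub_mult:
            raise ValueError(f"population references unknown subclone {p.subclone}")

    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 13]))
    blocks, obs_rows = [], []
    cell_counter = 0
    for p in design.populations:
        if p.n_cells == 0:
            continue
        if p.cell_type not in design.cell_types:
            raise ValueError(f"unknown cell type {p.cell_type}")
        mean = type_means[p.cell_type].to_numpy().copy()
        if p.subclone is not None:
            mean = mean * sub_mult[p.subclone]
        lib = rng.lognormal(0.0, design.library_sigma, size=p.n_cells)
        mu = np.outer(lib, mean)
        if np.isinf(design.dispersion):
            counts = rng.poisson(mu)
        else:
            r = design.dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
        blocks.append(sp.csr_matrix(counts))
        cond = design.sample_conditions.get(p.sample, "unknown")
        stage = design.sample_stages.get(p.sample, "I")
        for _ in range(p.n_cells):
            obs_rows.append(
                (
                    f"cell_{cell_counter:06d}", p.sample, p.cell_type, cond,
                    stage, p.subclone is not None,
                    -1 if p.subclone is None else p.subclone,
                )
            )
            cell_counter += 1
    obs = pd.DataFrame(
        obs_rows,
        columns=[
            "cell_id", "sample", "cell_type", "condition", "stage",
            "malignant", "subclone",
        ],
    ).set_index("cell_id")
    var = catalog.set_index("gene_id")
    adata = ad.AnnData(X=sp.vstack(blocks).tocsr(), obs=obs, var=var.copy())
    truth = SyntheticTruth(
        cell_malignant=obs["malignant"].copy(),
        cell_subclone=obs["subclone"].copy(),
        markers=markers,
        cnv_events=list(design.cnv_events),
    )
    return adata, truth


def expected_profiles(catalog: pd.DataFrame, design: CohortDesign) -> pd.DataFrame:
    """Noise-free expected expression per cell type (genes x types).

    These are the generative means without CNV dosage — the reference
    profiles that bulk mixtures are built from.
    """
    markers = _assign_markers(
        catalog, design.cell_types,
        np.random.default_rng(np.random.SeedSequence([design.seed, 7])),
    )
    return _type_mean_matrix(catalog, design, markers)


def simulate_bulk(
    catalog: pd.DataFrame,
    cell_type_profiles: pd.DataFrame,
    design: CohortDesign,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Bulk samples as noisy mixtures of cell-type profiles.

    Each sample's true composition is a Dirichlet draw from its group's
    archetype concentrations; the expected profile is ``profiles @ w`` and
    multiplicative log-normal noise at ``bulk_noise_sigma`` is applied
    gene-wise (sigma = 0 gives exact mixtures).
    """
    if (cell_type_profiles.to_numpy() < 0).any():
        raise ValueError("cell-type profiles must be non-negative")
    if design.bulk_noise_sigma < 0:
        raise ValueError("bulk noise sigma must be >= 0")
    types = list(cell_type_profiles.columns)
    for g, conc in design.bulk_archetypes.items():
        if set(conc) < set(types):
            raise ValueError(f"archetype {g} does not cover all cell types")
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 17]))
    P = cell_type_profiles.to_numpy()
    cols, comp_rows, groups, names = {}, [], [], []
    for g, conc in design.bulk_archetypes.items():
        alpha = np.array([conc[t] for t in types])
        for i in range(design.n_bulk_per_group):
            w = rng.dirichlet(alpha)
            b = P @ w
            if design.bulk_noise_sigma > 0:
                b = b * rng.lognormal(0.0, design.bulk_noise_sigma, size=len(b))
            name = f"{g}_s{i:03d}"
            cols[name] = b
            comp_rows.append(w)
            groups.append(g)
            names.append(name)
    bulk = pd.DataFrame(cols, index=cell_type_profiles.index)
    comp = pd.DataFrame(comp_rows, index=names, columns=types)
    truth = SyntheticTruth(
        bulk_composition=comp,
        bulk_group=pd.Series(groups, index=names, name="group"),
    )
    return bulk, truth


def simulate_survival(
    group_labels: pd.Series | list,
    hazards: dict[str, float],
    censoring_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Exponential event times with group hazards and independent censoring.

    Censoring times are exponential with rate chosen so that, within each
    group, the expected censored fraction equals ``censoring_rate``;
    ``censoring_rate = 0`` observes every event.
    """
    labels = pd.Series(group_labels)
    unknown = set(labels) - set(hazards)
    if unknown:
        raise ValueError(f"unknown groups in labels: {sorted(unknown)}")
    if any(h <= 0 for h in hazards.values()):
        raise ValueError("hazards must be positive")
    if not 0 <= censoring_rate < 1:
        raise ValueError("censoring rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    h = labels.map(hazards).to_numpy(dtype=float)
    t_event = rng.exponential(1.0 / h)
    if censoring_rate == 0:
        time, event = t_event, np.ones(len(labels), dtype=int)
    else:
        c_rate = h * censoring_rate / (1.0 - censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=labels.index)
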