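"""Synthetic cohorts with the pooled three-group study design.

The generator emulates a placental-transcriptome case/control study of
intrahepatic cholestasis of pregnancy (ICP): three groups (healthy, mild,
severe — strata defined by maternal serum bile-acid concentration), ten
individuals per group, each group split into two sub-groups of five whose
RNA is pooled onto one array (six arrays total).  Planted effects —
differential expression, latent-factor co-expression modules, an
interaction hub, enriched annotation terms — are recorded as ground truth
so every downstream stage can be scored for recovery.

All outputs are pure functions of (design, effects, seed): per-operation
random streams are derived from one global integer seed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import EdgeList, ExpressionMatrix

GROUP_LABELS = ("healthy", "mild", "severe")

#: Serum bile-acid strata (μM) defining the three groups.
BILE_ACID_STRATA = {
    "healthy": (0.0, 10.0),
    "mild": (10.0, 40.0),
    "severe": (40.0, math.inf),
}

CONTRASTS = ("mild_vs_healthy", "severe_vs_healthy")

#: Detection probability by mean-intensity quantile: genes in the lowest
#: decile are unreliably detected, everything else is called on nearly
#: every array (mimics Present/Absent calls without scanner physics).
DEFAULT_DETECT_PROB = {0.10: 0.35, 1.0: 0.99}

#: Per-field Poisson means per group for the morphometry arm, emulating
#: reduced capillarisation and graded immune-cell infiltration in ICP.
DEFAULT_MORPHOMETRY_MEANS = {
    "healthy": {"capillaries": 6.0, "villi": 2.0, "cd45": 2.0, "cd3": 1.0, "cd19": 0.5},
    "mild": {"capillaries": 4.5, "villi": 2.0, "cd45": 10.0, "cd3": 3.0, "cd19": 1.5},
    "severe": {"capillaries": 3.5, "villi": 2.0, "cd45": 30.0, "cd3": 6.0, "cd19": 3.0},
}


def _rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-operation stream derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


# ---------------------------------------------------------------------------
# Design / planted-effect descriptions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortDesign:
    """Study design: groups, pooling layout and gene universe size."""

    n_genes: int = 4000
    group_labels: tuple[str, ...] = GROUP_LABELS
    individuals_per_group: int = 10
    pool_size: int = 5
    arrays_per_group: int = 2
    bile_acid_strata: dict = field(default_factory=lambda: dict(BILE_ACID_STRATA))

    def __post_init__(self) -> None:
        if self.individuals_per_group != self.pool_size * self.arrays_per_group:
            raise ValueError(
                "individuals_per_group must equal pool_size * arrays_per_group "
                f"({self.individuals_per_group} != {self.pool_size} * {self.arrays_per_group})"
            )
        bounds = [self.bile_acid_strata[g] for g in self.group_labels if g in self.bile_acid_strata]
        for (lo1, hi1), (lo2, hi2) in zip(bounds, bounds[1:]):
            if not (lo1 < hi1 <= lo2 < hi2):
                raise ValueError("bile-acid strata must be disjoint and ordered")

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def n_arrays(self) -> int:
        return self.n_groups * self.arrays_per_group

    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]

    def individual_ids(self) -> list[str]:
        return [
            f"{g}_{i:02d}"
            for g in self.group_labels
            for i in range(1, self.individuals_per_group + 1)
        ]

    def individual_groups(self) -> list[str]:
        return [g for g in self.group_labels for _ in range(self.individuals_per_group)]


@dataclass
class Module:
    """One latent-factor co-expression module: genes with per-gene loadings."""

    genes: tuple[str, ...]
    loadings: dict[str, float]
    factor_sd: float = 5.0


@dataclass
class PlantedEffects:
    """Ground-truth effect structure planted into a simulated cohort.

    ``de_genes`` maps contrast name → {gene: true log2 fold change}; the
    magnitude of every planted fold change must be at least log2(1.5).
    Module gene sets must be disjoint.  ``seed`` fully determines every
    simulated output.
    """

    seed: int = 0
    de_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    modules: list[Module] = field(default_factory=list)
    hub_gene: str | None = None
    enriched_terms: dict[str, float] = field(default_factory=dict)
    baseline_log2_mean: float = 8.0
    baseline_gene_sd: float = 1.5
    individual_sd: float = 0.5
    measurement_sd: float = 0.2
    gene_baselines: dict[str, float] | None = None

    def __post_init__(self) -> None:
        min_lfc = math.log2(1.5)
        for contrast, mapping in self.de_genes.items():
            for gene, lfc in mapping.items():
                if abs(lfc) < min_lfc - 1e-12:
                    raise ValueError(
                        f"planted |log2FC| for {gene} in {contrast} is {abs(lfc):.3f} "
                        f"< log2(1.5)"
                    )
        seen: set[str] = set()
        for mod in self.modules:
            overlap = seen & set(mod.genes)
            if overlap:
                raise ValueError(f"module gene sets overlap: {sorted(overlap)}")
            seen |= set(mod.genes)

    def all_planted_genes(self) -> set[str]:
        out: set[str] = set()
        for mapping in self.de_genes.values():
            out |= set(mapping)
        for mod in self.modules:
            out |= set(mod.genes)
        if self.hub_gene is not None:
            out.add(self.hub_gene)
        return out

    def de_union(self) -> set[str]:
        out: set[str] = set()
        for mapping in self.de_genes.values():
            out |= set(mapping)
        return out


@dataclass
class CohortTruth:
    """Serializable ground truth emitted alongside a simulated cohort."""

    true_de: dict[str, dict[str, float]] = field(default_factory=dict)
    true_modules: dict[str, int] = field(default_factory=dict)
    true_hubs: list[str] = field(default_factory=list)
    true_enriched_terms: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "true_de": {c: dict(sorted(m.items())) for c, m in sorted(self.true_de.items())},
            "true_modules": dict(sorted(self.true_modules.items())),
            "true_hubs": sorted(self.true_hubs),
            "true_enriched_terms": sorted(self.true_enriched_terms),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortTruth":
        return cls(
            true_de={c: {g: float(v) for g, v in m.items()} for c, m in d["true_de"].items()},
            true_modules={g: int(v) for g, v in d["true_modules"].items()},
            true_hubs=list(d["true_hubs"]),
            true_enriched_terms=list(d["true_enriched_terms"]),
        )


def truth_from_effects(effects: PlantedEffects) -> CohortTruth:
    return CohortTruth(
        true_de={c: dict(m) for c, m in effects.de_genes.items()},
        true_modules={
            g: i for i, mod in enumerate(effects.modules) for g in mod.genes
        },
        true_hubs=[] if effects.hub_gene is None else [effects.hub_gene],
        true_enriched_terms=sorted(effects.enriched_terms),
    )


# ---------------------------------------------------------------------------
# Standard effect construction
# ---------------------------------------------------------------------------


def make_standard_effects(
    design: CohortDesign,
    seed: int = 0,
    n_de_mild: int = 80,
    n_de_severe: int = 100,
    frac_shared: float = 0.5,
    lfc_range: tuple[float, float] = (1.0, 3.0),
    n_modules: int = 1,
    module_size: int = 30,
    loading_range: tuple[float, float] = (0.6, 1.0),
    module_factor_sd: float = 5.0,
    plant_hub: bool = True,
    n_enriched_terms: int = 5,
    enriched_fraction: float = 0.8,
    **noise_kwargs,
) -> PlantedEffects:
    """Draw a random but fully reproducible planted-effect structure.

    Planted genes are sampled from the expressed range (baseline above the
    15th intensity percentile): an effect on a transcript below the
    detection floor is unobservable by design, so planting there would
    only measure the flag filter, not the statistics.  Log2 fold-change
    magnitudes are uniform over ``lfc_range`` (default fold changes of
    2-8x, the long-tailed spectrum typical of disease-tissue arrays) with
    random signs; genes shared between the two contrasts keep a common
    sign.
    """
    rng = _rng(seed, "effects")
    genes = np.array(design.gene_ids())
    baselines = effects_baselines = rng.normal(
        noise_kwargs.get("baseline_log2_mean", 8.0),
        noise_kwargs.get("baseline_gene_sd", 1.5),
        size=design.n_genes,
    )
    eligible = genes[baselines > np.quantile(baselines, 0.15)]
    n_shared = int(round(frac_shared * min(n_de_mild, n_de_severe)))
    n_needed = n_de_mild + n_de_severe - n_shared + n_modules * module_size
    if n_needed > eligible.size:
        raise ValueError(
            f"gene universe too small: need {n_needed} planted genes, "
            f"only {eligible.size} eligible"
        )
    picked = rng.choice(eligible, size=n_needed, replace=False)
    shared = picked[:n_shared]
    mild_only = picked[n_shared : n_shared + (n_de_mild - n_shared)]
    severe_only = picked[
        n_shared + (n_de_mild - n_shared) : n_de_mild + n_de_severe - n_shared
    ]
    module_genes = picked[n_de_mild + n_de_severe - n_shared :]

    def lfcs(n: int) -> np.ndarray:
        mag = rng.uniform(*lfc_range, size=n)
        sign = rng.choice([-1.0, 1.0], size=n)
        return mag * sign

    shared_lfc = lfcs(n_shared)
    de_genes = {
        "mild_vs_healthy": {
            **{g: float(v) for g, v in zip(shared, shared_lfc)},
            **{g: float(v) for g, v in zip(mild_only, lfcs(mild_only.size))},
        },
        "severe_vs_healthy": {
            # shared genes move in the same direction, typically further in severe
            **{g: float(v * rng.uniform(1.0, 1.5)) for g, v in zip(shared, shared_lfc)},
            **{g: float(v) for g, v in zip(severe_only, lfcs(severe_only.size))},
        },
    }
    modules = []
    for m in range(n_modules):
        mg = tuple(sorted(module_genes[m * module_size : (m + 1) * module_size]))
        loadings = {g: float(rng.uniform(*loading_range)) for g in mg}
        modules.append(Module(genes=mg, loadings=loadings, factor_sd=module_factor_sd))
    hub = modules[0].genes[0] if (plant_hub and modules) else None
    if hub is not None:
        # the hub is the most central module member on both network sides:
        # top factor loading here, high interaction degree in simulate_interactions
        modules[0].loadings[hub] = float(loading_range[1])
    enriched = {f"PT{i:03d}": enriched_fraction for i in range(n_enriched_terms)}
    effects = PlantedEffects(
        seed=seed,
        de_genes=de_genes,
        modules=modules,
        hub_gene=hub,
        enriched_terms=enriched,
        gene_baselines={g: float(b) for g, b in zip(genes, effects_baselines)},
        **noise_kwargs,
    )
    return effects


# ---------------------------------------------------------------------------
# Simulation operations
# ---------------------------------------------------------------------------


def simulate_individuals(design: CohortDesign, effects: PlantedEffects) -> pd.DataFrame:
    """Per-individual log2 expression: baseline + group effect + modules + noise.

    Returns a genes x individuals DataFrame, deterministic given
    ``effects.seed``.
    """
    genes = design.gene_ids()
    gene_set = set(genes)
    for g in sorted(effects.all_planted_genes()):
        if g not in gene_set:
            raise ValueError(f"planted gene {g!r} outside the gene universe")
    gene_index = {g: i for i, g in enumerate(genes)}
    individuals = design.individual_ids()
    ind_groups = design.individual_groups()

    if effects.gene_baselines is not None:
        baselines = np.array([effects.gene_baselines[g] for g in genes])
    else:
        baselines = _rng(effects.seed, "baseline").normal(
            effects.baseline_log2_mean, effects.baseline_gene_sd, size=design.n_genes
        )
    values = np.tile(baselines[:, None], (1, len(individuals)))

    for contrast, mapping in effects.de_genes.items():
        group = contrast.split("_vs_")[0]
        cols = [j for j, g in enumerate(ind_groups) if g == group]
        for gene, lfc in mapping.items():
            values[gene_index[gene], cols] += lfc

    for m, mod in enumerate(effects.modules):
        factor = _rng(effects.seed, f"module{m}").normal(
            0.0, mod.factor_sd, size=len(individuals)
        )
        for gene in mod.genes:
            values[gene_index[gene]] += mod.loadings[gene] * factor

    if effects.individual_sd > 0:
        values = values + _rng(effects.seed, "individual").normal(
            0.0, effects.individual_sd, size=values.shape
        )
    return pd.DataFrame(values, index=genes, columns=individuals)


def pool_samples(
    individuals: pd.DataFrame,
    design: CohortDesign,
    measurement_sd: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Pool individuals into arrays by averaging LINEAR-scale intensities.

    Each group's individuals are partitioned, in column order, into
    ``arrays_per_group`` sub-groups of ``pool_size``; each array is the
    log2 of the mean linear intensity of its pool, plus per-array
    measurement noise of standard deviation ``measurement_sd`` (log2
    scale).
    """
    cols_by_group: dict[str, list[str]] = {g: [] for g in design.group_labels}
    for col in individuals.columns:
        group = col.rsplit("_", 1)[0]
        if group not in cols_by_group:
            raise ValueError(f"individual {col!r} does not belong to any design group")
        cols_by_group[group].append(col)
    arrays = []
    pools = []
    design_rows = []
    for group in design.group_labels:
        cols = cols_by_group[group]
        if len(cols) != design.pool_size * design.arrays_per_group:
            raise ValueError(
                f"group {group!r} has {len(cols)} individuals; pooling partition "
                f"requires {design.pool_size} x {design.arrays_per_group}"
            )
        for k in range(design.arrays_per_group):
            pool_cols = cols[k * design.pool_size : (k + 1) * design.pool_size]
            arrays.append(f"{group}_a{k + 1}")
            pools.append(pool_cols)
            design_rows.append((arrays[-1], group, f"{group}_s{k + 1}"))
    linear = np.power(2.0, individuals.to_numpy())
    pooled = np.column_stack(
        [np.log2(linear[:, [individuals.columns.get_loc(c) for c in cols]].mean(axis=1))
         for cols in pools]
    )
    if measurement_sd > 0:
        pooled = pooled + _rng(seed, "measurement").normal(
            0.0, measurement_sd, size=pooled.shape
        )
    values = pd.DataFrame(pooled, index=individuals.index, columns=arrays)
    design_df = pd.DataFrame(
        design_rows, columns=["array", "group", "subgroup"]
    ).set_index("array")
    return ExpressionMatrix(values=values, design=design_df)


def simulate_flags(
    matrix: ExpressionMatrix,
    detect_prob_by_quantile: dict[float, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli "detected" flags conditioned on mean-intensity quantile.

    ``detect_prob_by_quantile`` maps an upper quantile bound to a
    detection probability: a gene whose mean intensity falls in quantile
    bin (previous bound, bound] is detected on each array independently
    with that probability.
    """
    probs = dict(DEFAULT_DETECT_PROB if detect_prob_by_quantile is None else detect_prob_by_quantile)
    for q, p in probs.items():
        if not (0.0 <= p <= 1.0) or not (0.0 < q <= 1.0):
            raise ValueError(f"malformed detection probability mapping entry {q}: {p}")
    bounds = sorted(probs)
    if bounds[-1] < 1.0:
        raise ValueError("detection mapping must cover quantile 1.0")
    mean_intensity = matrix.values.mean(axis=1).to_numpy()
    order = np.argsort(np.argsort(mean_intensity, kind="stable"), kind="stable")
    quantile = (order + 0.5) / matrix.n_genes
    gene_prob = np.empty(matrix.n_genes)
    for i, q in enumerate(quantile):
        gene_prob[i] = probs[next(b for b in bounds if q <= b)]
    draws = _rng(seed, "flags").random(size=matrix.values.shape)
    flags = draws < gene_prob[:, None]
    return pd.DataFrame(flags, index=matrix.values.index, columns=matrix.values.columns)


def simulate_annotation(
    design: CohortDesign,
    effects: PlantedEffects,
    n_background_terms: int = 100,
    term_size_range: tuple[int, int] = (20, 200),
    planted_term_size: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gene→term table: uniform background terms plus planted enriched terms.

    Each planted term of size ``planted_term_size`` draws
    ``round(fraction * size)`` of its genes from the planted DE union and
    the rest from non-DE genes.
    """
    for term, frac in effects.enriched_terms.items():
        if not (0.0 < frac <= 1.0):
            raise ValueError(f"planted fraction for {term} must be in (0, 1]")
    rng = _rng(effects.seed if seed is None else seed, "annotation")
    genes = np.array(design.gene_ids())
    de_union = np.array(sorted(effects.de_union()))
    non_de = np.array(sorted(set(genes) - set(de_union)))
    rows: list[tuple[str, str]] = []
    for i in range(n_background_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        members = rng.choice(genes, size=min(size, genes.size), replace=False)
        rows.extend((g, f"T{i:03d}") for g in members)
    for term in sorted(effects.enriched_terms):
        frac = effects.enriched_terms[term]
        k_de = int(round(frac * planted_term_size))
        if k_de > de_union.size:
            raise ValueError(
                f"term {term!r} requests {k_de} DE genes but only "
                f"{de_union.size} are planted"
            )
        members = list(rng.choice(de_union, size=k_de, replace=False))
        members += list(
            rng.choice(non_de, size=planted_term_size - k_de, replace=False)
        )
        rows.extend((g, term) for g in members)
    return pd.DataFrame(rows, columns=["gene", "term"]).drop_duplicates(
        ignore_index=True
    )


def simulate_interactions(
    design: CohortDesign,
    effects: PlantedEffects,
    hub_degree: int = 25,
    background_rounds: int = 2,
    seed: int | None = None,
) -> EdgeList:
    """Sparse interaction edge list with one high-degree hub.

    Background edges are added in rounds of random perfect matchings, so
    every non-hub gene keeps degree <= background_rounds + 1; the planted
    hub (if any) additionally connects to ``hub_degree`` random partners.
    """
    rng = _rng(effects.seed if seed is None else seed, "interactions")
    genes = design.gene_ids()
    edges: set[tuple[str, str]] = set()
    for _ in range(background_rounds):
        perm = rng.permutation(genes)
        for a, b in zip(perm[0::2], perm[1::2]):
            edges.add((a, b) if a < b else (b, a))
    if effects.hub_gene is not None:
        partners = rng.choice(
            [g for g in genes if g != effects.hub_gene],
            size=hub_degree,
            replace=False,
        )
        for p in partners:
            a, b = (effects.hub_gene, p)
            edges.add((a, b) if a < b else (b, a))
    return EdgeList(edges=sorted(edges))


def simulate_qpcr(
    truth: CohortTruth,
    design: CohortDesign,
    genes: list[str] | None = None,
    reference_gene: str = "GAPDH",
    base_ct: float = 15.0,
    target_offset: float = 5.0,
    ct_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Triplicate Ct values per individual for target genes plus a reference.

    Model: reference Ct = ``base_ct``; target Ct = base_ct + offset −
    planted log2 expression of the individual's group, each replicate
    perturbed by N(0, ct_sd).  The reference gene carries no group effect,
    so with zero noise the ΔΔCt fold change inverts exactly to
    2**(planted log2FC).
    """
    if genes is None:
        genes = sorted(truth.true_de.get("severe_vs_healthy", {}))[:6]
    rng = _rng(seed, "qpcr")
    rows = []
    for individual, group in zip(design.individual_ids(), design.individual_groups()):
        contrast = f"{group}_vs_healthy"
        lfc_map = truth.true_de.get(contrast, {})
        for rep in (1, 2, 3):
            rows.append(
                (individual, group, reference_gene, rep,
                 base_ct + (rng.normal(0.0, ct_sd) if ct_sd > 0 else 0.0))
            )
        for gene in genes:
            lfc = lfc_map.get(gene, 0.0)
            for rep in (1, 2, 3):
                rows.append(
                    (individual, group, gene, rep,
                     base_ct + target_offset - lfc
                     + (rng.normal(0.0, ct_sd) if ct_sd > 0 else 0.0))
                )
    return pd.DataFrame(
        rows, columns=["individual", "group", "gene", "replicate", "ct"]
    )


def simulate_morphometry(
    design: CohortDesign,
    group_means: dict[str, dict[str, float]] | None = None,
    n_fields: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson per-field counts for each placenta (default 50 fields).

    ``group_means`` maps group → per-field mean counts for capillaries,
    terminal villi and CD45+/CD3+/CD19+ cells.
    """
    means = DEFAULT_MORPHOMETRY_MEANS if group_means is None else group_means
    measures = ("capillaries", "villi", "cd45", "cd3", "cd19")
    for group, mm in means.items():
        for measure, mu in mm.items():
            if mu < 0:
                raise ValueError(f"negative mean {mu} for {measure} in group {group}")
    rng = _rng(seed, "morphometry")
    rows = []
    for group in design.group_labels:
        mm = means[group]
        for i in range(1, design.individuals_per_group + 1):
            placenta = f"{group}_p{i:02d}"
            for fld in range(1, n_fields + 1):
                counts = [int(rng.poisson(mm.get(m, 0.0))) for m in measures]
                rows.append((placenta, group, fld, *counts))
    return pd.DataFrame(
        rows, columns=["placenta", "group", "field", *measures]
    )


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_cohort`."""

    matrix: ExpressionMatrix
    individuals: pd.DataFrame
    truth: CohortTruth
    annotation: pd.DataFrame
    interactions: EdgeList
    qpcr: pd.DataFrame
    morphometry: pd.DataFrame


def simulate_cohort(
    design: CohortDesign,
    effects: PlantedEffects,
    detect_prob_by_quantile: dict[float, float] | None = None,
    annotation_kwargs: dict | None = None,
    qpcr_ct_sd: float = 0.2,
    morphometry_means: dict | None = None,
) -> SimulatedCohort:
    """Run every simulator arm once and bundle the results with truth."""
    individuals = simulate_individuals(design, effects)
    matrix = pool_samples(
        individuals, design, measurement_sd=effects.measurement_sd, seed=effects.seed
    )
    matrix.flags = simulate_flags(matrix, detect_prob_by_quantile, seed=effects.seed)
    truth = truth_from_effects(effects)
    annotation = simulate_annotation(design, effects, **(annotation_kwargs or {}))
    interactions = simulate_interactions(design, effects)
    qpcr = simulate_qpcr(truth, design, ct_sd=qpcr_ct_sd, seed=effects.seed)
    morphometry = simulate_morphometry(
        design, group_means=morphometry_means, seed=effects.seed
    )
    return SimulatedCohort(
        matrix=matrix,
        individuals=individuals,
        truth=truth,
        annotation=annotation,
        interactions=interactions,
        qpcr=qpcr,
        morphometry=morphometry,
    )
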