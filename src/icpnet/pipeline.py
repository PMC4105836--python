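"""End-to-end orchestration: simulate → preprocess → DE → enrich → network →
core genes → validation, with a manifest and a truth-recovery report.

Every stage writes plain TSV/JSON files into the run directory so any
stage can be inspected or re-run from its persisted inputs.  A run is a
pure function of (config, seed): re-running with the same config yields a
byte-identical output tree.  Stage timings are printed to the console
only; the persisted log keeps the stage sequence without timestamps so
the output tree stays deterministic.
"""

from __future__ import annotations

import hashlib
import logging
import sys
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, enrichment, networks, preprocess, validation_stats
from . import io_formats as io
from . import synthetic_cohort as sc

logger = logging.getLogger("icpnet")


@dataclass
class RunConfig:
    """All knobs of a synthetic end-to-end run.

    Defaults reproduce the published gates: genes detected on >= 2 of 6
    arrays, fold change >= 1.5, p < 0.05, FDR < 0.05.
    """

    seed: int = 0
    # cohort
    n_genes: int = 4000
    n_de_mild: int = 80
    n_de_severe: int = 100
    frac_shared: float = 0.5
    lfc_range: tuple[float, float] = (1.0, 3.0)
    n_modules: int = 1
    module_size: int = 30
    module_factor_sd: float = 5.0
    individual_sd: float = 0.5
    measurement_sd: float = 0.2
    n_enriched_terms: int = 5
    enriched_fraction: float = 0.8
    qpcr_ct_sd: float = 0.2
    # gates
    min_flagged_arrays: int = 2
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    fdr_threshold: float = 0.05
    enrichment_fdr: float = 0.05
    r_min: float = 0.9
    top_fraction: float = 0.05
    variance_min: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.fc_threshold and 0 <= self.p_threshold <= 1
                and 0 <= self.fdr_threshold <= 1 and 0 < self.r_min <= 1
                and 0 < self.top_fraction <= 1):
            raise ValueError("config thresholds outside documented ranges")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["lfc_range"] = list(d["lfc_range"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        if "lfc_range" in d:
            d["lfc_range"] = tuple(d["lfc_range"])
        return cls(**d)

    def sha256(self) -> str:
        d = asdict(self)
        d["lfc_range"] = list(d["lfc_range"])
        return hashlib.sha256(
            yaml.safe_dump(d, sort_keys=True).encode()
        ).hexdigest()


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


class _Stage:
    """Console timing + deterministic file log line."""

    def __init__(self, name: str, log_lines: list[str]):
        self.name = name
        self.log_lines = log_lines

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc_type is None:
            logger.info(
                "stage %s: done in %.2fs", self.name, time.perf_counter() - self.t0
            )
            self.log_lines.append(f"stage {self.name}: ok")
        else:
            self.log_lines.append(f"stage {self.name}: FAILED ({exc})")
        return False


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full synthetic pipeline into ``out_dir``.

    Returns the recovery report (also persisted as ``report.json``).  A
    stage failure aborts the run with the stage name in the raised error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    report: dict = {"seed": config.seed}
    design = sc.CohortDesign(n_genes=config.n_genes)

    try:
        with _Stage("simulate", log_lines):
            effects = sc.make_standard_effects(
                design,
                seed=config.seed,
                n_de_mild=config.n_de_mild,
                n_de_severe=config.n_de_severe,
                frac_shared=config.frac_shared,
                lfc_range=config.lfc_range,
                n_modules=config.n_modules,
                module_size=config.module_size,
                module_factor_sd=config.module_factor_sd,
                n_enriched_terms=config.n_enriched_terms,
                enriched_fraction=config.enriched_fraction,
                individual_sd=config.individual_sd,
                measurement_sd=config.measurement_sd,
            )
            cohort = sc.simulate_cohort(design, effects, qpcr_ct_sd=config.qpcr_ct_sd)
            sim_dir = out / "simulate"
            sim_dir.mkdir(exist_ok=True)
            io.write_expression(cohort.matrix, sim_dir / "expression.tsv")
            io.write_flags(cohort.matrix.flags, sim_dir / "flags.tsv")
            io.write_design(cohort.matrix.design, sim_dir / "design.tsv")
            io.write_annotation(cohort.annotation, sim_dir / "annotation.tsv")
            io.write_edges(cohort.interactions, sim_dir / "interactions.tsv")
            io.write_qpcr(cohort.qpcr, sim_dir / "qpcr.tsv")
            io.write_morphometry(cohort.morphometry, sim_dir / "morphometry.tsv")
            io.write_json(cohort.truth.to_dict(), sim_dir / "truth.json")

        with _Stage("preprocess", log_lines):
            normalized = preprocess.preprocess(
                cohort.matrix, min_flagged_arrays=config.min_flagged_arrays
            )
            pre_dir = out / "preprocess"
            pre_dir.mkdir(exist_ok=True)
            io.write_expression(normalized, pre_dir / "normalized.tsv")
            report["n_genes_simulated"] = config.n_genes
            report["n_genes_after_filter"] = normalized.n_genes

        with _Stage("de", log_lines):
            de_tables = diffexpr.de_analysis(
                normalized,
                fc_threshold=config.fc_threshold,
                p_threshold=config.p_threshold,
                fdr_threshold=config.fdr_threshold,
            )
            de_dir = out / "de"
            de_dir.mkdir(exist_ok=True)
            calls = {}
            for name, table in de_tables.items():
                _write_tsv(table, de_dir / f"de_{name}.tsv")
                calls[name] = diffexpr.called_genes(table)
            algebra = diffexpr.de_set_algebra(
                calls["mild_vs_healthy"], calls["severe_vs_healthy"]
            )
            algebra_rows = [
                (cat, g, "/".join(dirs))
                for cat, mapping in algebra.items()
                for g, dirs in mapping.items()
            ]
            _write_tsv(
                pd.DataFrame(algebra_rows, columns=["category", "gene", "direction"]),
                de_dir / "set_algebra.tsv",
            )
            de_union = sorted(set(calls["mild_vs_healthy"]) | set(calls["severe_vs_healthy"]))
            report["n_de_mild"] = len(calls["mild_vs_healthy"])
            report["n_de_severe"] = len(calls["severe_vs_healthy"])
            if len(de_union) >= 2:
                cluster = diffexpr.hierarchical_cluster(normalized.values.loc[de_union])
                (de_dir / "gene_dendrogram.nwk").write_text(cluster.gene_newick + "\n")
                (de_dir / "array_dendrogram.nwk").write_text(cluster.array_newick + "\n")
                cluster.ordered.rename_axis("gene_id").reset_index().to_csv(
                    de_dir / "heatmap_matrix.tsv", sep="\t", index=False
                )

        with _Stage("enrich", log_lines):
            enr_dir = out / "enrichment"
            enr_dir.mkdir(exist_ok=True)
            universe = normalized.gene_ids
            annotation = cohort.annotation[cohort.annotation["gene"].isin(set(universe))]
            sig = {}
            for name in ("mild_vs_healthy", "severe_vs_healthy"):
                result = enrichment.enrich_all(set(calls[name]), annotation, universe)
                _write_tsv(result, enr_dir / f"enrich_{name}.tsv")
                sig[name] = enrichment.significant_terms(result, config.enrichment_fdr)
            cats = enrichment.categorize_terms(
                sig["mild_vs_healthy"], sig["severe_vs_healthy"]
            )
            cat_rows = [
                (cat, rank + 1, term)
                for cat, terms in cats.items()
                for rank, term in enumerate(terms)
            ]
            _write_tsv(
                pd.DataFrame(cat_rows, columns=["category", "rank", "term"]),
                enr_dir / "term_categories.tsv",
            )

        with _Stage("network", log_lines):
            net_dir = out / "network"
            net_dir.mkdir(exist_ok=True)
            candidates = networks.coexpression_candidates(
                normalized, extra_genes=de_union, variance_min=config.variance_min
            )
            corr = networks.pairwise_pearson(normalized, candidates)
            coexpr = networks.build_coexpression(corr, r_min=config.r_min)
            attrs = {}
            for cat, mapping in algebra.items():
                for g, dirs in mapping.items():
                    attrs[g] = {"membership": cat, "direction": "/".join(dirs)}
            inter_net = networks.interaction_network(cohort.interactions, attrs or None)
            edge_rows = [
                (a, b, coexpr[a][b]["weight"]) for a, b in sorted(coexpr.edges)
            ]
            _write_tsv(
                pd.DataFrame(edge_rows, columns=["gene1", "gene2", "r"]),
                net_dir / "coexpr_edges.tsv",
            )
            _write_tsv(networks.node_metrics(coexpr, attrs), net_dir / "node_metrics.tsv")
            core_df = networks.identify_core_genes(
                coexpr, inter_net, top_fraction=config.top_fraction
            )
            _write_tsv(core_df, net_dir / "core_genes.tsv")

        with _Stage("validation", log_lines):
            val_dir = out / "validation"
            val_dir.mkdir(exist_ok=True)
            ddct = validation_stats.ddct_fold_change(cohort.qpcr)
            _write_tsv(ddct.per_individual, val_dir / "qpcr_folds.tsv")
            _write_tsv(ddct.per_group, val_dir / "qpcr_groups.tsv")
            anova_rows = [
                (gene, res.f_stat, res.p_value, grp, p, validation_stats.significance_stars(p))
                for gene, res in sorted(ddct.anova.items())
                for grp, p in sorted(res.comparisons.items())
            ]
            _write_tsv(
                pd.DataFrame(
                    anova_rows,
                    columns=["gene", "anova_f", "anova_p", "comparison", "dunnett_p", "stars"],
                ),
                val_dir / "qpcr_anova.tsv",
            )
            morph_rows = []
            cap = validation_stats.capillaries_per_villus(cohort.morphometry)
            for measure, res in [
                ("capillaries_per_villus", cap),
                *[
                    (m, validation_stats.mean_cells_per_field(cohort.morphometry, m))
                    for m in validation_stats.MARKERS
                ],
            ]:
                for _, row in res.per_group.iterrows():
                    dunnett_p = res.anova.comparisons.get(row["group"], float("nan"))
                    morph_rows.append(
                        (measure, row["group"], row["mean"], row["sd"], row["n"],
                         res.anova.p_value, dunnett_p)
                    )
            _write_tsv(
                pd.DataFrame(
                    morph_rows,
                    columns=["measure", "group", "mean", "sd", "n", "anova_p", "dunnett_p"],
                ),
                val_dir / "morphometry_summary.tsv",
            )

        with _Stage("report", log_lines):
            report.update(
                recovery_metrics(
                    cohort.truth, calls, sig, coexpr, core_df, universe=set(universe)
                )
            )
            io.write_json(report, out / "report.json")
    except Exception as err:
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline aborted: {err}") from err

    config.to_yaml(out / "config.yaml")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": config.seed,
        "config_sha256": config.sha256(),
        "files": {str(p.relative_to(out)): _sha256_file(p) for p in files},
    }
    io.write_json(manifest, out / "manifest.json")
    return report


def recovery_metrics(
    truth: sc.CohortTruth,
    calls: dict[str, dict[str, str]],
    significant_terms: dict[str, list[str]],
    coexpr,
    core_df: pd.DataFrame,
    universe: set[str],
) -> dict:
    """Score called results against planted truth (synthetic mode only).

    Sensitivity counts planted genes recovered among those still in the
    analysis universe after filtering; empirical FDR is the fraction of
    calls that were not planted.
    """
    out: dict = {}
    for contrast, mapping in truth.true_de.items():
        called = set(calls.get(contrast, {}))
        planted = set(mapping)
        planted_testable = planted & universe
        tp = len(called & planted)
        out[f"sensitivity_{contrast}"] = (
            tp / len(planted_testable) if planted_testable else float("nan")
        )
        out[f"empirical_fdr_{contrast}"] = (
            (len(called) - tp) / len(called) if called else 0.0
        )
    module_genes = set(truth.true_modules)
    if module_genes:
        core_set, k = networks.max_kcore(coexpr)
        out["module_max_kcore_recovery"] = len(module_genes & core_set) / len(module_genes)
        out["max_kcore_level"] = k
    if truth.true_hubs:
        ranks = {g: i + 1 for i, g in enumerate(core_df["gene"])} if not core_df.empty else {}
        out["hub_rank"] = ranks.get(truth.true_hubs[0], 0)
    planted_terms = set(truth.true_enriched_terms)
    if planted_terms:
        found = set().union(*significant_terms.values()) if significant_terms else set()
        out["enriched_term_recovery"] = len(planted_terms & found) / len(planted_terms)
    return out


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
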