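"""End-to-end orchestration: cluster -> derive -> associate -> correct.

A run covers one or more tumor types (cohort directories). Per
(tumor type, gene set) pair the clustering gate and subtyping run;
feature tables are derived from the cohort's raw files; every
(partition, feature) pair is tested; Bonferroni correction is applied
per variable class across all tumor types together; recurrent
associations are extracted over non-composite tumor types.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sstats

from . import io as msio
from .associate import (
    DEFAULT_ALPHA, DEFAULT_COMPOSITE_TYPES, associate, bonferroni_families,
    find_recurrent, overall_bonferroni_count, results_frame,
)
from .cluster import (
    DEFAULT_GATE_ALPHA, DEFAULT_K_MAX, ClusterSolution, cluster_gene_set,
    nmi_matrix,
)
from .features import (
    FeatureTable, gene_level_copy_number, gene_level_mutation_matrix,
    global_methylation, load_clinical, mirna_rank_feature, region_sgol_scores,
    rppa_feature,
)
from .genesets import GeneSetCollection, filter_metabolic, parse_gmt

logger = logging.getLogger(__name__)

#: Cohort directory file names (the synthetic generator writes these).
COHORT_FILES = {
    "expression": "expression.tsv",
    "mirna": "mirna.tsv",
    "methylation": "methylation.tsv",
    "rppa": "rppa.tsv",
    "seg": "cn.seg",
    "maf": "mutations.maf.tsv",
    "clinical": "clinical.tsv",
    "genes_bed": "genes.bed",
    "regions_gmt": "regions.gmt",
}


@dataclass
class RunConfig:
    """Configuration of a pipeline run (flat YAML-compatible)."""

    cohorts: dict[str, str]  # tumor type -> cohort directory
    gene_sets_gmt: str
    out_dir: str
    collection: str = "user"
    apply_metabolic_filter: bool = False
    gate_alpha: float = DEFAULT_GATE_ALPHA
    k_max: int = DEFAULT_K_MAX
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    composite_types: frozenset[str] = DEFAULT_COMPOSITE_TYPES
    sgol_per_sample: bool = True
    count_invalid_in_m: bool = False
    gate_space: str = "rank"

    def __post_init__(self) -> None:
        if not 0 < self.gate_alpha < 1 or not 0 < self.alpha < 1:
            raise ValueError("gate_alpha and alpha must be in (0,1)")
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        self.composite_types = frozenset(self.composite_types)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def derive_cohort_features(cohort_dir: str | Path, seed: int,
                           sgol_per_sample: bool = True) -> list[FeatureTable]:
    """Build every available feature table from a cohort directory.

    Missing optional files simply skip their variable class.
    """
    cohort_dir = Path(cohort_dir)
    tables: list[FeatureTable] = []

    seg_path = cohort_dir / COHORT_FILES["seg"]
    bed_path = cohort_dir / COHORT_FILES["genes_bed"]
    reg_path = cohort_dir / COHORT_FILES["regions_gmt"]
    if seg_path.exists() and bed_path.exists() and reg_path.exists():
        seg = msio.read_seg(seg_path)
        coords = msio.read_bed(bed_path)
        regions = {s.name: sorted(s.genes) for s in parse_gmt(reg_path)}
        gene_cn = gene_level_copy_number(seg, coords)
        tables.append(region_sgol_scores(gene_cn, regions,
                                         per_sample=sgol_per_sample))

    meth_path = cohort_dir / COHORT_FILES["methylation"]
    if meth_path.exists():
        tables.append(global_methylation(msio.read_matrix(meth_path)))

    mirna_path = cohort_dir / COHORT_FILES["mirna"]
    if mirna_path.exists():
        tables.append(mirna_rank_feature(msio.read_matrix(mirna_path), seed=seed))

    maf_path = cohort_dir / COHORT_FILES["maf"]
    if maf_path.exists():
        expr_cols = None
        expr_path = cohort_dir / COHORT_FILES["expression"]
        if expr_path.exists():
            expr_cols = pd.read_csv(expr_path, sep="\t", index_col=0,
                                    nrows=0).columns.tolist()
        gene_tab, point_tab = gene_level_mutation_matrix(
            msio.read_maf(maf_path), samples=expr_cols)
        tables.extend([gene_tab, point_tab])

    rppa_path = cohort_dir / COHORT_FILES["rppa"]
    if rppa_path.exists():
        tables.append(rppa_feature(msio.read_matrix(rppa_path)))

    clin_path = cohort_dir / COHORT_FILES["clinical"]
    if clin_path.exists():
        tables.extend(load_clinical(msio.read_clinical(clin_path)))
    return tables


def cohort_tables(cohort, seed: int, sgol_per_sample: bool = True) -> list[FeatureTable]:
    """Derive every feature table from an in-memory synthetic cohort
    (same derivations as :func:`derive_cohort_features`, no file I/O)."""
    tables: list[FeatureTable] = []
    gene_cn = gene_level_copy_number(cohort.seg, cohort.gene_coords)
    tables.append(region_sgol_scores(gene_cn, cohort.regions,
                                     per_sample=sgol_per_sample))
    tables.append(global_methylation(cohort.methylation))
    tables.append(mirna_rank_feature(cohort.mirna, seed=seed))
    gene_tab, point_tab = gene_level_mutation_matrix(
        cohort.calls, samples=cohort.expression.columns.tolist())
    tables.extend([gene_tab, point_tab])
    tables.append(rppa_feature(cohort.rppa))
    tables.extend(load_clinical(cohort.clinical))
    return tables


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write deterministic outputs.

    Writes, under ``config.out_dir``: ``clusters.tsv`` (one row per
    sample per clustered pair), ``associations.tsv``, ``recurrent.tsv``,
    ``nmi_<tumor>.tsv`` per tumor type, and ``run_log.json`` with the
    bookkeeping counts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collection = parse_gmt(config.gene_sets_gmt, collection=config.collection)
    if config.apply_metabolic_filter:
        collection = filter_metabolic(collection)
    if len(collection) == 0:
        raise ValueError("no usable gene sets after filtering")

    all_solutions: list[ClusterSolution] = []
    all_results = []
    cluster_rows = []
    for tumor in sorted(config.cohorts):
        cohort_dir = Path(config.cohorts[tumor])
        expr = msio.read_matrix(cohort_dir / COHORT_FILES["expression"])
        tables = derive_cohort_features(cohort_dir, seed=config.seed,
                                        sgol_per_sample=config.sgol_per_sample)
        sample_universe = set(expr.columns)
        for t in tables:
            sample_universe &= set(t.samples)
        if not sample_universe:
            raise ValueError(f"{tumor}: empty sample intersection across inputs")
        solutions = []
        for gs in collection:
            sol = cluster_gene_set(expr, gs, tumor_type=tumor,
                                   gate_alpha=config.gate_alpha,
                                   k_max=config.k_max,
                                   gate_space=config.gate_space)
            solutions.append(sol)
            if sol.clustered:
                for sample, cl in sol.assignments.items():
                    cluster_rows.append((tumor, gs.name, sample, cl, sol.k,
                                         sol.avg_silhouette, sol.duda_hart_p,
                                         sol.passed_gate))
                all_results.extend(associate(sol, tables,
                                             collection=config.collection))
        all_solutions.extend(solutions)
        nmi_df = nmi_matrix(solutions)
        nmi_df.to_csv(out / f"nmi_{tumor}.tsv", sep="\t", float_format="%.6g")

    families = bonferroni_families(all_results, alpha=config.alpha,
                                   count_invalid=config.count_invalid_in_m)
    assoc_df = results_frame(all_results)
    assoc_df.to_csv(out / "associations.tsv", sep="\t", index=False,
                    float_format="%.6g")
    recurrent = find_recurrent(all_results, composite_types=config.composite_types)
    recurrent.to_csv(out / "recurrent.tsv", sep="\t", index=False)
    clusters_df = pd.DataFrame(cluster_rows, columns=[
        "tumor_type", "gene_set", "sample", "cluster", "k", "avg_silhouette",
        "duda_hart_p", "passed_gate"])
    clusters_df.to_csv(out / "clusters.tsv", sep="\t", index=False,
                       float_format="%.6g")

    k_hist = Counter(s.k for s in all_solutions if s.clustered)
    log = {
        "config": {k: (sorted(v) if isinstance(v, frozenset) else v)
                   for k, v in vars(config).items()},
        "pairs_total": len(all_solutions),
        "pairs_gated_in": sum(s.clustered for s in all_solutions),
        "pairs_gated_out": sum(s.status == "gated_out" for s in all_solutions),
        "pairs_unusable": sum(s.status == "unusable" for s in all_solutions),
        "skipped_pairs": [
            {"tumor_type": s.tumor_type, "gene_set": s.gene_set,
             "status": s.status, "reason": s.reason}
            for s in all_solutions if not s.clustered
        ],
        "k_histogram": {str(k): k_hist[k] for k in sorted(k_hist)},
        "tests_run": len(all_results),
        "tests_valid": sum(r.valid for r in all_results),
        "significant_per_class": {
            f.variable_class: sum(
                r.significant for r in all_results
                if r.variable_class == f.variable_class)
            for f in families
        },
        "family_sizes": {f.variable_class: f.m for f in families},
        "significant_total": sum(r.significant for r in all_results),
        "significant_overall_bonferroni": overall_bonferroni_count(
            all_results, alpha=config.alpha),
        "recurrent_total": int(len(recurrent)),
    }
    with (out / "run_log.json").open("w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    return out


def summarize_run(run_dir: str | Path) -> dict:
    """Aggregate a finished run: significant-association counts by tumor
    type and by gene set, plus the Spearman correlation between a tumor
    type's sample count and its association count."""
    run_dir = Path(run_dir)
    assoc_path = run_dir / "associations.tsv"
    log_path = run_dir / "run_log.json"
    if not assoc_path.exists() or not log_path.exists():
        raise FileNotFoundError(f"{run_dir} is not a completed run directory")
    assoc = pd.read_csv(assoc_path, sep="\t")
    clusters = pd.read_csv(run_dir / "clusters.tsv", sep="\t")
    if len(assoc):
        sig = assoc[assoc["significant"] == True]  # noqa: E712
        by_tumor = sig.groupby("tumor_type").size().to_dict()
        by_set = sig.groupby("gene_set").size().to_dict()
    else:
        by_tumor, by_set = {}, {}
    n_samples = clusters.groupby("tumor_type")["sample"].nunique() if len(clusters) else pd.Series(dtype=int)
    rho = float("nan")
    if len(n_samples) >= 3:
        counts = [by_tumor.get(t, 0) for t in n_samples.index]
        if np.ptp(counts) > 0 and np.ptp(n_samples.to_numpy()) > 0:
            rho = float(sstats.spearmanr(n_samples.to_numpy(), counts).statistic)
    return {
        "significant_by_tumor_type": by_tumor,
        "significant_by_gene_set": by_set,
        "samples_vs_associations_spearman": rho,
    }


# ---------------------------------------------------------------------------
# study bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class PairAccounting:
    """Arithmetic bookkeeping of a (gene set x tumor type) screen."""

    n_gene_sets: int
    n_tumor_types: int
    n_gated_in: int
    n_k2: int
    collection_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def pairs_total(self) -> int:
        return self.n_gene_sets * self.n_tumor_types

    @property
    def gated_in_pct(self) -> float:
        return 100.0 * self.n_gated_in / self.pairs_total

    @property
    def k2_pct(self) -> float:
        return 100.0 * self.n_k2 / self.n_gated_in

    @property
    def collection_total(self) -> int:
        return sum(self.collection_sizes.values())


def pair_accounting(n_gene_sets: int, n_tumor_types: int, n_gated_in: int,
                    n_k2: int, collection_sizes: dict[str, int] | None = None) -> PairAccounting:
    """Bookkeeping identities of a screen: total pairs, fraction passing
    the separation gate, fraction resolved at k=2, collection sizes."""
    return PairAccounting(n_gene_sets=n_gene_sets, n_tumor_types=n_tumor_types,
                          n_gated_in=n_gated_in, n_k2=n_k2,
                          collection_sizes=collection_sizes or {})
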