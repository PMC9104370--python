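"""Per-sample feature tables for the nine variable classes.

Molecular classes: region copy-number (SGOL-style scores), global DNA
methylation, miRNA expression (rank-transformed with random tie
resolution), specific point mutations, gene-level mutations, and RPPA
protein abundance. Phenotypic classes: clinical covariates, overall
survival, and recurrence-free survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VARIABLE_CLASSES = (
    "copy_number", "methylation_global", "mirna", "point_mutation",
    "gene_mutation", "protein_rppa", "clinical",
    "overall_survival", "recurrence_free_survival",
)

#: MAF variant classifications counted as non-synonymous.
NONSYNONYMOUS_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
    "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins", "Splice_Site",
    "Nonstop_Mutation", "Translation_Start_Site",
})

SGOL_POS_THRESHOLD = 0.5
SGOL_NEG_THRESHOLD = -0.5
MAX_CATEGORICAL_LEVELS = 10


@dataclass
class FeatureTable:
    """Features of one variable class for a set of samples.

    ``kind`` is "continuous" or "categorical" with ``data`` holding
    features as rows and samples as columns, or "survival" with rows
    ``time`` (days) and ``event`` (0/1) and the feature named after the
    endpoint.
    """

    variable_class: str
    kind: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.variable_class not in VARIABLE_CLASSES:
            raise ValueError(f"unknown variable class {self.variable_class!r}")
        if self.kind not in ("continuous", "categorical", "survival"):
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def feature_names(self) -> list[str]:
        if self.kind == "survival":
            return [self.variable_class]
        return [str(f) for f in self.data.index]


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

def gene_level_copy_number(seg: pd.DataFrame, gene_coords: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene the seg.mean of its overlapping segment(s).

    When several segments overlap a gene, the length-weighted mean of
    their seg.means over the overlapped bases is used. Genes overlapped
    by no segment of a sample get 0 (with a warning). Coordinates are
    1-based inclusive on both sides.
    """
    if (seg["loc.start"] > seg["loc.end"]).any():
        raise ValueError("malformed segment: start > end")
    samples = sorted(seg["ID"].unique())
    genes = gene_coords["gene"].tolist()
    out = np.zeros((len(genes), len(samples)))
    uncovered = 0
    by_sample_chrom = {
        key: grp for key, grp in seg.groupby(["ID", "chrom"], sort=False)
    }
    for gi, g in enumerate(gene_coords.itertuples(index=False)):
        for si, sample in enumerate(samples):
            grp = by_sample_chrom.get((sample, g.chrom))
            if grp is None:
                uncovered += 1
                continue
            start = grp["loc.start"].to_numpy()
            end = grp["loc.end"].to_numpy()
            ov = np.minimum(end, g.end) - np.maximum(start, g.start) + 1
            mask = ov > 0
            if not mask.any():
                uncovered += 1
                continue
            w = ov[mask].astype(float)
            out[gi, si] = float(np.average(grp["seg.mean"].to_numpy()[mask], weights=w))
    if uncovered:
        logger.warning("gene_level_copy_number: %d (gene, sample) cells uncovered -> 0",
                       uncovered)
    return pd.DataFrame(out, index=genes, columns=samples)


def region_sgol_scores(
    gene_cn: pd.DataFrame,
    regions: dict[str, list[str]],
    pos_threshold: float = SGOL_POS_THRESHOLD,
    neg_threshold: float = SGOL_NEG_THRESHOLD,
    per_sample: bool = True,
) -> FeatureTable:
    """SGOL-style gain/loss scores per genomic region.

    Gene-level values inside the dead zone [neg_threshold, pos_threshold]
    are zeroed; each region's score is the mean of the thresholded values
    over its genes. With ``per_sample=True`` (default) this yields one
    score per (region, sample), suitable for subtype association tests.
    ``per_sample=False`` gives the cohort-level variant, first summing
    thresholded values across samples per gene, then averaging over
    region genes (one number per region, broadcast to all samples).
    """
    if not (neg_threshold < 0 < pos_threshold):
        raise ValueError("thresholds must satisfy neg < 0 < pos")
    values = gene_cn.to_numpy(dtype=float)
    kept = np.where((values > pos_threshold) | (values < neg_threshold), values, 0.0)
    kept = pd.DataFrame(kept, index=gene_cn.index, columns=gene_cn.columns)
    rows = {}
    for name, genes in regions.items():
        present = [g for g in genes if g in kept.index]
        if not present:
            logger.warning("region %s has no genes in the matrix; dropped", name)
            continue
        if per_sample:
            rows[name] = kept.loc[present].mean(axis=0)
        else:
            cohort = kept.loc[present].sum(axis=1).mean()
            rows[name] = pd.Series(cohort, index=kept.columns)
    if rows:
        data = pd.DataFrame(rows).T
        data.columns = gene_cn.columns
    else:
        data = pd.DataFrame(columns=gene_cn.columns)
    return FeatureTable(variable_class="copy_number", kind="continuous", data=data)


# ---------------------------------------------------------------------------
# methylation, mutations, miRNA / RPPA
# ---------------------------------------------------------------------------

def global_methylation(meth: pd.DataFrame) -> FeatureTable:
    """Sum gene-level methylation over genes: one global value per sample.

    Missing gene values are ignored (count logged); a sample with no
    observed genes at all gets a missing feature value.
    """
    n_missing = int(meth.isna().sum().sum())
    if n_missing:
        logger.info("global_methylation: ignoring %d missing gene values", n_missing)
    total = meth.sum(axis=0, skipna=True)
    total[meth.notna().sum(axis=0) == 0] = np.nan
    data = pd.DataFrame([total], index=["global_methylation"])
    return FeatureTable(variable_class="methylation_global", kind="continuous", data=data)


def gene_level_mutation_matrix(
    calls: pd.DataFrame,
    samples: list[str] | None = None,
    nonsynonymous_classes: frozenset[str] = NONSYNONYMOUS_CLASSES,
) -> tuple[FeatureTable, FeatureTable]:
    """Collapse mutation calls to binary feature tables.

    Calls are filtered to non-synonymous variant classifications. The
    gene-level table marks a sample mutated in a gene if it carries one
    or more retained calls for that gene; the point-mutation table has
    one binary row per distinct (gene, protein change) pair.

    ``samples`` fixes the column universe (samples without calls get
    all-zero columns); defaults to the samples observed in ``calls``.
    """
    kept = calls[calls["Variant_Classification"].isin(nonsynonymous_classes)]
    kept = kept.drop_duplicates(
        subset=["Tumor_Sample_Barcode", "Hugo_Symbol", "Protein_Change"]
    )
    if samples is None:
        samples = sorted(calls["Tumor_Sample_Barcode"].unique())
    genes = sorted(kept["Hugo_Symbol"].unique())
    gene_mat = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    for row in kept.itertuples(index=False):
        if row.Tumor_Sample_Barcode in gene_mat.columns:
            gene_mat.loc[row.Hugo_Symbol, row.Tumor_Sample_Barcode] = 1
    pm_index = sorted(
        {(r.Hugo_Symbol, r.Protein_Change) for r in kept.itertuples(index=False)}
    )
    pm_names = [f"{g}:{p}" for g, p in pm_index]
    pm_mat = pd.DataFrame(0, index=pm_names, columns=samples, dtype=int)
    for row in kept.itertuples(index=False):
        if row.Tumor_Sample_Barcode in pm_mat.columns:
            pm_mat.loc[f"{row.Hugo_Symbol}:{row.Protein_Change}",
                       row.Tumor_Sample_Barcode] = 1
    return (
        FeatureTable(variable_class="gene_mutation", kind="categorical", data=gene_mat),
        FeatureTable(variable_class="point_mutation", kind="categorical", data=pm_mat),
    )


def mirna_rank_feature(mirna: pd.DataFrame, seed: int) -> FeatureTable:
    """Rank-transform miRNA expression with random resolution of ties.

    Because many miRNAs are zero in a large share of samples, ordinary
    average ranks would leave massive tie groups; instead every tie
    group receives distinct consecutive ranks in an order drawn
    uniformly at random (deterministic given ``seed``). Each row of the
    output is a permutation of 1..n_samples.
    """
    rng = np.random.default_rng(seed)
    values = mirna.to_numpy(dtype=float)
    n = values.shape[1]
    out = np.empty_like(values)
    for i, row in enumerate(values):
        jitter = rng.permutation(n)
        order = np.lexsort((jitter, row))
        ranks = np.empty(n)
        ranks[order] = np.arange(1, n + 1)
        out[i] = ranks
    data = pd.DataFrame(out, index=mirna.index, columns=mirna.columns)
    return FeatureTable(variable_class="mirna", kind="continuous", data=data)


def rppa_feature(rppa: pd.DataFrame) -> FeatureTable:
    """RPPA protein abundance as a generic continuous table (ordinary
    average-rank ties downstream; no transform applied here)."""
    return FeatureTable(variable_class="protein_rppa", kind="continuous",
                        data=rppa.astype(float))


# ---------------------------------------------------------------------------
# clinical and survival
# ---------------------------------------------------------------------------

def load_clinical(table: pd.DataFrame) -> list[FeatureTable]:
    """Split a clinical table into clinical / OS / RFS feature tables.

    Survival endpoints come from paired columns (``os_time``/``os_event``,
    ``rfs_time``/``rfs_event``); records with negative times are dropped
    with a warning, non-0/1 events are an error. Remaining columns
    become clinical features: numeric columns continuous, others
    categorical; categorical columns with more than 10 levels are
    rejected with a warning (free-text guard).
    """
    tables: list[FeatureTable] = []
    used: set[str] = set()
    for cls, prefix in (("overall_survival", "os"),
                        ("recurrence_free_survival", "rfs")):
        tcol, ecol = f"{prefix}_time", f"{prefix}_event"
        if tcol in table.columns and ecol in table.columns:
            used |= {tcol, ecol}
            time = pd.to_numeric(table[tcol], errors="coerce")
            event = pd.to_numeric(table[ecol], errors="coerce")
            bad_event = event.dropna()[~event.dropna().isin([0, 1])]
            if len(bad_event):
                raise ValueError(
                    f"{ecol}: event values must be 0/1, got {bad_event.unique()}")
            neg = time < 0
            if neg.any():
                logger.warning("%s: dropping %d records with negative time",
                               tcol, int(neg.sum()))
                time = time.where(~neg)
                event = event.where(~neg)
            data = pd.DataFrame({"time": time, "event": event}).T
            data.columns = table.index
            tables.append(FeatureTable(variable_class=cls, kind="survival", data=data))
    cont_rows, cat_rows = {}, {}
    for col in table.columns:
        if col in used:
            continue
        numeric = pd.to_numeric(table[col], errors="coerce")
        if numeric.notna().sum() == table[col].notna().sum():
            cont_rows[col] = numeric
        else:
            levels = table[col].dropna().unique()
            if len(levels) > MAX_CATEGORICAL_LEVELS:
                logger.warning("clinical column %s rejected: %d levels (>%d)",
                               col, len(levels), MAX_CATEGORICAL_LEVELS)
                continue
            cat_rows[col] = table[col]
    if cont_rows:
        data = pd.DataFrame(cont_rows).T
        data.columns = table.index
        tables.append(FeatureTable(variable_class="clinical", kind="continuous", data=data))
    if cat_rows:
        data = pd.DataFrame(cat_rows).T
        data.columns = table.index
        tables.append(FeatureTable(variable_class="clinical", kind="categorical", data=data))
    return tables


def ordinary_rank_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Average-rank each row (standard tie handling); used for RPPA."""
    return pd.DataFrame(stats.rankdata(df.to_numpy(float), axis=1),
                        index=df.index, columns=df.columns)
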