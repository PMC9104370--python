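"""Association tests between metabolic subtypes and sample features.

The test dispatch depends on the feature's variable kind:

* continuous -> Mann-Whitney U for k=2 subtypes (exact enumeration when
  both groups have <=8 samples and there are no ties, otherwise the
  normal approximation with tie correction), Kruskal-Wallis for k>2;
* categorical -> Fisher's exact test on 2x2 tables, Pearson chi-square
  (no continuity correction) on larger tables after iteratively removing
  category levels whose expected count falls below 5;
* survival -> the log-rank test over the k subtypes, declared invalid
  when any subtype's expected event count is below 5.

Bonferroni correction is applied per variable class, pooling the tests
of all tumor types and gene sets of that class into one family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterSolution
from .features import FeatureTable

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
MIN_EXPECTED = 5.0
MIN_EXPECTED_EVENTS = 5.0
#: Point-mutation features mutated in fewer samples than this overall are
#: skipped as untestable (degenerate Fisher margins).
MIN_MUTATED_SAMPLES = 3

#: TCGA cohorts that are unions of narrower cohorts; excluded from
#: recurrence counting.
DEFAULT_COMPOSITE_TYPES = frozenset({"LUNG", "KIPAN", "GBMLGG", "COADREAD", "STES"})


@dataclass
class AssociationResult:
    tumor_type: str
    gene_set: str
    collection: str
    variable_class: str
    feature: str
    test: str
    k: int
    statistic: float = float("nan")
    p_value: float = float("nan")
    valid: bool = False
    n_used: int = 0
    reason: str = ""
    significant: bool = False
    m_family: int = 0


# ---------------------------------------------------------------------------
# individual tests
# ---------------------------------------------------------------------------

def test_continuous(values: np.ndarray, assignments: np.ndarray) -> tuple[str, float, float, bool, int, str]:
    """Mann-Whitney (k=2) / Kruskal-Wallis (k>2) for a continuous feature.

    Samples with missing values are dropped pairwise. Returns
    (test name, statistic, p, valid, n_used, reason).
    """
    values = np.asarray(values, dtype=float)
    assignments = np.asarray(assignments)
    ok = ~np.isnan(values)
    values, assignments = values[ok], assignments[ok]
    clusters = np.unique(assignments)
    k = clusters.size
    groups = [values[assignments == c] for c in clusters]
    name = "mann_whitney" if k == 2 else "kruskal_wallis"
    if any(len(g) == 0 for g in groups) or k < 2:
        return name, np.nan, np.nan, False, int(values.size), "empty cluster"
    if np.ptp(values) == 0:
        return name, np.nan, 1.0, True, int(values.size), ""
    if k == 2:
        has_ties = np.unique(values).size < values.size
        method = "exact" if (max(map(len, groups)) <= 8 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided",
                                 method=method)
        return name, float(res.statistic), float(res.pvalue), True, int(values.size), ""
    res = stats.kruskal(*groups)
    return name, float(res.statistic), float(res.pvalue), True, int(values.size), ""


def _expected_counts(table: np.ndarray) -> np.ndarray:
    total = table.sum()
    return np.outer(table.sum(axis=1), table.sum(axis=0)) / total


def reduce_contingency(table: pd.DataFrame, min_expected: float = MIN_EXPECTED) -> pd.DataFrame:
    """Iteratively drop category levels (rows) with low expected counts.

    Repeatedly removes the level whose smallest expected cell is lowest
    among levels having any expected cell < ``min_expected``,
    recomputing expectations after each removal.
    """
    tab = table.copy()
    while tab.shape[0] >= 2:
        exp = _expected_counts(tab.to_numpy(dtype=float))
        row_min = exp.min(axis=1)
        offenders = np.where(row_min < min_expected)[0]
        if offenders.size == 0:
            break
        worst = offenders[np.argmin(row_min[offenders])]
        tab = tab.drop(index=tab.index[worst])
    return tab


def test_categorical(
    labels: np.ndarray, assignments: np.ndarray, min_expected: float = MIN_EXPECTED
) -> tuple[str, float, float, bool, int, str]:
    """Fisher exact (2x2) / chi-square (larger) on levels x clusters.

    A 2x2 table goes straight to Fisher's exact test. For larger tables,
    levels with expected count below ``min_expected`` in any cluster are
    removed iteratively before the chi-square test; if fewer than 2
    levels survive, or a cluster is emptied, the test is invalid, and a
    table reduced to exactly 2x2 is routed to Fisher for consistency.
    """
    labels = pd.Series(np.asarray(labels, dtype=object))
    assignments = np.asarray(assignments)
    ok = labels.notna().to_numpy()
    labels, assignments = labels[ok], assignments[ok]
    n_used = int(len(labels))
    if len(labels) == 0 or pd.unique(labels).size < 2:
        return "fisher_exact", np.nan, np.nan, False, n_used, "<2 category levels"
    table = pd.crosstab(labels.to_numpy(), assignments)
    if table.shape != (2, 2):
        table = reduce_contingency(table, min_expected)
    if table.shape[0] < 2:
        return "fisher_exact", np.nan, np.nan, False, n_used, "<2 levels after reduction"
    if (table.sum(axis=0) == 0).any():
        return "fisher_exact", np.nan, np.nan, False, n_used, "cluster emptied by reduction"
    n_used = int(table.to_numpy().sum())
    if table.shape == (2, 2):
        odds, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
        return "fisher_exact", float(odds), float(p), True, n_used, ""
    res = stats.chi2_contingency(table.to_numpy(), correction=False)
    return "chi_square", float(res.statistic), float(res.pvalue), True, n_used, ""


def logrank_test(
    times: np.ndarray, events: np.ndarray, assignments: np.ndarray
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """k-group log-rank test with per-group observed/expected events.

    Returns (chi2 statistic with k-1 df, p, observed per group, expected
    per group). Expected events per group g are
    ``sum over event times of deaths * (group at risk / total at risk)``.
    The statistic uses the full hypergeometric covariance of the
    observed-minus-expected vector (first group dropped).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    assignments = np.asarray(assignments)
    clusters = np.unique(assignments)
    k = clusters.size
    gi = np.searchsorted(clusters, assignments)
    event_times = np.unique(times[events == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n_t = at_risk.sum()
        d_t = int(((times == t) & (events == 1)).sum())
        n_g = np.bincount(gi[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gi[(times == t) & (events == 1)], minlength=k).astype(float)
        observed += d_g
        expected += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            mult = d_t * (n_t - d_t) / (n_t - 1)
            cov += mult * (np.diag(frac) - np.outer(frac, frac))
    diff = (observed - expected)[1:]
    v = cov[1:, 1:]
    try:
        stat = float(diff @ np.linalg.solve(v, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(v) @ diff)
    p = float(stats.chi2.sf(stat, df=k - 1))
    return stat, p, observed, expected


def test_survival(
    times: np.ndarray,
    events: np.ndarray,
    assignments: np.ndarray,
    min_expected_events: float = MIN_EXPECTED_EVENTS,
) -> tuple[str, float, float, bool, int, str]:
    """Log-rank test, invalid when any subtype's expected events < 5."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    assignments = np.asarray(assignments)
    ok = ~(np.isnan(times) | np.isnan(events))
    times, events, assignments = times[ok], events[ok], assignments[ok]
    n_used = int(times.size)
    if np.unique(assignments).size < 2:
        return "log_rank", np.nan, np.nan, False, n_used, "<2 clusters"
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    events = events.astype(int)
    if events.sum() == 0:
        return "log_rank", np.nan, np.nan, False, n_used, "no events"
    stat, p, _, expected = logrank_test(times, events, assignments)
    if expected.min() < min_expected_events:
        return ("log_rank", stat, np.nan, False, n_used,
                f"min expected events {expected.min():.2f} < {min_expected_events:g}")
    return "log_rank", stat, p, True, n_used, ""


# ---------------------------------------------------------------------------
# engine: dispatch over a solution and feature tables
# ---------------------------------------------------------------------------

def associate(
    solution: ClusterSolution,
    tables: list[FeatureTable],
    collection: str = "user",
    min_mutated: int = MIN_MUTATED_SAMPLES,
) -> list[AssociationResult]:
    """Test one clustered solution against every feature of every table.

    Binary mutation features (gene_mutation / point_mutation classes)
    are presented to the categorical test as mutated / wild-type labels;
    point-mutation features mutated in fewer than ``min_mutated``
    samples overall are skipped as untestable. Each test uses the
    samples shared between the clustering and the feature table.
    """
    if not solution.clustered:
        return []
    out: list[AssociationResult] = []
    assign = solution.assignments
    for table in tables:
        shared = assign.index.intersection(table.samples)
        if len(shared) == 0:
            logger.warning("no shared samples for class %s", table.variable_class)
            continue
        a = assign.loc[shared].to_numpy()
        base = dict(tumor_type=solution.tumor_type, gene_set=solution.gene_set,
                    collection=collection, k=solution.k,
                    variable_class=table.variable_class)
        if table.kind == "survival":
            times = pd.to_numeric(table.data.loc["time", shared]).to_numpy()
            events = pd.to_numeric(table.data.loc["event", shared]).to_numpy()
            name, s, p, valid, n, reason = test_survival(times, events, a)
            out.append(AssociationResult(**base, feature=table.variable_class,
                                         test=name, statistic=s, p_value=p,
                                         valid=valid, n_used=n, reason=reason))
            continue
        for feat in table.data.index:
            row = table.data.loc[feat, shared]
            if table.kind == "continuous":
                name, s, p, valid, n, reason = test_continuous(
                    pd.to_numeric(row, errors="coerce").to_numpy(), a)
            else:
                vals = row.to_numpy()
                if table.variable_class in ("gene_mutation", "point_mutation"):
                    total = int(pd.to_numeric(row).sum())
                    if table.variable_class == "point_mutation" and total < min_mutated:
                        logger.debug("skipping %s: %d mutated samples", feat, total)
                        continue
                    vals = np.where(pd.to_numeric(row).to_numpy() > 0,
                                    "mutant", "wild_type")
                name, s, p, valid, n, reason = test_categorical(vals, a)
            out.append(AssociationResult(**base, feature=str(feat), test=name,
                                         statistic=s, p_value=p, valid=valid,
                                         n_used=n, reason=reason))
    return out


# ---------------------------------------------------------------------------
# correction and recurrence
# ---------------------------------------------------------------------------

@dataclass
class CorrectionFamily:
    variable_class: str
    m: int
    alpha: float
    threshold: float = field(init=False)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("family needs at least one test")
        self.threshold = self.alpha / self.m


def bonferroni_families(
    results: list[AssociationResult],
    alpha: float = DEFAULT_ALPHA,
    count_invalid: bool = False,
) -> list[CorrectionFamily]:
    """Set significance flags with a per-class Bonferroni correction.

    For each variable class, the family size m is the number of valid
    tests of that class pooled over all tumor types and gene sets
    (``count_invalid=True`` counts every attempted test instead). A
    result is significant iff it is valid and p < alpha/m. Flags are set
    in place; the per-class families are returned.
    """
    families: list[CorrectionFamily] = []
    classes = sorted({r.variable_class for r in results})
    for cls in classes:
        in_cls = [r for r in results if r.variable_class == cls]
        m = len(in_cls) if count_invalid else sum(r.valid for r in in_cls)
        if m == 0:
            continue
        fam = CorrectionFamily(variable_class=cls, m=m, alpha=alpha)
        for r in in_cls:
            r.m_family = m
            r.significant = bool(r.valid and r.p_value < fam.threshold)
        families.append(fam)
    return families


def overall_bonferroni_count(results: list[AssociationResult], alpha: float = DEFAULT_ALPHA) -> int:
    """Summary count under a single correction over all classes together."""
    valid = [r for r in results if r.valid]
    if not valid:
        return 0
    thr = alpha / len(valid)
    return sum(r.p_value < thr for r in valid)


def find_recurrent(
    results: list[AssociationResult],
    composite_types: frozenset[str] = DEFAULT_COMPOSITE_TYPES,
) -> pd.DataFrame:
    """Associations significant in more than one non-composite tumor type.

    Groups significant results by (gene set, variable class, feature),
    drops composite tumor types first, and keeps groups spanning >=2
    distinct tumor types. Sorted by recurrence count descending, then
    by (gene_set, variable_class, feature).
    """
    rows: dict[tuple[str, str, str], set[str]] = {}
    for r in results:
        if not r.significant or r.tumor_type in composite_types:
            continue
        rows.setdefault((r.gene_set, r.variable_class, r.feature), set()).add(r.tumor_type)
    records = [
        {"gene_set": gs, "variable_class": vc, "feature": ft,
         "n_tumor_types": len(tt), "tumor_types": ";".join(sorted(tt))}
        for (gs, vc, ft), tt in rows.items() if len(tt) >= 2
    ]
    df = pd.DataFrame(records, columns=["gene_set", "variable_class", "feature",
                                        "n_tumor_types", "tumor_types"])
    if len(df):
        df = df.sort_values(
            ["n_tumor_types", "gene_set", "variable_class", "feature"],
            ascending=[False, True, True, True], kind="mergesort",
        ).reset_index(drop=True)
    return df


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Flatten results to the associations table, deterministically ordered
    by (variable_class, tumor_type, gene_set, feature)."""
    df = pd.DataFrame([vars(r) for r in results])
    if len(df):
        df = df.sort_values(["variable_class", "tumor_type", "gene_set", "feature"],
                            kind="mergesort").reset_index(drop=True)
        df = df[["tumor_type", "gene_set", "collection", "k", "variable_class",
                 "feature", "test", "statistic", "p_value", "valid", "n_used",
                 "m_family", "significant", "reason"]]
    return df
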