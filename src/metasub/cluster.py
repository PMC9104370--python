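"""Metabolic subtype discovery for one tumor type and one gene set.

The procedure, per (tumor type, gene set) pair:

1. Restrict the expression matrix (genes x samples, TPM-like) to the
   gene set and rank-transform each gene across samples.
2. Run a Duda-Hart test on the rank-space points, with the candidate
   2-split taken from PAM (k=2) on the Spearman distance. If the
   one-cluster null is not rejected at ``gate_alpha`` the pair is
   "gated out" and no subtypes are reported.
3. Otherwise partition the samples with PAM on the Spearman distance
   ``d = 1 - rho`` for k = 2..k_max, and keep the k that maximizes the
   average silhouette width (ties toward smaller k).

Partitions from different gene sets are compared with normalized mutual
information (normalized by the geometric mean of the entropies), and
cluster-differential genes are ranked by Kruskal-Wallis p-value.

Everything here is deterministic: all ties (medoid choice, nearest-medoid
assignment, k selection) break toward the lowest sample index / smallest k.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneSet, MIN_USABLE_GENES

logger = logging.getLogger(__name__)

DEFAULT_GATE_ALPHA = 0.001
DEFAULT_K_MAX = 10


# ---------------------------------------------------------------------------
# transforms and distances
# ---------------------------------------------------------------------------

def rank_transform(expr: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Rank each gene (row) across samples; ties get average ranks.

    Returns the ranked matrix and the list of zero-variance genes, whose
    rows come out constant and which should be dropped before computing
    sample-sample correlations.
    """
    values = expr.to_numpy(dtype=float)
    ranked = stats.rankdata(values, axis=1)
    flat = expr.index[np.ptp(values, axis=1) == 0].tolist()
    if flat:
        logger.info("rank_transform: %d zero-variance genes", len(flat))
    return pd.DataFrame(ranked, index=expr.index, columns=expr.columns), flat


def log_transform(expr: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(x + pseudocount); input must be non-negative."""
    values = expr.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("log_transform requires non-negative values")
    return pd.DataFrame(
        np.log2(values + pseudocount), index=expr.index, columns=expr.columns
    )


class UnusablePairError(ValueError):
    """Raised when a gene set leaves <2 usable genes in the matrix."""


def spearman_distance(expr: pd.DataFrame, gene_set: GeneSet | None = None) -> pd.DataFrame:
    """Spearman distance d = 1 - rho between sample expression profiles.

    Profiles are taken over the gene-set genes present in the matrix,
    after dropping genes with zero variance across samples. The result
    is a symmetric samples x samples DataFrame with zero diagonal and
    values in [0, 2].
    """
    sub = expr if gene_set is None else expr.loc[expr.index.intersection(sorted(gene_set.genes))]
    values = sub.to_numpy(dtype=float)
    keep = np.ptp(values, axis=1) > 0
    values = values[keep]
    if values.shape[0] < MIN_USABLE_GENES:
        raise UnusablePairError(
            f"<{MIN_USABLE_GENES} usable genes after zero-variance filtering"
        )
    # rank within each sample profile, then Pearson of the rank vectors
    ranks = stats.rankdata(values, axis=0)
    sd = ranks.std(axis=0)
    if (sd == 0).any():
        bad = sub.columns[np.where(sd == 0)[0][0]]
        raise ValueError(f"sample {bad!r} has zero variance across gene-set genes")
    rho = np.corrcoef(ranks.T)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=sub.columns, columns=sub.columns)


# ---------------------------------------------------------------------------
# Duda-Hart test
# ---------------------------------------------------------------------------

def duda_hart_test(points: np.ndarray, split: np.ndarray) -> tuple[float, float]:
    """Duda-Hart test of the one-cluster null against a given 2-split.

    ``points`` is an (n, p) array; ``split`` a length-n array of two
    labels. The statistic is H = Je(2)/Je(1), the ratio of the
    within-part sum of squared distances to part centroids to the total
    sum of squared distances to the overall centroid. Small H means the
    split explains most of the scatter. The p-value uses the normal
    approximation z = (1 - 2/(pi*p) - H) * sqrt(n*p / (2*(1 - 8/(pi^2*p)))),
    p-value = 1 - Phi(z).
    """
    points = np.asarray(points, dtype=float)
    split = np.asarray(split)
    n, p = points.shape
    if n < 3:
        raise ValueError("Duda-Hart test needs at least 3 points")
    labels = np.unique(split)
    if labels.size != 2:
        raise ValueError("split must have exactly two non-empty parts")
    centroid = points.mean(axis=0)
    je1 = float(((points - centroid) ** 2).sum())
    if je1 == 0.0:
        raise ValueError("degenerate input: all points identical (Je(1)=0)")
    je2 = 0.0
    for lab in labels:
        part = points[split == lab]
        je2 += float(((part - part.mean(axis=0)) ** 2).sum())
    h = je2 / je1
    z = (1.0 - 2.0 / (math.pi * p) - h) * math.sqrt(
        n * p / (2.0 * (1.0 - 8.0 / (math.pi ** 2 * p)))
    )
    return h, float(stats.norm.sf(z))


# ---------------------------------------------------------------------------
# PAM (k-medoids, BUILD + SWAP)
# ---------------------------------------------------------------------------

def pam_cluster(d: np.ndarray | pd.DataFrame, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Partition around medoids on a precomputed distance matrix.

    BUILD greedily selects k medoids minimizing total distance to the
    nearest medoid; SWAP repeatedly applies the best strictly improving
    (medoid, non-medoid) exchange until none exists. All ties break
    toward the lowest sample index, so the result is deterministic.

    Returns ``(medoids, labels)``: medoid sample indices sorted
    ascending, and integer labels 1..k assigned in medoid order.
    """
    dm = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    n = dm.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n, got k={k}, n={n}")

    # BUILD: np.argmin returns the first (lowest-index) minimizer.
    medoids = [int(np.argmin(dm.sum(axis=1)))]
    nearest = dm[:, medoids[0]].copy()
    while len(medoids) < k:
        cand = np.array([i for i in range(n) if i not in medoids])
        # objective after adding each candidate
        obj = np.minimum(nearest[:, None], dm[:, cand]).sum(axis=0)
        medoids.append(int(cand[int(np.argmin(obj))]))
        nearest = np.minimum(nearest, dm[:, medoids[-1]])

    medoids = sorted(medoids)
    obj = _pam_objective(dm, medoids)
    while True:
        best = _best_swap(dm, medoids)
        if best is None or best[0] >= obj - 1e-12:
            break
        obj = best[0]
        medoids = best[1]

    med = np.array(sorted(medoids))
    labels = np.argmin(dm[:, med], axis=1) + 1  # ties -> lowest medoid index
    return med, labels


def _pam_objective(dm: np.ndarray, medoids: list[int]) -> float:
    return float(dm[:, medoids].min(axis=1).sum())


def _best_swap(dm: np.ndarray, medoids: list[int]) -> tuple[float, list[int]] | None:
    """Best (lowest objective) single medoid exchange; ties toward the
    lowest medoid sample index, then the lowest candidate index."""
    n = dm.shape[0]
    med = np.array(medoids)
    dmed = dm[:, med]
    order = np.argsort(dmed, axis=1)
    nearest_val = dmed[np.arange(n), order[:, 0]]
    second_val = dmed[np.arange(n), order[:, 1]]
    nearest_j = order[:, 0]
    cand = np.array([i for i in range(n) if i not in medoids])

    best: tuple[float, list[int]] | None = None
    for j in range(len(medoids)):  # medoids sorted -> lowest index first
        base = np.where(nearest_j == j, second_val, nearest_val)
        costs = np.minimum(base[:, None], dm[:, cand]).sum(axis=0)
        i = int(np.argmin(costs))  # first minimizer -> lowest candidate
        if best is None or costs[i] < best[0] - 1e-15:
            new = sorted(m for jj, m in enumerate(medoids) if jj != j)
            new = sorted(new + [int(cand[i])])
            best = (float(costs[i]), new)
    return best


def pam_objective(d: np.ndarray | pd.DataFrame, medoids) -> float:
    """Total distance of every point to its nearest medoid."""
    dm = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    return _pam_objective(dm, list(medoids))


# ---------------------------------------------------------------------------
# silhouette and model selection
# ---------------------------------------------------------------------------

def silhouette_width(d: np.ndarray | pd.DataFrame, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-sample silhouettes s(i) = (b - a)/max(a, b) and their mean.

    a(i) is the mean distance to the sample's own cluster (excluding
    itself), b(i) the smallest mean distance to another cluster.
    Singleton clusters get s(i) = 0, as does the degenerate a = b = 0
    case (identical points).
    """
    dm = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    n = dm.shape[0]
    s = np.zeros(n)
    sums = np.stack([dm[:, labels == c].sum(axis=1) for c in uniq], axis=1)
    sizes = np.array([(labels == c).sum() for c in uniq])
    for i in range(n):
        ci = int(np.where(uniq == labels[i])[0][0])
        if sizes[ci] == 1:
            continue  # singleton convention: s = 0
        a = sums[i, ci] / (sizes[ci] - 1)
        other = [sums[i, c] / sizes[c] for c in range(uniq.size) if c != ci]
        b = min(other)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


def select_k(
    d: np.ndarray | pd.DataFrame, k_max: int = DEFAULT_K_MAX
) -> tuple[int, np.ndarray, np.ndarray, float]:
    """Choose k in 2..k_max by maximal average silhouette width.

    k_max is clamped to n-1. Ties break toward the smaller k. Returns
    (k, medoids, labels, average silhouette width).
    """
    dm = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    n = dm.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to choose k")
    best = None
    for k in range(2, min(k_max, n - 1) + 1):
        med, labels = pam_cluster(dm, k)
        _, asw = silhouette_width(dm, labels)
        if best is None or asw > best[3]:
            best = (k, med, labels, asw)
    return best


# ---------------------------------------------------------------------------
# the full per-pair procedure
# ---------------------------------------------------------------------------

@dataclass
class ClusterSolution:
    """Outcome of subtyping one (tumor type, gene set) pair.

    ``status`` is "clustered" when the Duda-Hart gate passed and a
    partition was produced, "gated_out" when the one-cluster null was
    not rejected, and "unusable" when the gene set had too few usable
    genes in the matrix.
    """

    tumor_type: str
    gene_set: str
    status: str
    duda_hart_p: float = float("nan")
    passed_gate: bool = False
    k: int = 0
    avg_silhouette: float = float("nan")
    assignments: pd.Series | None = None
    medoids: list[str] = field(default_factory=list)
    n_genes_used: int = 0
    reason: str = ""

    @property
    def clustered(self) -> bool:
        return self.status == "clustered"


def cluster_gene_set(
    expr: pd.DataFrame,
    gene_set: GeneSet,
    tumor_type: str = "COHORT",
    gate_alpha: float = DEFAULT_GATE_ALPHA,
    k_max: int = DEFAULT_K_MAX,
    gate_space: str = "rank",
) -> ClusterSolution:
    """Gate, then subtype, one (tumor type, gene set) pair.

    ``gate_space`` selects the coordinates for the Duda-Hart test:
    per-gene ranks (default, the more conservative choice) or log2(x+1)
    expression.
    """
    genes = expr.index.intersection(sorted(gene_set.genes))
    sub = expr.loc[genes]
    # drop zero-variance genes before anything else
    sub = sub.loc[np.ptp(sub.to_numpy(dtype=float), axis=1) > 0]
    if sub.shape[0] < MIN_USABLE_GENES:
        return ClusterSolution(
            tumor_type=tumor_type, gene_set=gene_set.name, status="unusable",
            reason=f"<{MIN_USABLE_GENES} usable genes in matrix",
        )
    d = spearman_distance(sub)
    _, split = pam_cluster(d, 2)
    if gate_space == "rank":
        points_df, _ = rank_transform(sub)
    elif gate_space == "log":
        points_df = log_transform(sub)
    else:
        raise ValueError(f"unknown gate_space {gate_space!r}")
    points = points_df.to_numpy(dtype=float).T  # samples as points
    _, p_value = duda_hart_test(points, split)
    if not p_value < gate_alpha:
        return ClusterSolution(
            tumor_type=tumor_type, gene_set=gene_set.name, status="gated_out",
            duda_hart_p=p_value, passed_gate=False,
            n_genes_used=sub.shape[0], reason="no cluster separation",
        )
    k, med, labels, asw = select_k(d, k_max=k_max)
    return ClusterSolution(
        tumor_type=tumor_type, gene_set=gene_set.name, status="clustered",
        duda_hart_p=p_value, passed_gate=True, k=k, avg_silhouette=asw,
        assignments=pd.Series(labels, index=d.index, name="cluster"),
        medoids=[str(d.index[m]) for m in med], n_genes_used=sub.shape[0],
    )


# ---------------------------------------------------------------------------
# partition comparison and differential genes
# ---------------------------------------------------------------------------

def nmi(a, b) -> float:
    """Normalized mutual information between two partitions.

    I(A;B) / sqrt(H(A) * H(B)) from the empirical joint distribution;
    0 when either partition has a single cluster (zero entropy), 1 for
    identical partitions with >=2 clusters. Label values are arbitrary.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same samples")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    ha = -np.sum(pa * np.log(pa, where=pa > 0, out=np.zeros_like(pa)))
    hb = -np.sum(pb * np.log(pb, where=pb > 0, out=np.zeros_like(pb)))
    if ha == 0.0 or hb == 0.0:
        return 0.0
    outer = pa[:, None] * pb[None, :]
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))
    return max(0.0, min(1.0, mi / math.sqrt(ha * hb)))


def nmi_matrix(solutions: list[ClusterSolution]) -> pd.DataFrame:
    """Pairwise NMI between the partitions of clustered gene sets."""
    done = [s for s in solutions if s.clustered]
    names = [s.gene_set for s in done]
    out = pd.DataFrame(np.eye(len(done)), index=names, columns=names)
    for i in range(len(done)):
        for j in range(i + 1, len(done)):
            a = done[i].assignments
            b = done[j].assignments.reindex(a.index)
            v = nmi(a.to_numpy(), b.to_numpy())
            out.iat[i, j] = out.iat[j, i] = v
    return out


def differential_genes(
    expr: pd.DataFrame, assignments: pd.Series, top_n: int = 20
) -> pd.DataFrame:
    """Rank genes by Kruskal-Wallis p-value across clusters.

    Genes with identical values in every sample are untestable and get
    p = 1. Returns the ``top_n`` genes sorted by (p-value, gene name).
    """
    groups = assignments.to_numpy()
    if np.unique(groups).size < 2:
        raise ValueError("need at least 2 clusters")
    values = expr[assignments.index].to_numpy(dtype=float)
    pvals = np.ones(values.shape[0])
    for i, row in enumerate(values):
        if np.ptp(row) == 0:
            logger.debug("gene %s constant; p set to 1", expr.index[i])
            continue
        pvals[i] = stats.kruskal(*(row[groups == g] for g in np.unique(groups))).pvalue
    out = pd.DataFrame({"gene": expr.index, "p_value": pvals})
    out = out.sort_values(["p_value", "gene"], kind="mergesort").reset_index(drop=True)
    return out.head(top_n)
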