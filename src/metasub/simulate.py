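"""Synthetic multi-omic cohorts with planted ground truth.

The generator emulates the statistical structure the pipeline is built
to detect: TPM-like log-normal expression with subtype structure
planted inside chosen gene sets (each subtype marked by both up- and
down-regulated genes), zero-inflated miRNA expression, non-synonymous
mutation calls with subtype-dependent enrichment, SEG-format copy
number with subtype-amplified regions, exponential survival with
subtype-dependent hazards, and categorical histology labels. Every
output is a deterministic function of (spec, seed), and a truth sidecar
records the planted assignments and effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .genesets import GeneSet, GeneSetCollection, write_gmt
from .features import NONSYNONYMOUS_CLASSES

# log2-scale expression model: gene baselines ~ N(BASE_MEAN, BASE_SD),
# within-gene noise sd NOISE_SD. "Strong" separation (3.0 on log2 scale,
# i.e. 3 noise SDs between subtype means) plants structure that PAM
# recovers essentially perfectly, the regime the study's k=2 subtypes
# represent; separation 0 is the calibration null.
BASE_MEAN = 3.0
BASE_SD = 1.0
NOISE_SD = 1.0
STRONG_SEPARATION = 3.0


@dataclass
class PlantedSubtype:
    gene_set: str
    true_k: int = 2
    separation: float = STRONG_SEPARATION
    fraction_up: float = 0.5


@dataclass
class MutationEffect:
    gene: str
    gene_set: str
    probs: tuple[float, ...]  # mutation probability per true cluster
    hotspot: str = "p.R175H"  # shared protein change -> testable point mutation


@dataclass
class SurvivalEffect:
    gene_set: str
    hazard_ratios: tuple[float, ...]  # per true cluster, relative to baseline
    censoring_rate: float = 0.3
    endpoint: str = "os"  # "os" or "rfs"
    baseline_hazard: float = 1.0 / 365.0


@dataclass
class CategoricalEffect:
    name: str
    gene_set: str
    level_probs: tuple[tuple[float, ...], ...]  # per cluster, over levels
    levels: tuple[str, ...] = ()


@dataclass
class MirnaEffect:
    name: str
    gene_set: str
    shifts: tuple[float, ...]  # log2-scale mean shift per cluster
    zero_inflation: float = 0.3


@dataclass
class CnRegionEffect:
    region: str  # e.g. "reg_1_1"
    gene_set: str
    deltas: tuple[float, ...]  # seg.mean shift per cluster


@dataclass
class MethylationEffect:
    gene_set: str
    shifts: tuple[float, ...]  # per-cluster shift of the global scale factor


@dataclass
class RppaEffect:
    name: str
    gene_set: str
    shifts: tuple[float, ...]
    sd: float = 1.0


@dataclass
class NullFeatureCounts:
    mirna: int = 20
    mutation_genes: int = 10
    rppa: int = 5
    categorical: int = 1
    methylation_genes: int = 50


@dataclass
class SyntheticCohortSpec:
    n_samples: int = 120
    gene_sets: GeneSetCollection = field(default_factory=GeneSetCollection)
    background_genes: int = 100
    planted: list[PlantedSubtype] = field(default_factory=list)
    features: list = field(default_factory=list)
    nulls: NullFeatureCounts = field(default_factory=NullFeatureCounts)
    null_mutation_rate: float = 0.08
    mirna_zero_inflation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.planted:
            if p.true_k < 1:
                raise ValueError("true_k must be >= 1")
            if not 0 <= p.fraction_up <= 1:
                raise ValueError("fraction_up must be in [0,1]")
            if p.separation < 0:
                raise ValueError("separation must be >= 0")
        for f in self.features:
            if isinstance(f, SurvivalEffect) and min(f.hazard_ratios) <= 0:
                raise ValueError("hazard ratios must be positive")


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame
    mirna: pd.DataFrame
    methylation: pd.DataFrame
    rppa: pd.DataFrame
    seg: pd.DataFrame
    calls: pd.DataFrame
    clinical: pd.DataFrame
    gene_coords: pd.DataFrame
    regions: dict[str, list[str]]
    gene_sets: GeneSetCollection
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        msio.write_matrix(self.expression, outdir / "expression.tsv")
        msio.write_matrix(self.mirna, outdir / "mirna.tsv", index_name="mirna")
        msio.write_matrix(self.methylation, outdir / "methylation.tsv")
        msio.write_matrix(self.rppa, outdir / "rppa.tsv", index_name="protein")
        msio.write_seg(self.seg, outdir / "cn.seg")
        msio.write_maf(self.calls, outdir / "mutations.maf.tsv")
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t")
        msio.write_bed(self.gene_coords, outdir / "genes.bed")
        region_sets = GeneSetCollection(sets=[
            GeneSet(name=n, genes=frozenset(g)) for n, g in self.regions.items()
        ])
        write_gmt(region_sets, outdir / "regions.gmt")
        write_gmt(self.gene_sets, outdir / "genesets.gmt")
        with (outdir / "truth.json").open("w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# component generators (each consumes its own child rng stream)
# ---------------------------------------------------------------------------

def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(1, n + 1)]


def _truth_assignments(spec: SyntheticCohortSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Balanced, shuffled cluster labels (1..k) per planted gene set."""
    truth = {}
    for p in spec.planted:
        base = np.tile(np.arange(1, p.true_k + 1),
                       spec.n_samples // p.true_k + 1)[: spec.n_samples]
        truth[p.gene_set] = rng.permutation(base)
    return truth


def _cluster_of(truth: dict[str, np.ndarray], gene_set: str, n: int) -> np.ndarray:
    """Planted labels for a conditioning gene set; all-ones when none."""
    if gene_set in truth:
        return truth[gene_set]
    return np.ones(n, dtype=int)


def generate_expression(
    spec: SyntheticCohortSpec, truth: dict[str, np.ndarray], rng: np.random.Generator
) -> pd.DataFrame:
    """TPM-like expression with planted subtype blocks.

    A planted gene set splits its genes into "up" (fraction_up) and
    "down" directions; each gene is driven by one cluster, in which its
    log2 mean moves by +/- separation (balanced so the set's centroids
    differ between all clusters). Background genes are i.i.d.
    """
    samples = _sample_ids(spec.n_samples)
    planted_by_set = {p.gene_set: p for p in spec.planted}
    set_genes: list[str] = []
    seen: set[str] = set()
    for s in spec.gene_sets:
        for g in sorted(s.genes):
            if g not in seen:
                set_genes.append(g)
                seen.add(g)
    genes = set_genes + [f"BG{i:04d}" for i in range(1, spec.background_genes + 1)]
    mu = rng.normal(BASE_MEAN, BASE_SD, size=len(genes))
    log2x = mu[:, None] + rng.normal(0.0, NOISE_SD, size=(len(genes), spec.n_samples))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for p in planted_by_set.values():
        if p.gene_set not in spec.gene_sets.names:
            raise ValueError(f"planted gene set {p.gene_set!r} not in spec universe")
        labels = truth[p.gene_set]
        members = sorted(spec.gene_sets[p.gene_set].genes)
        n_up = int(round(p.fraction_up * len(members)))
        for j, g in enumerate(members):
            direction = 1.0 if j < n_up else -1.0
            driver = j % p.true_k + 1
            shift = np.where(labels == driver, 1.0,
                             -1.0 / max(p.true_k - 1, 1))
            log2x[gene_pos[g]] += direction * p.separation * shift
    return pd.DataFrame(2.0 ** log2x, index=genes, columns=samples)


def generate_mutations(
    spec: SyntheticCohortSpec, truth: dict[str, np.ndarray], rng: np.random.Generator
) -> pd.DataFrame:
    """MAF-like calls: planted genes mutated with cluster-specific
    probability (one hotspot non-synonymous call each), null genes at a
    cluster-independent rate with random protein changes."""
    samples = _sample_ids(spec.n_samples)
    classes = sorted(NONSYNONYMOUS_CLASSES)
    rows = []
    for eff in [f for f in spec.features if isinstance(f, MutationEffect)]:
        labels = _cluster_of(truth, eff.gene_set, spec.n_samples)
        probs = np.array([eff.probs[c - 1] for c in labels])
        mutated = rng.random(spec.n_samples) < probs
        for si in np.nonzero(mutated)[0]:
            rows.append((eff.gene, samples[si],
                         classes[rng.integers(len(classes))], eff.hotspot))
    for i in range(1, spec.nulls.mutation_genes + 1):
        gene = f"NMUT{i:03d}"
        mutated = rng.random(spec.n_samples) < spec.null_mutation_rate
        for si in np.nonzero(mutated)[0]:
            pos = int(rng.integers(1, 500))
            rows.append((gene, samples[si],
                         classes[rng.integers(len(classes))], f"p.A{pos}V"))
    return pd.DataFrame(rows, columns=msio.MAF_COLUMNS)


def generate_survival(
    spec: SyntheticCohortSpec, truth: dict[str, np.ndarray], rng: np.random.Generator
) -> dict[str, pd.DataFrame]:
    """Exponential event times with cluster-specific hazards and
    independent exponential censoring tuned to the requested rate."""
    out: dict[str, pd.DataFrame] = {}
    for eff in [f for f in spec.features if isinstance(f, SurvivalEffect)]:
        labels = _cluster_of(truth, eff.gene_set, spec.n_samples)
        hr = np.array([eff.hazard_ratios[c - 1] for c in labels])
        hazard = eff.baseline_hazard * hr
        t_event = rng.exponential(1.0 / hazard)
        if eff.censoring_rate >= 1.0:
            time, event = t_event, np.zeros(spec.n_samples, dtype=int)
        elif eff.censoring_rate <= 0.0:
            time, event = t_event, np.ones(spec.n_samples, dtype=int)
        else:
            # for competing exponentials P(censor first) = lc/(lc+le)
            mean_hazard = eff.baseline_hazard * float(np.mean(eff.hazard_ratios))
            lc = mean_hazard * eff.censoring_rate / (1.0 - eff.censoring_rate)
            t_cens = rng.exponential(1.0 / lc, size=spec.n_samples)
            event = (t_event <= t_cens).astype(int)
            time = np.minimum(t_event, t_cens)
        out[eff.endpoint] = pd.DataFrame(
            {"time": np.maximum(time, 0.01), "event": event},
            index=_sample_ids(spec.n_samples))
    return out


TOY_CHROMS = ("1", "2")
TOY_CHROM_LEN = 10_000_000
TOY_GENES_PER_CHROM = 50
TOY_GENE_SPACING = 200_000
TOY_GENE_LEN = 100_000
TOY_GENES_PER_REGION = 10


def toy_genome() -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """A small synthetic genome: 2 chromosomes, 100 genes on a regular
    grid, grouped into positional regions of 10 consecutive genes."""
    rows = []
    regions: dict[str, list[str]] = {}
    for ci, chrom in enumerate(TOY_CHROMS):
        for i in range(TOY_GENES_PER_CHROM):
            gene = f"CNG{ci * TOY_GENES_PER_CHROM + i + 1:03d}"
            start = i * TOY_GENE_SPACING + 50_001
            rows.append((gene, chrom, start, start + TOY_GENE_LEN - 1))
            region = f"reg_{chrom}_{i // TOY_GENES_PER_REGION + 1}"
            regions.setdefault(region, []).append(gene)
    coords = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    return coords, regions


def generate_cn_segments(
    spec: SyntheticCohortSpec, truth: dict[str, np.ndarray], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """SEG records on the toy genome: per sample, one baseline segment
    per region span (seg.mean ~ N(0, 0.05)), planted regions shifted by
    the cluster's delta; equal-valued neighbors merged."""
    coords, regions = toy_genome()
    samples = _sample_ids(spec.n_samples)
    effects = [f for f in spec.features if isinstance(f, CnRegionEffect)]
    region_delta = np.zeros((len(regions), spec.n_samples))
    region_names = list(regions)
    for eff in effects:
        if eff.region not in regions:
            raise ValueError(f"unknown region {eff.region!r}")
        labels = _cluster_of(truth, eff.gene_set, spec.n_samples)
        ri = region_names.index(eff.region)
        region_delta[ri] = np.array([eff.deltas[c - 1] for c in labels])
    # region genomic spans, per chromosome in order
    span: dict[str, tuple[str, int, int]] = {}
    for name, genes in regions.items():
        sub = coords[coords["gene"].isin(genes)]
        span[name] = (sub["chrom"].iloc[0], int(sub["start"].min()), int(sub["end"].max()))
    rows = []
    base = rng.normal(0.0, 0.05, size=(spec.n_samples, len(region_names)))
    for si, sample in enumerate(samples):
        for chrom in TOY_CHROMS:
            segs = []
            for ri, name in enumerate(region_names):
                c, s, e = span[name]
                if c != chrom:
                    continue
                segs.append([s, e, base[si, ri] + region_delta[ri, si]])
            segs.sort()
            merged = [segs[0]]
            for s, e, v in segs[1:]:
                if v == merged[-1][2] and s == merged[-1][1] + 1:
                    merged[-1][1] = e
                else:
                    merged.append([s, e, v])
            for s, e, v in merged:
                rows.append((sample, chrom, s, e, (e - s + 1) // 10_000, v))
    seg = pd.DataFrame(rows, columns=msio.SEG_COLUMNS)
    return seg, coords, regions


def generate_mirna_methylation(
    spec: SyntheticCohortSpec, truth: dict[str, np.ndarray], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Zero-inflated log-normal miRNA and Beta-distributed methylation.

    Planted miRNAs shift their log2 mean per cluster; the planted
    methylation effect scales each sample's gene values by a
    cluster-shifted global factor.
    """
    n = spec.n_samples
    samples = _sample_ids(n)
    rows = {}
    for eff in [f for f in spec.features if isinstance(f, MirnaEffect)]:
        labels = _cluster_of(truth, eff.gene_set, n)
        shift = np.array([eff.shifts[c - 1] for c in labels])
        vals = 2.0 ** rng.normal(5.0 + shift, 1.0)
        vals[rng.random(n) < eff.zero_inflation] = 0.0
        rows[eff.name] = vals
    for i in range(1, spec.nulls.mirna + 1):
        vals = 2.0 ** rng.normal(5.0, 1.0, size=n)
        vals[rng.random(n) < spec.mirna_zero_inflation] = 0.0
        rows[f"null-mir-{i:03d}"] = vals
    mirna = pd.DataFrame(rows, index=samples).T

    n_genes = spec.nulls.methylation_genes
    beta = rng.beta(2.0, 5.0, size=(n_genes, n))
    factor = np.ones(n)
    for eff in [f for f in spec.features if isinstance(f, MethylationEffect)]:
        labels = _cluster_of(truth, eff.gene_set, n)
        factor = factor + np.array([eff.shifts[c - 1] for c in labels])
    meth = np.clip(beta * factor[None, :], 0.0, 1.0)
    methylation = pd.DataFrame(
        meth, index=[f"MG{i:03d}" for i in range(1, n_genes + 1)], columns=samples)
    return mirna, methylation


def generate_rppa(
    spec: SyntheticCohortSpec, truth: dict[str, np.ndarray], rng: np.random.Generator
) -> pd.DataFrame:
    n = spec.n_samples
    rows = {}
    for eff in [f for f in spec.features if isinstance(f, RppaEffect)]:
        labels = _cluster_of(truth, eff.gene_set, n)
        shift = np.array([eff.shifts[c - 1] for c in labels])
        rows[eff.name] = rng.normal(shift, eff.sd)
    for i in range(1, spec.nulls.rppa + 1):
        rows[f"NPROT{i:03d}"] = rng.normal(0.0, 1.0, size=n)
    return pd.DataFrame(rows, index=_sample_ids(n)).T


def generate_clinical(
    spec: SyntheticCohortSpec, truth: dict[str, np.ndarray],
    survival: dict[str, pd.DataFrame], rng: np.random.Generator,
) -> pd.DataFrame:
    n = spec.n_samples
    table = pd.DataFrame(index=pd.Index(_sample_ids(n), name="sample"))
    table["age"] = np.round(rng.normal(60.0, 10.0, size=n), 1)
    for eff in [f for f in spec.features if isinstance(f, CategoricalEffect)]:
        labels = _cluster_of(truth, eff.gene_set, n)
        levels = eff.levels or tuple(
            f"{eff.name}_{chr(97 + i)}" for i in range(len(eff.level_probs[0])))
        vals = [levels[rng.choice(len(levels), p=eff.level_probs[c - 1])]
                for c in labels]
        table[eff.name] = vals
    for i in range(1, spec.nulls.categorical + 1):
        table[f"nullcat{i}"] = rng.choice(["x", "y", "z"], size=n)
    for endpoint, df in survival.items():
        table[f"{endpoint}_time"] = np.round(df["time"].to_numpy(), 2)
        table[f"{endpoint}_event"] = df["event"].to_numpy()
    return table


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Run every component generator off one seed and bundle the cohort.

    Each component draws from its own child stream of the spec seed, so
    adding a feature to one data type does not perturb the others.
    """
    n_streams = 8
    streams = [np.random.default_rng([spec.seed, i]) for i in range(n_streams)]
    truth_assign = _truth_assignments(spec, streams[0])
    expression = generate_expression(spec, truth_assign, streams[1])
    calls = generate_mutations(spec, truth_assign, streams[2])
    survival = generate_survival(spec, truth_assign, streams[3])
    seg, coords, regions = generate_cn_segments(spec, truth_assign, streams[4])
    mirna, methylation = generate_mirna_methylation(spec, truth_assign, streams[5])
    rppa = generate_rppa(spec, truth_assign, streams[6])
    clinical = generate_clinical(spec, truth_assign, survival, streams[7])
    truth = {
        "seed": spec.seed,
        "n_samples": spec.n_samples,
        "assignments": {k: v.tolist() for k, v in truth_assign.items()},
        "samples": _sample_ids(spec.n_samples),
        "planted": [asdict(p) for p in spec.planted],
        "effects": [
            {"type": type(f).__name__, **asdict(f)} for f in spec.features
        ],
    }
    return SyntheticCohort(
        expression=expression, mirna=mirna, methylation=methylation, rppa=rppa,
        seg=seg, calls=calls, clinical=clinical, gene_coords=coords,
        regions=regions, gene_sets=spec.gene_sets, truth=truth,
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _demo_gene_sets() -> GeneSetCollection:
    set_a = GeneSet(name="PATHWAY_A_METABOLISM",
                    genes=frozenset(f"GA{i:03d}" for i in range(1, 31)),
                    collection="demo")
    set_b = GeneSet(name="PATHWAY_B_METABOLISM",
                    genes=frozenset(f"GB{i:03d}" for i in range(1, 31)),
                    collection="demo")
    return GeneSetCollection(sets=[set_a, set_b])


def demo_spec(seed: int = 0, n_samples: int = 120) -> SyntheticCohortSpec:
    """Small cohort with one planted two-subtype gene set (PATHWAY_A),
    one null gene set (PATHWAY_B), and one planted effect per variable
    class, all conditioned on the PATHWAY_A subtypes."""
    gs = "PATHWAY_A_METABOLISM"
    return SyntheticCohortSpec(
        n_samples=n_samples,
        gene_sets=_demo_gene_sets(),
        planted=[PlantedSubtype(gene_set=gs, true_k=2,
                                separation=STRONG_SEPARATION)],
        features=[
            MutationEffect(gene="MUTA", gene_set=gs, probs=(0.35, 0.04)),
            SurvivalEffect(gene_set=gs, hazard_ratios=(1.0, 3.0),
                           censoring_rate=0.3, endpoint="os"),
            SurvivalEffect(gene_set=gs, hazard_ratios=(1.0, 1.0),
                           censoring_rate=0.3, endpoint="rfs"),
            CategoricalEffect(name="histology", gene_set=gs,
                              level_probs=((0.7, 0.2, 0.1), (0.15, 0.25, 0.6))),
            MirnaEffect(name="mir-900", gene_set=gs, shifts=(0.0, 2.0)),
            CnRegionEffect(region="reg_1_1", gene_set=gs, deltas=(1.0, 0.0)),
            MethylationEffect(gene_set=gs, shifts=(0.0, 0.4)),
            RppaEffect(name="PROTA", gene_set=gs, shifts=(0.0, 1.5)),
        ],
        seed=seed,
    )


def null_spec(seed: int = 0, n_samples: int = 50) -> SyntheticCohortSpec:
    """Global null: no planted structure and no planted effects, but all
    data types present (null features only)."""
    return SyntheticCohortSpec(
        n_samples=n_samples,
        gene_sets=_demo_gene_sets(),
        planted=[],
        features=[
            SurvivalEffect(gene_set="PATHWAY_A_METABOLISM",
                           hazard_ratios=(1.0,), censoring_rate=0.3,
                           endpoint="os"),
        ],
        nulls=NullFeatureCounts(mirna=10, mutation_genes=5, rppa=3,
                                categorical=1, methylation_genes=20),
        seed=seed,
    )


def strong_spec(seed: int = 0, true_k: int = 2, n_samples: int = 90) -> SyntheticCohortSpec:
    """Planted k in {2,3} at strong separation; used for k-recovery."""
    return SyntheticCohortSpec(
        n_samples=n_samples,
        gene_sets=_demo_gene_sets(),
        planted=[PlantedSubtype(gene_set="PATHWAY_A_METABOLISM",
                                true_k=true_k, separation=STRONG_SEPARATION)],
        nulls=NullFeatureCounts(mirna=2, mutation_genes=2, rppa=2,
                                categorical=1, methylation_genes=10),
        seed=seed,
    )


def mutation_power_spec(seed: int = 0) -> SyntheticCohortSpec:
    """Two subtypes at n=200 with a planted mutation at prevalence
    0.25 vs 0.04 (odds ratio ~8) plus null mutation genes."""
    gs = "PATHWAY_A_METABOLISM"
    return SyntheticCohortSpec(
        n_samples=200,
        gene_sets=_demo_gene_sets(),
        planted=[PlantedSubtype(gene_set=gs, true_k=2,
                                separation=STRONG_SEPARATION)],
        features=[MutationEffect(gene="MUTA", gene_set=gs, probs=(0.25, 0.04))],
        nulls=NullFeatureCounts(mirna=2, mutation_genes=10, rppa=2,
                                categorical=1, methylation_genes=10),
        seed=seed,
    )


def survival_power_spec(seed: int = 0) -> SyntheticCohortSpec:
    """Two subtypes of 150 samples each, hazard ratio 3, ~30% censoring."""
    gs = "PATHWAY_A_METABOLISM"
    return SyntheticCohortSpec(
        n_samples=300,
        gene_sets=_demo_gene_sets(),
        planted=[PlantedSubtype(gene_set=gs, true_k=2,
                                separation=STRONG_SEPARATION)],
        features=[SurvivalEffect(gene_set=gs, hazard_ratios=(1.0, 3.0),
                                 censoring_rate=0.3, endpoint="os")],
        nulls=NullFeatureCounts(mirna=2, mutation_genes=2, rppa=2,
                                categorical=1, methylation_genes=10),
        seed=seed,
    )


PRESETS = {
    "demo": demo_spec,
    "null": null_spec,
    "strong": strong_spec,
}
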