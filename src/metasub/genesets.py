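"""Gene-set collections and the metabolic-name filter.

Gene sets are read from GMT files (one set per line: name, description,
then gene symbols, tab-separated). Metabolic gene sets are selected by a
name rule: the set name must contain the substring ``metabol`` and must
not contain ``regul``, so that sets describing metabolic pathways are
kept while sets describing the *regulation* of metabolism are dropped.
Matching is case-insensitive; gene symbols are uppercased on parse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

#: Minimum number of gene-set genes present in an expression matrix for
#: the (tumor, gene set) pair to be clusterable: a single gene cannot
#: define a correlation distance between samples.
MIN_USABLE_GENES = 2


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols from one collection."""

    name: str
    genes: frozenset[str]
    collection: str = "user"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set needs a non-empty name")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    sets: list[GeneSet] = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


class GMTParseError(ValueError):
    pass


def parse_gmt(path: str | Path, collection: str = "user") -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each non-empty line must have at least three tab-separated fields:
    name, description (discarded), and one or more gene symbols. Symbols
    are uppercased and deduplicated within a line; file order is kept.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in seen:
                raise GMTParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            genes = frozenset(g.upper() for g in fields[2:] if g)
            sets.append(GeneSet(name=name, genes=genes, collection=collection))
    return GeneSetCollection(sets=sets, source_path=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection back to GMT (description column left blank).

    Genes are written in sorted order so output is deterministic and the
    parse -> write -> parse round trip is identity.
    """
    with Path(path).open("w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, "", *sorted(s.genes)]) + "\n")


def filter_metabolic(
    collection: GeneSetCollection,
    include: str = "metabol",
    exclude: str = "regul",
) -> GeneSetCollection:
    """Keep sets whose name matches ``include`` but not ``exclude``.

    Both substring matches are case-insensitive. With the defaults this
    selects gene sets of metabolic pathways while excluding sets about
    the regulation of metabolism. Idempotent; preserves order.
    """
    inc, exc = include.lower(), exclude.lower()
    kept = [
        s
        for s in collection
        if inc in s.name.lower() and exc not in s.name.lower()
    ]
    return GeneSetCollection(sets=kept, source_path=collection.source_path)


def restrict_to_matrix(gene_set: GeneSet, gene_ids: Iterable[str]) -> tuple[GeneSet, float]:
    """Intersect a gene set with the genes available in a matrix.

    Returns the restricted set and its coverage fraction (matched genes /
    set size). An intersection of fewer than :data:`MIN_USABLE_GENES`
    genes makes the pair unusable for clustering (see :func:`is_usable`).
    """
    ids = list(gene_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("matrix gene ids must be unique")
    present = gene_set.genes & {g.upper() for g in ids}
    coverage = len(present) / len(gene_set.genes) if gene_set.genes else 0.0
    restricted = GeneSet(
        name=gene_set.name, genes=frozenset(present), collection=gene_set.collection
    )
    logger.info(
        "gene set %s: %d/%d genes in matrix (coverage %.2f)",
        gene_set.name, len(present), len(gene_set.genes), coverage,
    )
    if len(present) < MIN_USABLE_GENES:
        logger.warning("gene set %s unusable: <%d genes in matrix",
                       gene_set.name, MIN_USABLE_GENES)
    return restricted, coverage


def is_usable(gene_set: GeneSet) -> bool:
    """True if the set has enough genes to define a sample-sample distance."""
    return len(gene_set.genes) >= MIN_USABLE_GENES
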