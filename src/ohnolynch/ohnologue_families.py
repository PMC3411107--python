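"""Assemble 2R-ohnologue families from gene-pair lists.

A 2R-ohnologue family is the set of vertebrate genes retained from the two
rounds of whole-genome duplication at the origin of the vertebrates; absent
later duplications a family has 2–4 members. Families are built as connected
components of the pair graph. Components of five or more genes are retained
but flagged *unresolved*: they cannot stem from the 2R events alone and are
kept as a temporary measure until they can be sorted into proper subsets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .tabular_io import DataError, IdMap, map_genes_to_proteins

SIZE_CLASSES = ("2", "3", "4", "5plus")


@dataclass(frozen=True)
class OhnologPair:
    gene_a: str
    gene_b: str
    source: str = "curated"

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise DataError(f"self-pair {self.gene_a!r}")


def size_class_of(size: int) -> str:
    if size < 2:
        raise ValueError("families have size ≥ 2")
    return str(size) if size <= 4 else "5plus"


@dataclass(frozen=True)
class Family:
    """One ohnologue family; ``unresolved`` marks families of five or more."""

    family_id: str
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def size_class(self) -> str:
        return size_class_of(self.size)

    @property
    def unresolved(self) -> bool:
        return self.size >= 5


@dataclass
class FamilySet:
    """A partition of a gene universe into families plus a singleton remainder."""

    families: list[Family]
    singletons: set[str]
    universe: set[str]
    _gene_to_family: dict[str, Family] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._gene_to_family:
            for fam in self.families:
                for g in fam.members:
                    if g in self._gene_to_family:
                        raise DataError(f"gene {g!r} in two families")
                    self._gene_to_family[g] = fam
        covered = set(self._gene_to_family) | self.singletons
        if covered != self.universe:
            raise DataError("families ∪ singletons does not equal the universe")

    def family_of(self, gene: str) -> Family | None:
        return self._gene_to_family.get(gene)

    @property
    def family_genes(self) -> set[str]:
        return set(self._gene_to_family)

    def __len__(self) -> int:
        return len(self.families)


@dataclass(frozen=True)
class VennCounts:
    overlap: int
    unique_a: int
    unique_b: int


def build_families(
    pairs: Sequence[OhnologPair], universe: Iterable[str]
) -> FamilySet:
    """Cluster ohnologue pairs into families (connected components of the pair graph).

    family_id is the lexicographically smallest member gene — deterministic and
    diff-friendly. Genes of the universe that occur in no pair are singletons.
    Pair genes outside the universe are a hard error.
    """
    universe = set(universe)
    offenders = sorted(
        {g for p in pairs for g in (p.gene_a, p.gene_b) if g not in universe}
    )
    if offenders:
        raise DataError(f"pair genes outside universe: {offenders[:10]}")

    graph: nx.Graph = nx.Graph()
    for p in pairs:
        graph.add_edge(p.gene_a, p.gene_b)
    families = [
        Family(family_id=min(comp), members=frozenset(comp))
        for comp in nx.connected_components(graph)
    ]
    families.sort(key=lambda f: f.family_id)
    singletons = universe - set(graph.nodes)
    return FamilySet(families=families, singletons=singletons, universe=universe)


@dataclass(frozen=True)
class SizeDistribution:
    """Family counts and member (gene) totals per size class, plus singletons."""

    n_families: dict[str, int]
    n_members: dict[str, int]
    n_singletons: int

    @property
    def total_families(self) -> int:
        return sum(self.n_families.values())

    @property
    def total_members(self) -> int:
        return sum(self.n_members.values())


def size_distribution(fs: FamilySet) -> SizeDistribution:
    """Count families and family members per size class {2, 3, 4, 5plus}."""
    fam_counts: Counter[str] = Counter()
    mem_counts: Counter[str] = Counter()
    for fam in fs.families:
        fam_counts[fam.size_class] += 1
        mem_counts[fam.size_class] += fam.size
    return SizeDistribution(
        n_families={c: fam_counts.get(c, 0) for c in SIZE_CLASSES},
        n_members={c: mem_counts.get(c, 0) for c in SIZE_CLASSES},
        n_singletons=len(fs.singletons),
    )


def compare_sources(genes_a: Iterable[str], genes_b: Iterable[str]) -> VennCounts:
    """Exact set-algebra comparison of two ohnologue gene lists."""
    a, b = set(genes_a), set(genes_b)
    return VennCounts(
        overlap=len(a & b), unique_a=len(a - b), unique_b=len(b - a)
    )


def assign_membership(
    proteins: Iterable[str], fs: FamilySet, idmap: IdMap | None = None
) -> pd.DataFrame:
    """Assign proteins to families through the gene↔protein map.

    A protein is in a family iff any of its genes is. Returns a table with
    columns (protein_acc, family_id, size_class, conflict); family_id is empty
    for unassigned proteins, and ``conflict`` is True when a protein's genes
    fall into more than one family (reported, first family by id kept).
    """
    by_id = {f.family_id: f for f in fs.families}
    rows = []
    for acc in sorted(set(proteins)):
        genes = idmap.protein_to_genes.get(acc, set()) if idmap is not None else {acc}
        fams = sorted(
            {f.family_id for g in genes for f in [fs.family_of(g)] if f is not None}
        )
        if not fams:
            rows.append((acc, "", "", False))
        else:
            fam = by_id[fams[0]]
            rows.append((acc, fam.family_id, fam.size_class, len(fams) > 1))
    return pd.DataFrame(
        rows, columns=["protein_acc", "family_id", "size_class", "conflict"]
    )


def family_proteins(fs: FamilySet, idmap: IdMap | None = None) -> set[str]:
    """All proteins whose gene belongs to a family (gene ids if no map given)."""
    if idmap is None:
        return set(fs.family_genes)
    proteins, _ = map_genes_to_proteins(fs.family_genes, idmap)
    return proteins


def write_families(fs: FamilySet, path) -> None:
    rows = [
        (fam.family_id, member, fam.size_class, fam.unresolved)
        for fam in fs.families
        for member in sorted(fam.members)
    ]
    pd.DataFrame(
        rows, columns=["family_id", "member", "size_class", "unresolved"]
    ).to_csv(path, sep="\t", index=False)


def write_size_distribution(dist: SizeDistribution, path) -> None:
    rows = [
        (c, dist.n_families[c], dist.n_members[c]) for c in SIZE_CLASSES
    ] + [("singleton", dist.n_singletons, dist.n_singletons)]
    pd.DataFrame(rows, columns=["size_class", "n_families", "n_members"]).to_csv(
        path, sep="\t", index=False
    )
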