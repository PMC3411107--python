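"""Ohnologue enrichment of the 14-3-3 interactome.

Classifies gold/silver binding standards, tests over-representation of
ohnologue-family membership with an exact hypergeometric upper tail, filters
high-throughput (HTP) capture lists with inclusion/exclusion sets, and exports
the study↔protein interactome graph.

The enrichment universe N defaults to all proteins in the identifier map —
the non-redundant proteome the gene lists were transcribed onto — and is
configurable and reported in the output.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import math

from scipy.special import logsumexp

from ._util import truncated_percent
from .ohnologue_families import Family, FamilySet, family_proteins
from .tabular_io import CaptureExperiment, DataError, IdMap, PhosphositeRecord


@dataclass(frozen=True)
class StandardsSet:
    """Gold (site mapped) and silver (binding shown, site unmapped) standards.

    The two tiers are disjoint by construction: a protein with at least one
    gold-tier site is gold even if it also appears on the silver list.
    """

    gold: frozenset[str]
    silver: frozenset[str]

    @property
    def all(self) -> frozenset[str]:
        return self.gold | self.silver


def classify_standards(
    sites: Sequence[PhosphositeRecord], silver_list: Iterable[str]
) -> StandardsSet:
    gold = frozenset(s.protein_acc for s in sites if s.tier == "gold")
    silver = frozenset(silver_list) - gold
    return StandardsSet(gold=gold, silver=silver)


def _validate_hypergeom(N: int, K: int, n: int, k: int) -> None:
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if not isinstance(v, (int, np.integer)):
            raise DataError(f"{name} must be an integer, got {v!r}")
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise DataError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise DataError(f"k={k} outside [0, min(K, n)={min(K, n)}]")


def _log_comb(a: int, b: int) -> float:
    """log C(a, b) from the exact integer binomial coefficient.

    math.log of an arbitrary-precision int is correctly scaled internally, so
    this is accurate to ~1 ulp of the (≤ ~1e5-magnitude) log value — roughly
    1e-12 absolute — where a log-gamma difference of large arguments loses
    two further digits.
    """
    return math.log(math.comb(a, b))


def _log_pmf_scalar(N: int, K: int, n: int, k: int) -> float:
    return _log_comb(K, k) + _log_comb(N - K, n - k) - _log_comb(N, n)


def hypergeometric_pmf(N: int, K: int, n: int, k: int) -> float:
    """P(X = k) for X ~ Hypergeometric(N, K, n), via exact log-combinatorics."""
    _validate_hypergeom(N, K, n, k)
    if k < max(0, n + K - N):
        return 0.0
    return math.exp(_log_pmf_scalar(N, K, n, k))


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X ≥ k) for X ~ Hypergeometric(N, K, n).

    Each pmf term is computed in log space from exact integer binomial
    coefficients (no overflow, no large-argument log-gamma cancellation) and
    the terms are combined with logsumexp; accurate to ≥ 10 significant
    digits for N ≤ 1e5. Symmetric in K and n.
    """
    _validate_hypergeom(N, K, n, k)
    k_min = max(0, n + K - N)
    if k <= k_min:
        return 1.0
    log_terms = np.array(
        [_log_pmf_scalar(N, K, n, i) for i in range(k, min(K, n) + 1)]
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


@dataclass(frozen=True)
class OverlapResult:
    """2×2 overlap counts plus the hypergeometric upper-tail probability.

    N: universe size; K: ohnologue-protein count; n: query size;
    k: query∩ohnologue count; n_families / n_members_total describe the
    distinct families hit and the sum of their full sizes.
    """

    N: int
    K: int
    n: int
    k: int
    n_families: int
    n_members_total: int
    p_hyper: float

    @property
    def fraction(self) -> float:
        return self.k / self.n if self.n else 0.0

    @property
    def percent(self) -> int:
        return truncated_percent(self.k, self.n) if self.n else 0


def _hit_families(
    proteins: Iterable[str], fs: FamilySet, idmap: IdMap | None
) -> list[Family]:
    hit: dict[str, Family] = {}
    for acc in proteins:
        genes = idmap.protein_to_genes.get(acc, set()) if idmap is not None else {acc}
        for g in genes:
            fam = fs.family_of(g)
            if fam is not None:
                hit[fam.family_id] = fam
    return [hit[fid] for fid in sorted(hit)]


def overlap_stats(
    query: Iterable[str],
    fs: FamilySet,
    universe: Iterable[str],
    idmap: IdMap | None = None,
) -> OverlapResult:
    """Overlap of a protein query set with ohnologue-family membership.

    ``universe`` is the protein universe for the hypergeometric test; the
    query must be contained in it. When ``idmap`` is None, gene ids and
    protein accessions are taken to be the same namespace.
    """
    query = set(query)
    universe = set(universe)
    outside = query - universe
    if outside:
        raise DataError(f"query proteins outside universe: {sorted(outside)[:10]}")
    ohn = family_proteins(fs, idmap) & universe
    k_set = query & ohn
    fams = _hit_families(k_set, fs, idmap)
    p = hypergeometric_tail(len(universe), len(ohn), len(query), len(k_set))
    return OverlapResult(
        N=len(universe),
        K=len(ohn),
        n=len(query),
        k=len(k_set),
        n_families=len(fams),
        n_members_total=sum(f.size for f in fams),
        p_hyper=p,
    )


def filter_htp(
    experiments: Sequence[CaptureExperiment],
    inclusion: Iterable[str],
    exclusion: Iterable[str],
    fs: FamilySet,
    idmap: IdMap | None = None,
    universe: Iterable[str] | None = None,
) -> tuple[set[str], OverlapResult]:
    """Filter HTP capture lists with an inclusion and an exclusion set.

    kept = (union of captured proteins) ∩ inclusion \\ exclusion; family and
    member counts are computed on the kept set as in :func:`overlap_stats`.
    """
    inclusion, exclusion = set(inclusion), set(exclusion)
    union: set[str] = set()
    for e in experiments:
        union |= e.protein_accs
    kept = (union & inclusion) - exclusion
    if universe is None:
        universe = union | inclusion | exclusion
    counts = overlap_stats(kept, fs, universe, idmap=idmap)
    return kept, counts


#: class priority when one protein carries several labels
_CLASS_PRIORITY = ("gold", "silver", "contaminant", "plain")


def build_graph(
    experiments: Sequence[CaptureExperiment],
    standards: StandardsSet,
    contaminants: Iterable[str],
    fs: FamilySet,
    idmap: IdMap | None = None,
) -> nx.Graph:
    """Bipartite study↔protein interactome graph with family grouping.

    One node per study and per distinct captured protein; protein nodes carry
    a ``klass`` attribute with priority gold > silver > contaminant > plain,
    and a ``family_id`` attribute when the protein belongs to a family.
    Node insertion is sorted, so exports are deterministic.
    """
    contaminants = set(contaminants)
    g: nx.Graph = nx.Graph()
    proteins: set[str] = set()
    for e in experiments:
        proteins |= e.protein_accs
    for e in sorted(experiments, key=lambda e: e.study_id):
        g.add_node(f"study:{e.study_id}", kind="study")
    for acc in sorted(proteins):
        if acc in standards.gold:
            klass = "gold"
        elif acc in standards.silver:
            klass = "silver"
        elif acc in contaminants:
            klass = "contaminant"
        else:
            klass = "plain"
        genes = idmap.protein_to_genes.get(acc, set()) if idmap is not None else {acc}
        fams = sorted(
            {f.family_id for ggene in genes for f in [fs.family_of(ggene)] if f}
        )
        g.add_node(acc, kind="protein", klass=klass, family_id=fams[0] if fams else "")
    for e in sorted(experiments, key=lambda e: e.study_id):
        for acc in sorted(e.protein_accs):
            g.add_edge(f"study:{e.study_id}", acc)
    return g


def export_graph(g: nx.Graph, path, dialect: str = "graphml") -> None:
    """Write the interactome graph as GraphML or minimal VisANT-style XML.

    The VisANT dialect is intentionally minimal: node, edge and group elements
    with id/class attributes, enough to express family grouping.
    """
    if dialect == "graphml":
        nx.write_graphml(g, path)
    elif dialect == "visant_xml":
        root = ET.Element("VisAnt")
        groups: dict[str, list[str]] = {}
        for node in sorted(g.nodes):
            data = g.nodes[node]
            el = ET.SubElement(root, "VNodes", id=str(node), kind=data.get("kind", ""))
            if data.get("kind") == "protein":
                el.set("class", data.get("klass", "plain"))
                fid = data.get("family_id", "")
                if fid:
                    groups.setdefault(fid, []).append(str(node))
        for a, b in sorted(map(tuple, map(sorted, g.edges))):
            ET.SubElement(root, "VEdge", **{"from": str(a), "to": str(b)})
        for fid in sorted(groups):
            grp = ET.SubElement(root, "VGroup", id=fid)
            for node in groups[fid]:
                ET.SubElement(grp, "child", id=node)
        ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)
    else:
        raise DataError(f"unknown graph dialect {dialect!r}")


def write_enrichment_summary(result: OverlapResult, path) -> None:
    pd.DataFrame(
        [
            (
                result.N,
                result.K,
                result.n,
                result.k,
                result.fraction,
                result.percent,
                result.p_hyper,
                result.n_families,
                result.n_members_total,
            )
        ],
        columns=[
            "N",
            "K",
            "n",
            "k",
            "fraction",
            "percent",
            "p_hyper",
            "n_families",
            "n_members_total",
        ],
    ).to_csv(path, sep="\t", index=False)
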