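"""Family-level disease association.

Disease classes arrive as a prepared protein→class table (the upstream
OMIM/DAVID retrieval and mouse→human homology steps are curation inputs, not
computed here). A family is *diseased* when at least one member carries a
class; it shows *distinct disorders* when at least two members carry
non-identical, non-empty class sets — the signature of paralogues that have
diverged into different pathologies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from ._util import truncated_percent
from .ohnologue_families import FamilySet
from .tabular_io import DataError, IdMap

DiseaseMap = Mapping[str, set[str]]


@dataclass(frozen=True)
class FamilyDiseaseProfile:
    family_id: str
    member_classes: dict[str, frozenset[str]]

    @property
    def n_members_diseased(self) -> int:
        return sum(1 for c in self.member_classes.values() if c)

    @property
    def any_disease(self) -> bool:
        return self.n_members_diseased >= 1

    @property
    def distinct_disorders(self) -> bool:
        nonempty = {c for c in self.member_classes.values() if c}
        return len(nonempty) >= 2


def annotate_families(
    fs: FamilySet, dm: DiseaseMap, idmap: IdMap | None = None
) -> list[FamilyDiseaseProfile]:
    """One disease profile per family; classes reached via the gene→protein map."""
    profiles = []
    for fam in fs.families:
        member_classes: dict[str, frozenset[str]] = {}
        for gene in sorted(fam.members):
            if idmap is not None:
                accs = idmap.gene_to_proteins.get(gene, set())
            else:
                accs = {gene}
            classes: set[str] = set()
            for acc in accs:
                classes |= set(dm.get(acc, set()))
            member_classes[gene] = frozenset(classes)
        profiles.append(
            FamilyDiseaseProfile(family_id=fam.family_id, member_classes=member_classes)
        )
    return profiles


@dataclass(frozen=True)
class DiseaseSummary:
    n_families: int
    n_families_diseased: int
    fraction: float
    truncated_percent: int
    n_proteins_diseased: int
    n_distinct_disorder_families: int


def disease_summary(profiles: Sequence[FamilyDiseaseProfile]) -> DiseaseSummary:
    """Counts and floor-truncated percentages over a set of family profiles."""
    if not profiles:
        raise DataError("disease_summary needs at least one profile")
    n_dis = sum(1 for p in profiles if p.any_disease)
    return DiseaseSummary(
        n_families=len(profiles),
        n_families_diseased=n_dis,
        fraction=n_dis / len(profiles),
        truncated_percent=truncated_percent(n_dis, len(profiles)),
        n_proteins_diseased=sum(p.n_members_diseased for p in profiles),
        n_distinct_disorder_families=sum(1 for p in profiles if p.distinct_disorders),
    )


def write_profiles(profiles: Sequence[FamilyDiseaseProfile], path) -> None:
    rows = []
    for p in profiles:
        for member, classes in sorted(p.member_classes.items()):
            rows.append(
                (
                    p.family_id,
                    member,
                    ";".join(sorted(classes)),
                    p.any_disease,
                    p.distinct_disorders,
                )
            )
    pd.DataFrame(
        rows,
        columns=["family_id", "member", "classes", "any_disease", "distinct_disorders"],
    ).to_csv(path, sep="\t", index=False)


def write_summary(summary: DiseaseSummary, path) -> None:
    pd.DataFrame(
        [
            (
                summary.n_families,
                summary.n_families_diseased,
                summary.fraction,
                summary.truncated_percent,
                summary.n_proteins_diseased,
                summary.n_distinct_disorder_families,
            )
        ],
        columns=[
            "n_families",
            "n_families_diseased",
            "fraction",
            "truncated_percent",
            "n_proteins_diseased",
            "n_distinct_disorder_families",
        ],
    ).to_csv(path, sep="\t", index=False)
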