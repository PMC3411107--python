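"""Readers, writers and identifier mapping for every external format the pipeline touches.

Canonical on-disk dialects are plain TSV with mandatory headers and (aligned)
FASTA. Identifier namespaces (Ensembl-style gene ids, UniProt-style protein
accessions) are treated as opaque strings: nothing is validated against live
databases, which keeps every run offline and deterministic.

Positions are 1-based inclusive throughout (UniProt convention); motif offsets
downstream are relative to the phosphoresidue at offset 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: residue alphabet for ungapped protein sequences
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")
#: evidence tiers for phosphosite records
TIERS = ("gold", "silver", "htp", "background")


class DataError(ValueError):
    """Malformed or inconsistent input data (hard error)."""


# ---------------------------------------------------------------------------
# Identifier mapping
# ---------------------------------------------------------------------------


@dataclass
class IdMap:
    """A many-to-many gene ↔ protein identifier map.

    One gene may map to several protein accessions (isoforms) and vice versa;
    records are deduplicated on the (gene_id, protein_acc) pair. Isoform-level
    accessions are kept distinct — collapsing is left to callers.
    """

    records: list[tuple[str, str]]
    n_duplicates: int = 0
    n_malformed: int = 0
    gene_to_proteins: dict[str, set[str]] = field(default_factory=dict, repr=False)
    protein_to_genes: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.gene_to_proteins:
            for g, p in self.records:
                self.gene_to_proteins.setdefault(g, set()).add(p)
                self.protein_to_genes.setdefault(p, set()).add(g)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "IdMap":
        seen: set[tuple[str, str]] = set()
        records: list[tuple[str, str]] = []
        dups = 0
        bad = 0
        for g, p in pairs:
            g, p = str(g).strip(), str(p).strip()
            if not g or not p:
                bad += 1
                continue
            if (g, p) in seen:
                dups += 1
                continue
            seen.add((g, p))
            records.append((g, p))
        return cls(records=records, n_duplicates=dups, n_malformed=bad)

    @property
    def genes(self) -> set[str]:
        return set(self.gene_to_proteins)

    @property
    def proteins(self) -> set[str]:
        return set(self.protein_to_genes)

    def __len__(self) -> int:
        return len(self.records)


def read_id_map(path: str | Path) -> IdMap:
    """Load a tab-separated gene_id/protein_acc table (Biomart-style export).

    Well-formed rows are loaded; rows with empty fields are counted and a
    warning is logged. A missing file or a header lacking the required columns
    is a hard error.
    """
    df = _read_tsv(path, required=("gene_id", "protein_acc"))
    idmap = IdMap.from_pairs(zip(df["gene_id"].astype(str), df["protein_acc"].astype(str)))
    if len(idmap) == 0:
        logger.warning("identifier map %s contains no usable rows", path)
    if idmap.n_malformed:
        logger.warning("identifier map %s: %d malformed rows skipped", path, idmap.n_malformed)
    return idmap


def write_id_map(idmap: IdMap, path: str | Path) -> None:
    pd.DataFrame(idmap.records, columns=["gene_id", "protein_acc"]).to_csv(
        path, sep="\t", index=False
    )


def map_genes_to_proteins(
    genes: Iterable[str], idmap: IdMap
) -> tuple[set[str], set[str]]:
    """Map a gene set through the identifier map.

    Returns ``(proteins, unmapped_genes)`` where *proteins* is the union of
    all mappings and *unmapped_genes* the genes with no record. Unmapped genes
    are a normal outcome, not an error.
    """
    proteins: set[str] = set()
    unmapped: set[str] = set()
    for g in genes:
        hits = idmap.gene_to_proteins.get(g)
        if hits:
            proteins.update(hits)
        else:
            unmapped.add(g)
    return proteins, unmapped


# ---------------------------------------------------------------------------
# Sequences and alignments
# ---------------------------------------------------------------------------


@dataclass
class SequenceSet:
    """Mapping of seq_id → ungapped residue string (uppercase IUPAC + X)."""

    seqs: dict[str, str]

    def __post_init__(self) -> None:
        for sid, seq in self.seqs.items():
            if len(seq) < 1:
                raise DataError(f"empty sequence for {sid!r}")
            bad = set(seq) - AMINO_ACIDS
            if bad:
                raise DataError(
                    f"sequence {sid!r} contains non-amino-acid letters {sorted(bad)!r}"
                )

    def __getitem__(self, sid: str) -> str:
        return self.seqs[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self.seqs

    def __len__(self) -> int:
        return len(self.seqs)


@dataclass
class Msa:
    """An ordered multiple alignment: seq_id → aligned string over residues + '-'."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise DataError("alignment needs at least 2 sequences")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise DataError(f"ragged alignment: row lengths {sorted(lengths)}")
        for sid, row in self.rows.items():
            bad = set(row) - AMINO_ACIDS - {"-"}
            if bad:
                raise DataError(
                    f"alignment row {sid!r} contains unknown letters {sorted(bad)!r}"
                )

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def ungapped(self, sid: str) -> str:
        return self.rows[sid].replace("-", "")

    def __len__(self) -> int:
        return len(self.rows)


def read_fasta(path: str | Path) -> SequenceSet:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return SequenceSet(seqs)


def write_fasta(seqs: SequenceSet | Mapping[str, str], path: str | Path) -> None:
    mapping = seqs.seqs if isinstance(seqs, SequenceSet) else dict(seqs)
    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in mapping.items()]
    SeqIO.write(records, str(path), "fasta")


def read_alignment(path: str | Path) -> Msa:
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rows[rec.id] = str(rec.seq).upper()
    return Msa(rows)


def write_alignment(msa: Msa, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in msa.rows.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Phosphosites and capture experiments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhosphositeRecord:
    """A phosphosite with its evidence tier.

    ``position`` is the 1-based residue index in the protein sequence;
    ``residue`` is the phosphoacceptor (S, T or Y).
    """

    protein_acc: str
    position: int
    residue: str
    tier: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DataError(f"position must be ≥ 1, got {self.position}")
        if self.residue not in ("S", "T", "Y"):
            raise DataError(f"residue must be S/T/Y, got {self.residue!r}")
        if self.tier not in TIERS:
            raise DataError(f"tier must be one of {TIERS}, got {self.tier!r}")


def read_phosphosites(path: str | Path) -> list[PhosphositeRecord]:
    df = _read_tsv(path, required=("protein_acc", "position", "residue", "tier"))
    ev = df["evidence"] if "evidence" in df.columns else [""] * len(df)
    out = []
    for acc, pos, res, tier, e in zip(
        df["protein_acc"], df["position"], df["residue"], df["tier"], ev
    ):
        out.append(
            PhosphositeRecord(
                protein_acc=str(acc),
                position=int(pos),
                residue=str(res),
                tier=str(tier),
                evidence="" if pd.isna(e) else str(e),
            )
        )
    return out


def write_phosphosites(sites: Sequence[PhosphositeRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(s.protein_acc, s.position, s.residue, s.tier, s.evidence) for s in sites],
        columns=["protein_acc", "position", "residue", "tier", "evidence"],
    ).to_csv(path, sep="\t", index=False)


def validate_sites_against_sequences(
    sites: Sequence[PhosphositeRecord], seqs: SequenceSet
) -> None:
    """Check each site's stated residue against the supplied sequence (hard error)."""
    for s in sites:
        if s.protein_acc not in seqs:
            continue
        seq = seqs[s.protein_acc]
        if s.position > len(seq):
            raise DataError(
                f"site {s.protein_acc}:{s.position} beyond sequence length {len(seq)}"
            )
        if seq[s.position - 1] != s.residue:
            raise DataError(
                f"site {s.protein_acc}:{s.position} states {s.residue} but sequence "
                f"has {seq[s.position - 1]}"
            )


@dataclass(frozen=True)
class CaptureExperiment:
    """One high-throughput affinity-capture experiment: a study id and its protein list."""

    study_id: str
    protein_accs: frozenset[str]


def read_experiments(path: str | Path) -> list[CaptureExperiment]:
    df = _read_tsv(path, required=("study_id", "protein_acc"))
    grouped: dict[str, set[str]] = {}
    for sid, acc in zip(df["study_id"].astype(str), df["protein_acc"].astype(str)):
        grouped.setdefault(sid, set()).add(acc)
    return [
        CaptureExperiment(study_id=sid, protein_accs=frozenset(accs))
        for sid, accs in sorted(grouped.items())
    ]


def write_experiments(experiments: Sequence[CaptureExperiment], path: str | Path) -> None:
    rows = [
        (e.study_id, acc) for e in experiments for acc in sorted(e.protein_accs)
    ]
    pd.DataFrame(rows, columns=["study_id", "protein_acc"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Pair lists and disease maps
# ---------------------------------------------------------------------------


def read_pairs(path: str | Path) -> list[tuple[str, str, str]]:
    """Read an ohnologue pair list: (gene_a, gene_b, source) rows."""
    df = _read_tsv(path, required=("gene_a", "gene_b", "source"))
    return [
        (str(a), str(b), str(s))
        for a, b, s in zip(df["gene_a"], df["gene_b"], df["source"])
    ]


def write_pairs(pairs: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    pd.DataFrame(list(pairs), columns=["gene_a", "gene_b", "source"]).to_csv(
        path, sep="\t", index=False
    )


def read_disease_map(path: str | Path) -> dict[str, set[str]]:
    """Read a prepared protein→disease-class table (protein_acc, disease_class)."""
    df = _read_tsv(path, required=("protein_acc", "disease_class"))
    dm: dict[str, set[str]] = {}
    for acc, cls in zip(df["protein_acc"].astype(str), df["disease_class"].astype(str)):
        cls = cls.strip()
        if not cls:
            raise DataError(f"empty disease class for protein {acc!r}")
        dm.setdefault(acc, set()).add(cls)
    return dm


def write_disease_map(dm: Mapping[str, set[str]], path: str | Path) -> None:
    rows = [(acc, cls) for acc in sorted(dm) for cls in sorted(dm[acc])]
    pd.DataFrame(rows, columns=["protein_acc", "disease_class"]).to_csv(
        path, sep="\t", index=False
    )


def read_protein_list(path: str | Path, column: str = "protein_acc") -> set[str]:
    """Read a one-column protein list (e.g. silver standards or a contaminant list)."""
    df = _read_tsv(path, required=(column,))
    return set(df[column].astype(str))


def write_protein_list(
    proteins: Iterable[str], path: str | Path, column: str = "protein_acc"
) -> None:
    pd.DataFrame(sorted(proteins), columns=[column]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: header lacks required columns {missing}")
    return df
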