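"""Synthetic proteome/phosphoproteome generator with known ground truth.

Generates every input the pipeline consumes — identifier map, ohnologue pair
lists, family alignments with invertebrate-chordate outgroups, phosphosite
tables, multi-experiment capture lists with contaminant admixture, and
family-level disease labels — so that every stage runs offline and planted
features can be recovered exactly.

The sequence model is substitution-only (no indels): family alignments are
therefore exact by construction and site↔column mapping is trivially
correct. Outgroup truncation — the real-world reason conservation sometimes
cannot be assessed — is modelled as deletion of a prefix or suffix of the
outgroup row, rendered as a gap run. Default parameters mirror the scale of
the human analysis: a ~20k-protein universe with roughly a third of genes in
retained duplicate families, 16 capture experiments, a −2-serine frequency
of 0.46 among binding sites against 0.17 in background phosphosites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ohnologue_families import Family, FamilySet, OhnologPair, size_class_of
from .tabular_io import (
    CaptureExperiment,
    IdMap,
    Msa,
    PhosphositeRecord,
    SequenceSet,
    write_alignment,
    write_disease_map,
    write_experiments,
    write_fasta,
    write_id_map,
    write_pairs,
    write_phosphosites,
    write_protein_list,
)
from .lynchpin_detection import write_roles

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NON_ST = np.array(list("ACDEFGHIKLMNPQVWY"))
DISEASE_CLASSES = ("developmental", "cancer", "psychiatric", "metabolic", "neurological")


@dataclass
class SimConfig:
    """Tunable parameters of the generator; defaults emulate the human-scale study."""

    seed: int = 0
    n_genes: int = 20244
    frac_in_families: float = 0.35
    size_class_weights: dict[str, float] = field(
        default_factory=lambda: {"2": 0.55, "3": 0.25, "4": 0.12, "5plus": 0.08}
    )
    extra_edge_prob: float = 0.3
    seq_length: int = 400
    member_divergence: float = 0.15
    outgroup_divergence: float = 0.35
    outgroup_truncation_prob: float = 0.25
    lynchpin_plant_prob: float = 0.7
    minus2_fg: float = 0.46
    minus2_bg: float = 0.17
    n_background_sites: int = 500
    binder_family_frac: float = 0.05
    n_experiments: int = 16
    capture_prob: float = 0.6
    contaminant_pool_size: int = 200
    contaminant_admixture: float = 0.3
    disease_family_prob: float = 0.91
    disease_member_prob: float = 0.7
    #: exact per-class site counts (lynchpin, divergent, unassignable); overrides
    #: the probabilistic class draw when set
    class_counts: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        probs = [
            self.frac_in_families,
            self.extra_edge_prob,
            self.member_divergence,
            self.outgroup_divergence,
            self.outgroup_truncation_prob,
            self.lynchpin_plant_prob,
            self.minus2_fg,
            self.minus2_bg,
            self.capture_prob,
            self.contaminant_admixture,
            self.disease_family_prob,
            self.disease_member_prob,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must be in [0, 1]")
        if abs(sum(self.size_class_weights.values()) - 1.0) > 1e-9:
            raise ValueError("size_class_weights must sum to 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be ≥ 1")


@dataclass
class PlantedSite:
    family_id: str
    protein_acc: str
    position: int
    status: str  # intended lynchpin/divergent/unassignable verdict


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    family_set: FamilySet
    binder_families: list[str] = field(default_factory=list)
    lynchpin_sites: list[PlantedSite] = field(default_factory=list)
    binders: set[str] = field(default_factory=set)
    contaminants: set[str] = field(default_factory=set)
    disease_map: dict[str, set[str]] = field(default_factory=dict)


def gene_to_protein(gene: str) -> str:
    return "P" + gene[1:]


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


# ---------------------------------------------------------------------------


def simulate_proteome(cfg: SimConfig) -> tuple[IdMap, list[OhnologPair], GroundTruth]:
    """Partition genes into families per the size-class weights and emit pairs.

    Pairs are each family's spanning path plus random extra within-family
    edges, so family recovery by connected components is exact.
    """
    rng = _rng(cfg, 1)
    genes = [f"g{i:06d}" for i in range(1, cfg.n_genes + 1)]
    n_fam_genes = int(round(cfg.frac_in_families * cfg.n_genes))

    classes = list(cfg.size_class_weights)
    weights = np.array([cfg.size_class_weights[c] for c in classes])
    families: list[Family] = []
    pairs: list[OhnologPair] = []
    cursor = 0
    while n_fam_genes - cursor >= 2:
        cls = classes[int(rng.choice(len(classes), p=weights))]
        size = int(rng.integers(5, 9)) if cls == "5plus" else int(cls)
        size = min(size, n_fam_genes - cursor)
        if size < 2:
            break
        members = genes[cursor : cursor + size]
        cursor += size
        families.append(Family(family_id=min(members), members=frozenset(members)))
        for a, b in zip(members, members[1:]):
            pairs.append(OhnologPair(a, b, source="sim"))
        if size > 2:
            for i in range(size):
                for j in range(i + 2, size):
                    if rng.random() < cfg.extra_edge_prob:
                        pairs.append(OhnologPair(members[i], members[j], source="sim"))

    families.sort(key=lambda f: f.family_id)
    covered = {g for f in families for g in f.members}
    fs = FamilySet(
        families=families, singletons=set(genes) - covered, universe=set(genes)
    )
    idmap = IdMap.from_pairs((g, gene_to_protein(g)) for g in genes)
    return idmap, pairs, GroundTruth(family_set=fs)


def simulate_sequences(
    truth: GroundTruth, cfg: SimConfig
) -> tuple[SequenceSet, dict[str, Msa], dict[str, dict[str, str]]]:
    """Sequences and family alignments with a planted 14-3-3 motif per binder family.

    An ancestral sequence per family carries one consensus motif (basic at −3,
    −2 serine with probability ``minus2_fg``, no +1 proline). Members diverge
    by per-site substitution with the motif window held invariant; outgroups
    diverge faster with the phosphosite column set according to the planted
    class: kept S/T (lynchpin), substituted to non-S/T (divergent), or removed
    by prefix/suffix truncation of the outgroup rows (unassignable).
    """
    rng = _rng(cfg, 2)
    fams = truth.family_set.families
    n_binder = max(1, int(round(cfg.binder_family_frac * len(fams))))
    n_binder = min(n_binder, len(fams))
    chosen = sorted(rng.choice(len(fams), size=n_binder, replace=False).tolist())
    binder_fams = [fams[i] for i in chosen]
    truth.binder_families = [f.family_id for f in binder_fams]

    if cfg.class_counts is not None:
        n_l, n_d, n_u = cfg.class_counts
        if n_l + n_d + n_u != n_binder:
            raise ValueError(
                f"class_counts must sum to the number of binder families ({n_binder})"
            )
        statuses = ["lynchpin"] * n_l + ["divergent"] * n_d + ["unassignable"] * n_u
    else:
        statuses = []
        for _ in binder_fams:
            if rng.random() < cfg.outgroup_truncation_prob:
                statuses.append("unassignable")
            elif rng.random() < cfg.lynchpin_plant_prob:
                statuses.append("lynchpin")
            else:
                statuses.append("divergent")

    seqs: dict[str, str] = {}
    alignments: dict[str, Msa] = {}
    roles: dict[str, dict[str, str]] = {}
    L = cfg.seq_length
    center = L // 2  # 1-based phosphosite position
    c0 = center - 1

    for fam, status in zip(binder_fams, statuses):
        ancestral = rng.choice(AA20, size=L).copy()
        # plant the consensus window: basic at −3, centre S, no +1 proline
        ancestral[c0] = "S"
        ancestral[c0 - 3] = "R"
        ancestral[c0 - 2] = "S" if rng.random() < cfg.minus2_fg else str(
            rng.choice(NON_ST)
        )
        if ancestral[c0 + 1] == "P":
            ancestral[c0 + 1] = "A"
        window_idx = set(range(c0 - 5, c0 + 3))

        members = sorted(fam.members)
        rows: dict[str, str] = {}
        for gene in members:
            seq = ancestral.copy()
            mask = rng.random(L) < cfg.member_divergence
            for i in np.flatnonzero(mask):
                if i not in window_idx:
                    seq[i] = rng.choice(AA20)
            rows[gene_to_protein(gene)] = "".join(seq)

        out_rows: dict[str, str] = {}
        for k, og in enumerate((f"{fam.family_id}|amphioxus", f"{fam.family_id}|ciona")):
            seq = ancestral.copy()
            mask = rng.random(L) < cfg.outgroup_divergence
            for i in np.flatnonzero(mask):
                if i != c0:
                    seq[i] = rng.choice(AA20)
            if status == "lynchpin":
                seq[c0] = "S" if rng.random() < 0.5 else "T"
            elif status == "divergent":
                seq[c0] = rng.choice(NON_ST)
            row = "".join(seq)
            if status == "unassignable":
                # truncation covering the phosphosite column, as a gap run
                if k == 0:
                    row = row[:c0] + "-" * (L - c0)
                else:
                    row = "-" * (c0 + 1) + row[c0 + 1 :]
            out_rows[og] = row

        fid = fam.family_id
        alignments[fid] = Msa({**rows, **out_rows})
        roles[fid] = {acc: "member" for acc in rows} | {
            og: "outgroup" for og in out_rows
        }
        for acc, row in rows.items():
            seqs[acc] = row
        for og, row in out_rows.items():
            ungapped = row.replace("-", "")
            if ungapped:
                seqs[og] = ungapped

        ref = gene_to_protein(members[0])
        truth.lynchpin_sites.append(
            PlantedSite(family_id=fid, protein_acc=ref, position=center, status=status)
        )
        truth.binders.add(ref)

    return SequenceSet(seqs), alignments, roles


def simulate_phosphosites(
    truth: GroundTruth, cfg: SimConfig, seqs: SequenceSet
) -> list[PhosphositeRecord]:
    """Gold sites at the planted motif centres plus uniform background sites.

    Background sites live on dedicated non-binder proteins whose sequences are
    appended to ``seqs``; their −2 serine probability is ``minus2_bg``.
    """
    rng = _rng(cfg, 3)
    sites = [
        PhosphositeRecord(
            protein_acc=ps.protein_acc,
            position=ps.position,
            residue=seqs[ps.protein_acc][ps.position - 1],
            tier="gold",
            evidence="planted",
        )
        for ps in truth.lynchpin_sites
    ]
    bg_len = 60
    for i in range(1, cfg.n_background_sites + 1):
        acc = f"B{i:05d}"
        seq = rng.choice(AA20, size=bg_len).copy()
        pos = int(rng.integers(8, bg_len - 4))  # 1-based, away from termini
        seq[pos - 1] = "S"
        seq[pos - 3] = "S" if rng.random() < cfg.minus2_bg else str(rng.choice(NON_ST))
        seqs.seqs[acc] = "".join(seq)
        sites.append(
            PhosphositeRecord(
                protein_acc=acc,
                position=pos,
                residue="S",
                tier="background",
                evidence="planted-background",
            )
        )
    return sites


def simulate_experiments(
    truth: GroundTruth, cfg: SimConfig
) -> tuple[list[CaptureExperiment], set[str]]:
    """Capture experiments sampling binders plus admixed labelled contaminants."""
    rng = _rng(cfg, 4)
    singles = sorted(truth.family_set.singletons)
    n_cont = min(cfg.contaminant_pool_size, len(singles))
    idx = sorted(rng.choice(len(singles), size=n_cont, replace=False).tolist())
    contaminants = {gene_to_protein(singles[i]) for i in idx}
    truth.contaminants = contaminants

    binders = sorted(truth.binders)
    cont = sorted(contaminants)
    experiments = []
    for e in range(1, cfg.n_experiments + 1):
        captured = {b for b in binders if rng.random() < cfg.capture_prob}
        captured |= {c for c in cont if rng.random() < cfg.contaminant_admixture}
        experiments.append(
            CaptureExperiment(study_id=f"HTP{e:02d}", protein_accs=frozenset(captured))
        )
    return experiments, contaminants


def simulate_disease(truth: GroundTruth, cfg: SimConfig) -> dict[str, set[str]]:
    """Per-family disease labels: a family is diseased with the configured
    probability; members of a diseased family carry a class independently
    (at least one forced)."""
    rng = _rng(cfg, 5)
    dm: dict[str, set[str]] = {}
    for fam in truth.family_set.families:
        if rng.random() >= cfg.disease_family_prob:
            continue
        members = sorted(fam.members)
        hit_any = False
        for i, gene in enumerate(members):
            last = i == len(members) - 1
            if rng.random() < cfg.disease_member_prob or (last and not hit_any):
                cls = str(rng.choice(len(DISEASE_CLASSES)))
                dm.setdefault(gene_to_protein(gene), set()).add(
                    DISEASE_CLASSES[int(cls)]
                )
                hit_any = True
    truth.disease_map = dm
    return dm


# ---------------------------------------------------------------------------


@dataclass
class SimBundle:
    """A complete simulated fixture: all pipeline inputs plus the ground truth."""

    cfg: SimConfig
    idmap: IdMap
    pairs: list[OhnologPair]
    truth: GroundTruth
    sequences: SequenceSet
    alignments: dict[str, Msa]
    roles: dict[str, dict[str, str]]
    sites: list[PhosphositeRecord]
    experiments: list[CaptureExperiment]
    contaminants: set[str]
    disease_map: dict[str, set[str]]


def simulate_all(cfg: SimConfig) -> SimBundle:
    """Run every generator stage in order and return the complete bundle."""
    idmap, pairs, truth = simulate_proteome(cfg)
    sequences, alignments, roles = simulate_sequences(truth, cfg)
    sites = simulate_phosphosites(truth, cfg, sequences)
    experiments, contaminants = simulate_experiments(truth, cfg)
    disease_map = simulate_disease(truth, cfg)
    return SimBundle(
        cfg=cfg,
        idmap=idmap,
        pairs=pairs,
        truth=truth,
        sequences=sequences,
        alignments=alignments,
        roles=roles,
        sites=sites,
        experiments=experiments,
        contaminants=contaminants,
        disease_map=disease_map,
    )


def write_fixture_dir(bundle: SimBundle, outdir: str | Path) -> list[Path]:
    """Materialize a complete fixture directory in the pipeline's TSV/FASTA dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "alignments").mkdir(exist_ok=True)
    written: list[Path] = []

    def note(p: Path) -> Path:
        written.append(p)
        return p

    write_id_map(bundle.idmap, note(outdir / "idmap.tsv"))
    write_pairs(
        [(p.gene_a, p.gene_b, p.source) for p in bundle.pairs],
        note(outdir / "pairs.tsv"),
    )
    write_fasta(bundle.sequences, note(outdir / "sequences.fasta"))
    for fid in sorted(bundle.alignments):
        write_alignment(
            bundle.alignments[fid], note(outdir / "alignments" / f"{fid}.fasta")
        )
    write_roles(bundle.roles, note(outdir / "roles.tsv"))
    write_phosphosites(bundle.sites, note(outdir / "sites.tsv"))
    write_experiments(bundle.experiments, note(outdir / "experiments.tsv"))
    write_protein_list(bundle.contaminants, note(outdir / "exclusion.tsv"))
    write_protein_list(set(), note(outdir / "silver.tsv"))
    write_disease_map(bundle.disease_map, note(outdir / "disease.tsv"))
    # ground-truth bundle
    write_protein_list(bundle.truth.binders, note(outdir / "truth_binders.tsv"))
    import pandas as pd

    pd.DataFrame(
        [
            (s.family_id, s.protein_acc, s.position, s.status)
            for s in bundle.truth.lynchpin_sites
        ],
        columns=["family_id", "protein_acc", "position", "status"],
    ).to_csv(note(outdir / "truth_lynchpins.tsv"), sep="\t", index=False)
    return written
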