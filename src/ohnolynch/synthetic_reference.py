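"""Synthetic reconstruction of the published supplementary-table structure.

The original study distributed its standards, family and capture tables as
spreadsheets that are not redistributable here. This module *constructs*,
fully deterministically and in memory, a synthetic fixture whose composition
encodes the same structure the analysis operated on:

* two ohnologue gene lists overlapping by 6374 genes (920 / 3096 unique),
  transcribed onto a 20 244-protein universe with 7104 / 9367 proteins
  assignable to families of two or more;
* 172 gold + 35 silver 14-3-3-binding standards, 174 of the 207 inside
  139 families totalling 525 members;
* 216 gold-standard phosphosites of which 100 carry a −2 serine; 103 sites in
  76 families conserved family-wide and matched by an S/T in an invertebrate
  chordate outgroup (49 of the 103 with a −2 serine);
* 16 capture experiments whose union is 1772 proteins, 825 of them
  ohnologues in 564 families of 2023 members, reduced to 750 proteins in 538
  families of 1929 members once 75 labelled contaminants are excluded;
* disease labels making 127 of the 139 standards families disease-associated
  (350 member proteins), 76 of them with distinct disorders across members.

All of these quantities are *recomputed* by the pipeline from the constructed
inputs; nothing here shortcuts the analysis. The fixture is synthetic: gene
and protein identifiers, sequences and study ids are invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ohnologue_families import FamilySet, OhnologPair, build_families
from .tabular_io import (
    CaptureExperiment,
    IdMap,
    Msa,
    PhosphositeRecord,
    SequenceSet,
)

# family-size composition of the standards families: 139 families, 525 members
_STD_SIZES = [2] * 12 + [3] * 37 + [4] * 60 + [5] * 30
# capture-hit families that survive contaminant exclusion: 538 families, 1929 members
_HTP_KEPT_SIZES = [2] * 85 + [3] * 153 + [4] * 200 + [5] * 100
# capture-hit families removed entirely by the exclusion list: 26 families, 94 members
_HTP_EXCL_SIZES = [3] * 10 + [4] * 16

_SEQ_LEN = 80
_SITE_COLS = (40, 60)  # 1-based positions used for first/second sites


def _protein(gene: str) -> str:
    return "P" + gene[1:]


@dataclass
class ReferenceFixture:
    """In-memory bundle of all constructed inputs (see module docstring)."""

    idmap: IdMap
    genes_a: set[str]
    genes_b: set[str]
    pairs_a: list[OhnologPair]
    pairs_b: list[OhnologPair]
    family_set: FamilySet            # source-A families over the full gene universe
    family_set_b: FamilySet
    sites: list[PhosphositeRecord]   # 216 gold sites
    silver_list: set[str]
    sequences: SequenceSet
    alignments: dict[str, Msa]
    roles: dict[str, dict[str, str]]
    experiments: list[CaptureExperiment]
    exclusion: set[str]
    disease_map: dict[str, set[str]]
    standards_families: list[str] = field(default_factory=list)


def build_reference_fixture() -> ReferenceFixture:  # noqa: C901
    """Construct the synthetic reference fixture (deterministic, no RNG)."""
    # ------------------------------------------------------------------ genes
    def block(prefix: str, n: int) -> list[str]:
        return [f"{prefix}{i:05d}" for i in range(1, n + 1)]

    std_genes = block("gA", 525)        # standards-family genes
    htp_genes = block("gH", 2023)       # capture-hit-family genes
    fil_genes = block("gF", 4746)       # filler family genes (source A)
    bon_genes = block("gB", 3096)       # genes unique to source B
    sng_genes = block("gZ", 10044)      # singleton genes

    genes_a = set(std_genes) | set(htp_genes) | set(fil_genes)          # 7294
    overlap = std_genes + htp_genes + fil_genes[:3826]                  # 6374
    genes_b = set(overlap) | set(bon_genes)                             # 9470

    # unmapped genes: 103 in the overlap, 87 unique to source A
    unmapped = set(fil_genes[3723:3826]) | set(fil_genes[4659:])
    mapped_genes = (genes_a - unmapped) | set(bon_genes) | set(sng_genes)
    idmap = IdMap.from_pairs(sorted((g, _protein(g)) for g in mapped_genes))

    # ---------------------------------------------------------------- families
    pairs_a: list[OhnologPair] = []
    families: list[list[str]] = []

    def carve(genes: list[str], sizes: list[int]) -> list[list[str]]:
        out, cur = [], 0
        for s in sizes:
            members = genes[cur : cur + s]
            cur += s
            out.append(members)
            for a, b in zip(members, members[1:]):
                pairs_a.append(OhnologPair(a, b, source="A"))
        assert cur == len(genes)
        return out

    std_fams = carve(std_genes, _STD_SIZES)                  # 139
    htp_kept_fams = carve(htp_genes[:1929], _HTP_KEPT_SIZES)  # 538
    htp_excl_fams = carve(htp_genes[1929:], _HTP_EXCL_SIZES)  # 26
    fil_fams = carve(fil_genes, [2] * 2373)
    families = std_fams + htp_kept_fams + htp_excl_fams + fil_fams

    universe_genes = genes_a | genes_b | set(sng_genes)
    family_set = build_families(pairs_a, universe_genes)

    pairs_b: list[OhnologPair] = []
    ov = sorted(overlap)
    for i in range(0, len(ov), 2):
        pairs_b.append(OhnologPair(ov[i], ov[i + 1], source="B"))
    for i in range(0, len(bon_genes), 2):
        pairs_b.append(OhnologPair(bon_genes[i], bon_genes[i + 1], source="B"))
    family_set_b = build_families(pairs_b, universe_genes)

    # ---------------------------------------------------------------- standards
    # 174 in-family standards: 2 from each of the first 35 families, 1 from the rest
    in_family: list[str] = []
    for i, fam in enumerate(std_fams):
        picks = fam[:2] if i < 35 else fam[:1]
        in_family.extend(_protein(g) for g in picks)
    assert len(in_family) == 174

    gold_in = in_family[:144]
    silver_in = in_family[144:]          # 30
    gold_out = [_protein(g) for g in sng_genes[:28]]
    silver_out = [_protein(g) for g in sng_genes[28:33]]
    gold_proteins = gold_in + gold_out   # 172
    silver_list = set(silver_in) | set(silver_out)  # 35

    # gold protein per family, in family order (first 109 std families hold gold)
    fam_gold: dict[int, list[str]] = {}
    cursor = 0
    for i in range(35):
        fam_gold[i] = gold_in[cursor : cursor + 2]
        cursor += 2
    for i in range(35, 109):
        fam_gold[i] = [gold_in[cursor]]
        cursor += 1
    assert cursor == 144

    # ------------------------------------------------------------------- sites
    # lynchpin sites: 2 in each of families 0..26, 1 in families 27..75  → 103
    lynch_sites: list[tuple[int, str, int]] = []   # (family index, protein, pos)
    for i in range(27):
        lynch_sites.append((i, fam_gold[i][0], _SITE_COLS[0]))
        lynch_sites.append((i, fam_gold[i][1], _SITE_COLS[1]))
    for i in range(27, 76):
        lynch_sites.append((i, fam_gold[i][0], _SITE_COLS[0]))
    assert len(lynch_sites) == 103

    # non-lynchpin in-family sites (divergent at the outgroup): 57
    div_sites: list[tuple[int, str, int]] = []
    for i in range(27, 35):  # second gold protein of two-gold families 27..34
        div_sites.append((i, fam_gold[i][1], _SITE_COLS[1]))
    for i in range(76, 109):
        div_sites.append((i, fam_gold[i][0], _SITE_COLS[0]))
    for i in range(76, 92):  # 16 proteins carry a second site
        div_sites.append((i, fam_gold[i][0], _SITE_COLS[1]))
    assert len(div_sites) == 57

    # out-of-family sites (no alignment → unassignable): 28 proteins × 2 sites
    out_sites = [
        (None, acc, col) for acc in gold_out for col in _SITE_COLS
    ]
    assert len(lynch_sites) + len(div_sites) + len(out_sites) == 216

    # −2 serine flags: 49 of the 103 lynchpins, 51 of the 113 other sites
    minus2: dict[tuple[str, int], bool] = {}
    for j, (_, acc, col) in enumerate(lynch_sites):
        minus2[(acc, col)] = j < 49
    for j, (_, acc, col) in enumerate(div_sites + out_sites):
        minus2[(acc, col)] = j < 51

    # --------------------------------------------------- sequences & alignments
    def plant(row: list[str], col: int, has_minus2_s: bool) -> None:
        row[col - 1] = "S"
        row[col - 4] = "R"          # basic residue at −3
        row[col - 3] = "S" if has_minus2_s else "G"
        row[col] = "M"              # never a +1 proline

    sequences: dict[str, str] = {}
    alignments: dict[str, Msa] = {}
    roles: dict[str, dict[str, str]] = {}

    fam_sites: dict[int, list[tuple[str, int, str]]] = {}
    for i, acc, col in lynch_sites:
        fam_sites.setdefault(i, []).append((acc, col, "lynchpin"))
    for i, acc, col in div_sites:
        fam_sites.setdefault(i, []).append((acc, col, "divergent"))

    for i in sorted(fam_sites):
        fam = std_fams[i]
        fid = min(fam)
        member_row = ["A"] * _SEQ_LEN
        out_row = ["A"] * _SEQ_LEN
        for acc, col, verdict in fam_sites[i]:
            plant(member_row, col, minus2[(acc, col)])
            out_row[col - 4] = "R"
            out_row[col - 3] = member_row[col - 3]
            out_row[col] = "M"
            out_row[col - 1] = "S" if verdict == "lynchpin" else "A"
        rows: dict[str, str] = {}
        for g in fam:
            rows[_protein(g)] = "".join(member_row)
            sequences[_protein(g)] = "".join(member_row)
        out_str = "".join(out_row)
        rows[f"{fid}|amphioxus"] = out_str
        rows[f"{fid}|ciona"] = out_str
        alignments[fid] = Msa(rows)
        roles[fid] = {_protein(g): "member" for g in fam} | {
            f"{fid}|amphioxus": "outgroup",
            f"{fid}|ciona": "outgroup",
        }

    for acc in gold_out:
        row = ["A"] * _SEQ_LEN
        for col in _SITE_COLS:
            plant(row, col, minus2[(acc, col)])
        sequences[acc] = "".join(row)

    sites = [
        PhosphositeRecord(acc, col, "S", "gold", evidence="synthetic")
        for _, acc, col in lynch_sites + div_sites + out_sites
    ]

    # -------------------------------------------------------------- experiments
    captured: list[str] = []
    for j, fam in enumerate(htp_kept_fams):
        n_take = 2 if j < 212 else 1
        captured.extend(_protein(g) for g in fam[:n_take])
    assert len(captured) == 750
    contaminant_hits = [_protein(fam[0]) for fam in htp_excl_fams]   # 26
    size4_kept = [f for f in htp_kept_fams if len(f) == 4]
    for fam in size4_kept[:49]:
        contaminant_hits.append(_protein(fam[-1]))                    # 49 more
    assert len(contaminant_hits) == 75

    htp_singles = [_protein(g) for g in sng_genes[33 : 33 + 947]]
    union = captured + contaminant_hits + htp_singles                 # 1772
    assert len(union) == len(set(union)) == 1772

    buckets: dict[int, set[str]] = {e: set() for e in range(16)}
    for j, acc in enumerate(union):
        buckets[j % 16].add(acc)
    experiments = [
        CaptureExperiment(study_id=f"HTP{e + 1:02d}", protein_accs=frozenset(buckets[e]))
        for e in range(16)
    ]

    exclusion = set(contaminant_hits) | {
        _protein(g) for g in sng_genes[33 + 947 : 33 + 947 + 100]
    }

    # ------------------------------------------------------------------ disease
    disease: dict[str, set[str]] = {}
    n_diseased_members = 0
    for i in range(127):
        fam = std_fams[i]
        if i < 76:  # distinct disorders across two members
            disease[_protein(fam[0])] = {"cancer"}
            disease[_protein(fam[1])] = {"developmental"}
            n_diseased_members += 2
        else:
            disease[_protein(fam[0])] = {"cancer"}
            n_diseased_members += 1
    # top up to 350 diseased member proteins without changing family verdicts
    for i in range(127):
        if n_diseased_members >= 350:
            break
        fam = std_fams[i]
        start = 2 if i < 76 else 1
        for g in fam[start:]:
            if n_diseased_members >= 350:
                break
            key = _protein(g)
            if key not in disease:
                disease[key] = {"cancer"}
                n_diseased_members += 1
    assert n_diseased_members == 350

    return ReferenceFixture(
        idmap=idmap,
        genes_a=genes_a,
        genes_b=genes_b,
        pairs_a=pairs_a,
        pairs_b=pairs_b,
        family_set=family_set,
        family_set_b=family_set_b,
        sites=sites,
        silver_list=silver_list,
        sequences=SequenceSet(sequences),
        alignments=alignments,
        roles=roles,
        experiments=experiments,
        exclusion=exclusion,
        disease_map=disease,
        standards_families=[min(f) for f in std_fams],
    )


def analyse_reference_fixture(fix: ReferenceFixture | None = None) -> dict:
    """Run the full pipeline over the synthetic reference fixture.

    Returns the headline quantities as a flat dict; every value is computed by
    the pipeline operations, not read off the construction.
    """
    from .disease_annotation import annotate_families, disease_summary
    from .interactome_enrichment import (
        classify_standards,
        filter_htp,
        overlap_stats,
    )
    from .lynchpin_detection import scan_families
    from .motif_analysis import minus2_fraction, windows_from_sites
    from .ohnologue_families import assign_membership, compare_sources, family_proteins

    if fix is None:
        fix = build_reference_fixture()

    venn = compare_sources(fix.genes_a, fix.genes_b)
    universe = fix.idmap.proteins
    assigned_a = assign_membership(universe, fix.family_set, fix.idmap)
    n_assigned_a = int((assigned_a["family_id"] != "").sum())
    assigned_b = assign_membership(universe, fix.family_set_b, fix.idmap)
    n_assigned_b = int((assigned_b["family_id"] != "").sum())

    standards = classify_standards(fix.sites, fix.silver_list)
    ov = overlap_stats(standards.all, fix.family_set, universe, idmap=fix.idmap)

    inclusion = family_proteins(fix.family_set, fix.idmap)
    union: set[str] = set()
    for e in fix.experiments:
        union |= e.protein_accs
    pre = overlap_stats(
        union & inclusion, fix.family_set, universe, idmap=fix.idmap
    )
    kept, post = filter_htp(
        fix.experiments,
        inclusion,
        fix.exclusion,
        fix.family_set,
        idmap=fix.idmap,
        universe=universe,
    )

    windows = windows_from_sites(fix.sites, fix.sequences)
    m2_all = minus2_fraction(windows)
    calls, summary = scan_families(fix.alignments, fix.sites, fix.roles)
    lynch_windows = [
        w
        for w in windows
        if any(
            c.status == "lynchpin"
            and c.reference_site == (w.protein_acc, w.center_pos)
            for c in calls
        )
    ]
    m2_lynch = minus2_fraction(lynch_windows)

    std_fids = set(fix.standards_families)
    profiles = [
        p
        for p in annotate_families(fix.family_set, fix.disease_map, fix.idmap)
        if p.family_id in std_fids
    ]
    dsum = disease_summary(profiles)

    return {
        "source_overlap_genes": venn.overlap,
        "source_unique_a": venn.unique_a,
        "source_unique_b": venn.unique_b,
        "proteins_assigned_a": n_assigned_a,
        "proteins_assigned_b": n_assigned_b,
        "n_gold": len(standards.gold),
        "n_silver": len(standards.silver),
        "standards_k": ov.k,
        "standards_n": ov.n,
        "standards_percent": ov.percent,
        "standards_p_hyper": ov.p_hyper,
        "standards_families": ov.n_families,
        "standards_members": ov.n_members_total,
        "htp_union": len(union),
        "htp_ohnologues": pre.k,
        "htp_families": pre.n_families,
        "htp_members": pre.n_members_total,
        "htp_kept": len(kept),
        "htp_kept_families": post.n_families,
        "htp_kept_members": post.n_members_total,
        "gold_sites": m2_all.n_sites,
        "gold_sites_minus2": m2_all.n_minus2,
        "gold_sites_minus2_percent": m2_all.truncated_percent,
        "lynchpin_sites": summary.n_lynchpins,
        "lynchpin_families": summary.n_families_with_lynchpin,
        "lynchpin_minus2": m2_lynch.n_minus2,
        "lynchpin_minus2_percent": m2_lynch.truncated_percent,
        "disease_families": dsum.n_families_diseased,
        "disease_families_percent": dsum.truncated_percent,
        "disease_proteins": dsum.n_proteins_diseased,
        "distinct_disorder_families": dsum.n_distinct_disorder_families,
    }
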