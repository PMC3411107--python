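# Methods

## Family assembly

Ohnologue families are the connected components of the gene-pair graph.
Pair lists from different sources are kept separate and compared by exact set
algebra (Venn counts of the gene lists; per-source protein assignment
tables); a curated overlay can merge or override assignments. Family identity
is the lexicographically smallest member gene, so outputs are deterministic
and diff-friendly. Components of five or more genes cannot stem from the two
rounds of whole-genome duplication alone; they are retained under the size
class `5plus` and flagged `unresolved` rather than being split, since
splitting requires phylogenetic evidence the pair lists do not carry.

Identifier namespaces (gene ids, protein accessions) are opaque strings and
many-to-many maps are kept in full; nothing is validated against live
databases, which keeps every run offline and reproducible. A protein belongs
to a family iff any of its genes does; conflicting multi-gene assignments are
reported, with the first family by id kept.

## Enrichment statistic

Over-representation of ohnologue membership in a protein query set is tested
with the exact hypergeometric upper tail P(X ≥ k) for X ~ Hypergeom(N, K, n):
universe *N* (default: all proteins in the identifier map, configurable and
reported), *K* ohnologue proteins, query size *n*, overlap *k*. Only the
upper tail is computed — the claim under test is enrichment, not depletion.

Numerics: each pmf term is computed in log space as
log C(K,k) + log C(N−K,n−k) − log C(N,n), where each log-binomial comes from
`math.log` of the exact integer coefficient; terms are combined with
`logsumexp`. This avoids both overflow and the large-argument log-gamma
cancellation that limits a `gammaln`-based pmf to ~1e-10 absolute accuracy;
the pmf here normalizes to 1 within ~1e-12 at N = 1e5. Tests cross-check
against exact rational enumeration (all parameter combinations with N ≤ 12)
and against `scipy.stats.hypergeom`.

Alongside *k*, the number of distinct families hit and the sum of their full
sizes are reported, since the downstream conservation analysis operates on
whole families.

## Capture-list filtering

High-throughput affinity-capture experiments are modelled as (study id,
protein set) pairs. Filtering is pure set algebra:
`kept = (∪ experiments) ∩ inclusion \ exclusion`, with inclusion the
ohnologue proteins and exclusion a labelled contaminant list; family/member
counts on the kept set are computed as in the enrichment statistic. The
interactome graph is bipartite (study ↔ protein) with protein class priority
gold > silver > contaminant > plain and family grouping; node insertion is
sorted, so GraphML and the minimal VisANT-style XML export (node, edge,
group elements with id/class attributes only) are byte-deterministic.

## Motif grammar and −2 serine enrichment

The analysed window spans offsets −5..+2 around the phosphoresidue (offset
0), padded with `-` at protein termini; `-` never matches a residue class.
The consensus (mode-1-like) grammar requires ≥1 basic residue at −3..−5 and
no proline at +1. The basic set defaults to {K, R}; histidine can be added by
flag (some kinases, e.g. the Lats family, phosphorylate HxRxx(pS/pT) sites)
but is off by default to match the standard basic-residue convention.
"Phosphorylatable −2 serine" counts S only by default; a flag folds in T,
which is always reported separately.

Enrichment of the −2 serine among binding sites is assessed against
`n_resamples` draws (default 999) of `n_draw` windows (default: the observed
set size) without replacement from a background phosphosite pool, with the
add-one empirical p-value (1 + #{background ≥ observed}) / (n_resamples + 1),
which can never be exactly zero. The draw size and repetition count are
exposed as parameters because background-set construction is genuinely open;
the defaults make the background match the foreground's sample size.

Integer percentages are floor-truncated throughout (`percent_mode: round` is
available in the CLI config): truncation is the convention that reproduces
printed integer percentages such as 84 (174/207), 46 (100/216), 47 (49/103)
and 91 (127/139) from their ratios. One related published figure is
internally inconsistent — a 64% figure printed against the ratio 350/525,
which computes to 66.7% (floor 66); the package reports the count and the
computed percent and leaves the discrepancy documented rather than resolved.

## Lynchpin calling

A candidate site is mapped from its 1-based ungapped position to the
alignment column and judged by a 3-state rule:

1. **unassignable** — any member row lacks coverage at the column, or all
   outgroup rows do. Coverage means the column lies inside the row's
   sequenced span; leading/trailing gap runs model truncated database
   sequences, which are common for the invertebrate chordates and carry no
   evidence either way.
2. **lynchpin** — every member residue is S or T (S↔T interchange allowed;
   conservation is required of *all* members, not a majority, because the
   hypothesis is family-wide retention) and at least one covered outgroup
   residue is S or T. One matching outgroup (amphioxus *or* tunicate)
   suffices by default; requiring all covered outgroups is a flag.
3. **divergent** — otherwise. Internal gaps count as non-S/T residues
   (substitutional evidence), not missing coverage.

Verdicts are invariant to row order and outgroup order. Adding an outgroup
row can resolve `unassignable` and can promote `divergent` (outgroup-failed)
to `lynchpin` under the any-outgroup rule, but can never demote a
`lynchpin`. A site whose protein appears in no alignment is recorded as
unassignable with reason `no-alignment`; a protein appearing as a member in
two alignments is a hard error.

The pipeline consumes externally produced multiple alignments. The internal
Needleman–Wunsch aligner (affine gaps, gap of length L costing
`gap_open + L·gap_extend`; identity or named substitution matrix;
deterministic traceback under a fixed tie-break order over
diagonal/up/left) exists so fixtures need no external alignment tool; it is
never substituted for a real family alignment. Its scores are verified
against exhaustive enumeration of all global alignments for short sequences.

## Disease annotation

Disease classes arrive as a prepared protein→class table; upstream OMIM/DAVID
retrieval and mouse→human homology mapping are curation inputs, out of scope
so tests stay offline. A family is diseased when ≥1 member carries a class;
it shows distinct disorders when ≥2 members carry non-identical non-empty
class sets. Summaries report counts, fractions and floor percentages.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
full determinism under a seed (integer-seeded `numpy` generators, one
sub-stream per stage; no dependence on hash ordering):

* genes partitioned into families by size-class weights (default
  2:0.55, 3:0.25, 4:0.12, 5+:0.08 over a 20 244-gene universe with 35% of
  genes in families — the scale of the human analysis); pair lists are each
  family's spanning path plus random extra in-family edges, so component
  recovery is exact by construction;
* one ancestral sequence per binder family (default 5% of families, length
  400) carrying a planted consensus motif: basic at −3, no +1 proline,
  −2 serine with probability 0.46 in foreground sites against 0.17 in
  background sites — the observed separation between binding sites and
  random phosphosites; members diverge by per-site substitution (default
  0.15) with the motif window held invariant, outgroups at 0.35 with the
  phosphosite column set by the planted conservation class;
* the sequence model is substitution-only (no indels), so family
  "alignments" are exact by construction and site↔column mapping is
  trivially correct. This sacrifices indel realism for testability: passing
  recovery tests demonstrate correctness of the calling logic, not
  robustness to alignment error, which is why real analyses must supply
  externally computed alignments;
* outgroup truncation (default probability 0.25, matching the prevalence of
  incomplete invertebrate database sequences) is a prefix/suffix deletion
  rendered as a gap run, exercising the coverage rule; an exact per-class
  site count can be requested for recovery tests;
* 16 capture experiments sample binders at capture probability 0.6 with
  labelled contaminants admixed at 0.3 from a 200-protein singleton pool
  (binders and contaminants disjoint by construction);
* disease labels: a family is diseased with probability 0.91 and its members
  independently carry one of five classes with probability 0.7 (≥1 forced),
  mirroring the observed family-level disease association rate.

A separate deterministic constructive generator
(`synthetic_reference.build_reference_fixture`) encodes the *composition* of
the published supplementary tables — gene-list overlap structure, the
139-family/525-member standards layout, the 564→538-family capture/exclusion
structure, site counts and −2-serine placements, disease label layout — so
that the pipeline can recompute every headline count from realistic inputs
without redistributing the original spreadsheets. It is synthetic: all
identifiers and sequences are invented, and only the counted structure is
faithful.

## Problem sizes used in checks

Recovery checks run at: 200 families for the size-class distribution (3
binomial-SE band), 100 noise-free families for exact 3-state conservation
recovery (40/30/30 planted classes), 216 foreground sites against a
500-window background pool with 999 resamples for the −2-serine enrichment
(p ≤ 0.05), and full-scale (20 244-gene) simulation in the acceptance
script. These sizes were chosen to make binomial bands tight enough to be
meaningful while keeping the whole suite fast on one CPU.

## Known limitations

* Family assembly trusts the pair lists; no phylogenetic or synteny
  validation is performed, and 5+ components are flagged rather than
  resolved.
* The motif grammar stops at consensus flags; kinase-specificity prediction
  is out of scope.
* The lynchpin rule is strict (all members): a site divergent in one
  vertebrate member but conserved elsewhere is `divergent`, with no
  majority-rule option beyond the documented flags.
* The generator's substitution-only model cannot probe sensitivity to indels
  or alignment error.
* Disease annotation consumes prepared class tables; no ontology mapping.
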