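# Methods

This note documents the models, rules and numerical choices behind
`rnacensus`, and what the simulator does and does not emulate.

## Taxonomic assignment

The taxonomy is a rooted parent-pointer forest collapsed to a single
root; both the pipe-delimited NCBI dump dialect (`nodes.dmp`/`names.dmp`)
and a simplified headered TSV (`taxon_id, parent_id, rank, name`) are
accepted, auto-detected by delimiter. Assignment walks the parent chain
of a (merge-mapped) taxon id:

* **domain** — the unique configured domain node on the chain, else
  `UNASSIGNED`;
* **division** — for Archaea/Bacteria, the chain node immediately below
  the domain node (its "top-level classification"), with merge rules
  applied (so annotations under Thaumarchaeota can be binned with
  Crenarchaeota); for Eukaryota, the nearest supergroup-tagged ancestor
  (an Adl-style top-group map shipped as an overridable default config);
  for Viruses, the constant `Viruses`.

Merges are restricted to a single hop (no chained merges), making
assignment idempotent. Unknown or retired taxon ids degrade to
`UNASSIGNED` with a log line rather than aborting a multi-million-row
run; unassigned counts appear in the pipeline manifest. Taxa resolving
above division level (e.g. "uncultured bacterium") get
`division = UNASSIGNED` and are excluded from division-occupancy
numerators and denominators.

Viruses are carried as a fourth top-level set throughout, never called a
domain of life: interdomain counts and discovery-curve classes use the
three cellular domains only.

## Vetting

Only families whose annotations span more than one set (viruses
included) are filtered — single-domain families cannot gain a spurious
interdomain call, and this mirrors how such surveys are actually vetted.
Two rules apply, in order:

1. records with `evidence = MISANNOTATED` (an upstream taxonomic
   re-check, e.g. reciprocal BLAST catching vector contamination) are
   dropped;
2. records with bitscore `b < cutoff + margin` (default margin 10 bits)
   are *marginal* and dropped unless `evidence = CONFIRMED`.

Boundary semantics: "within +10 bits" is read as the half-open interval
`[cutoff, cutoff + 10)`; a score exactly at `cutoff + 10` is confident.
Strictness has to be fixed somewhere; this choice is pinned by tests.
Scores below the cutoff itself (absent from well-formed exports) fall
under the same predicate rather than a special case. A `vet_all` switch
extends filtering to all families. Vetting is idempotent and monotone:
raising the margin never keeps more records, and a kept record's
higher-scoring duplicate is always kept.

Vetting operates at family level; a clan whose *member families* are
each single-domain is not vetted even if the clan as a whole spans
domains, since each member's evidence is domain-consistent.

## Census

The presence matrix stores support counts (annotations behind each cell)
with `present == support > 0`. Clan-level accounting replaces member
families by their clan (presence = OR over members), preventing double
counting when clans and families are mixed in one total; families
without a clan stay as themselves. Units like the eukaryotic 5.8S rRNA,
whose domain-specific appearance is a curation artefact, can be removed
via an exclusion list in the pipeline config rather than hard-coded.

* **Venn partition** — each unit with non-empty presence belongs to
  exactly one of the 15 non-empty subsets of {A, B, E, V}; empty-presence
  units are tallied separately. Conservation (regions sum to non-empty
  units) is property-tested on random matrices.
* **Broad distribution** — `broad ⇔ divisions_present / divisions_total ≥ θ`
  with θ = 0.5 and an inclusive boundary ("at least 50 %"). The
  denominator is every division the taxonomy supplies for the domain,
  occupied or not: the comparison is against what is *known* of the
  domain, not what happens to be annotated. Rates are reported over
  units with ≥1 division presence, as percentages rounded **half-up** to
  one decimal — the convention under which 13/69, 15/223 and 20/826
  print as 18.8 %, 6.7 % and 2.4 %.
* **Normalized taxonomic abundance** — the fraction of a group's sampled
  taxa carrying ≥1 annotation of a unit. The denominator is an explicit
  per-group roster of sampled taxa supplied by the caller, keeping the
  normalisation auditable instead of conflating annotation density with
  sampling density.

## Dollo character mapping

Each family is a binary character on a rooted species tree (newick via
dendropy; unrooted inputs are rejected unless explicitly forced, because
rooting moves MRCAs and should never be guessed). Under Dollo parsimony
the reconstruction is closed-form: gain at the MRCA of present tips;
losses = maximal absent subtrees below the gain; a polytomy's absent
children each count one loss. The MRCA placement is loss-minimal — any
higher gain only adds absent subtrees, and no lower node covers the
presence set — and the implementation is verified against an exhaustive
brute-force minimiser over all gain placements on every rooted binary
shape up to 6 tips and random shapes to 10 tips.

Candidate nomination: a unit is consistent with vertical inheritance
from the domain ancestor when its gain maps to the domain root, or when
its presence touches ≥ 50 % of the root's immediate child clades
(`clade_coverage`, default 0.5 — the tree-shaped analogue of the
division rule), optionally capped by `max_losses`. No published criterion
pins this rule down exactly; the defaults are one defensible reading and
both knobs are exposed. Note that with a bifurcating domain root the
coverage rule nominates any unit spanning both children; a stricter
coverage (or `max_losses`) is advisable on binary trees.

A Fitch-style alternative was considered and rejected for nomination:
the premise of the analysis is homology (single origin), which is
exactly Dollo's constraint.

## Discovery curves

A family's discovery date is `min(literature dates, record dates)`;
families with no date anywhere are excluded with a warning. Dates are
accepted at day granularity and binned by year. Classes are
1-/2-/3-domain by cellular-domain count; virus-only families carry no
class. Curves are cumulative and end at the dated class size by
construction, which the tests assert.

## Simulator

The simulator emulates the statistical structure such a survey assumes,
with every parameter explicit (`SimulationParams` defaults in
parentheses):

* **Tree/taxonomy** — three domains, `divisions_per_domain` (6) divisions
  each, `taxa_per_division` (8) taxa per division; polytomies at the root
  and domain nodes, a caterpillar within each division (so Dollo cases
  are non-trivial); `n_viral_taxa` (8) viral taxa outside the tree. The
  emitted taxonomy, config, newick, and tables are exactly the dialects
  the pipeline reads.
* **Family classes** — `class_mix` (0.8/0.1/0.1) over DOMAIN_SPECIFIC
  (gain at a domain root with probability `broad_gain_prob` = 0.5, else
  at a division), LUCA_VERTICAL (gain at the root), and HGT_INTERDOMAIN
  (gain at a division, then `1 + Poisson(hgt_rate)` cross-domain
  transfers; the class is defined by having transferred at least once,
  so `hgt_rate` (0.5) is the expected number of *additional* transfers).
  Class counts follow the mix deterministically (largest remainder),
  then labels are shuffled.
* **Losses** — below each gain (and each transfer's recipient clade),
  every branch is pruned whole with probability `loss_prob` (0.1); a
  clade losing everything is rescued with one surviving tip, since an
  extinct family generates no data.
* **Sampling bias** — per-domain division weights are Dirichlet with
  concentration `1/(1 + sampling_bias)` (uniform at bias 0); a present
  taxon is detected with probability `detect_prob · w · n_div` (capped at
  1) and contributes `1 + Poisson(annotation_rate · w · n_div)`
  annotations. Larger bias concentrates annotations into few divisions,
  which measurably suppresses broad-distribution calls — the Fig-S2-style
  skew.
* **Bitscores** — per-family cutoffs uniform on 25–55 bits; true hits
  score `cutoff + 10 + Exp(15)`, i.e. never marginal; false positives
  (per family with probability `fp_rate` = 0.2) land uniformly in the
  marginal window `[cutoff, cutoff + 10)` of a domain the family does not
  occupy, 25 % of them tagged MISANNOTATED, the rest UNTESTED. The margin
  filter is therefore perfectly separating at default noise; overlapping
  mixtures are available by changing `BitscoreModel`.
* **Dates** — one literature date per family (1985–2008), record dates
  on 80 % of annotations from up to five years before the literature
  date.

Everything is driven by one `numpy` generator seeded from `seed`:
identical parameters give byte-identical output files.

What the simulator does **not** emulate: sequence-level evolution and
covariance-model scoring (bitscores are drawn, not computed), clan
structure, within-division phylogenetic correlation of sampling, rRNA
under-annotation, or taxonomy churn (stale taxon ids). Passing tests
therefore demonstrate that the pipeline's bookkeeping, filters and
reconstructions are correct under the stated model — not that the model
captures every pathology of real annotation databases.

## Problem sizes and determinism

Default test and acceptance runs use 60 families on a 144-tip tree
(~4 000 annotations), 20-seed replicate batches for recovery checks, an
exhaustive Dollo sweep of all 1 069 rooted binary shapes on ≤6 tips plus
100 random shapes on 7–10 tips (~110 000 reconstructions), and 1 000
random Venn matrices — sizes at which every property is checked
exhaustively or with ample replication while the whole suite stays
interactive. All randomness flows through explicit seeds; the pipeline
manifest records input hashes, seed and version so a run can be
reproduced byte-for-byte (timestamps are deliberately absent from all
outputs).

## Known limitations

* Eukaryote supergroup resolution depends entirely on the supplied
  supergroup map; taxa whose lineage never hits a tagged node stay
  `UNASSIGNED` at division level.
* Headline fractions from real Rfam/EMBL snapshots depend on curation
  decisions (clan rosters, rRNA coverage) that are inputs here, not
  computations; the package reproduces the arithmetic and the machinery,
  not the snapshot.
* `broad_distribution_rate` requires single-domain call lists; comparing
  across domains with different division counts is the caller's
  responsibility.
* Dollo mapping assumes the tip-to-taxon map is 1:1 per taxon id; multiple
  tips per taxon are all marked present if the taxon is annotated.
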