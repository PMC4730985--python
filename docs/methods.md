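# Methods

## Taxonomic binning

A taxonomy is a rooted tree of nodes (id, parent, rank, name); the root is a
node that is its own parent (NCBI taxdump convention) or carries a null
parent sentinel. Loading validates single-rootedness, resolvable parents and
acyclicity, and precomputes depths. Two dialects are read: a 4-column TSV and
NCBI `nodes.dmp`/`names.dmp` (scientific names only). Merged/deleted-node
files are not consulted; unknown ids are errors, which keeps the contract
strict and testable.

The LCA of a taxon set is computed by pairwise depth-equalised climbing: the
deeper node walks up to the shallower one's depth, then both walk up in
lockstep. The test suite checks this against an independent brute-force
oracle (positional intersection of full root-to-leaf lineages) on 1,000
random taxon sets over random trees. "Most specific" means deepest node, not
most specific *rank*: unranked nodes are legitimate assignments, since
conservative binning of conflicting hits routinely lands on internal,
sometimes unranked, nodes.

### Hit filtering and assignment

Hits are 12-column tabular alignments. Per query:

1. multiple HSPs to one subject collapse to that subject's best bit score
   (the assignment rule is per hit taxon; duplicate subjects add nothing);
2. hits must score strictly above the absolute threshold (default 50) and
   strictly above `window_fraction` (default 0.9) × the best hit's score.
   Both thresholds are configurable. At `window_fraction = 1` the strict
   window inequality would discard even the best hit, so the maximum-scoring
   hit is always retained once it clears the absolute threshold; for any
   fraction < 1 this is identical to the literal rule.
3. **lca mode** assigns the LCA of the distinct retained-hit taxa; **best_hit
   mode** assigns the unique top-scoring hit's taxon, with ties collapsing to
   the LCA of the tied taxa (never first-occurrence, which would depend on
   file order).

Subjects missing from the cross-reference are skipped with a debug log by
default (`missing_subject="error"` raises): such cross-references are
routinely incomplete in practice, and silently erroring out on one orphan hit
would discard the query's remaining evidence. A query with no usable hits is
`UNASSIGNED`.

Function assignment deliberately does **not** use an LCA-style consensus: the
function set of the best-scoring hit above the absolute threshold is taken,
falling back to the next best hit when the best is unannotated. Consensus
rules are only defined for hierarchies, and the functional hierarchy is
handled at the rollup stage instead.

## Functional hierarchy and rollup

The ontology maps function ids to one or more (level1, level2, level3)
category paths; duplicate identical paths collapse. When counts are
summarised at a level, the category identity is the label at that level and
the deduplication key is (function, label): a function whose two paths share
a level-1 parent contributes its count once there, while a function under two
distinct parents contributes to both. This is the only reading that prevents
double counting while preserving genuine multi-category membership. The same
rule is applied uniformly at levels 1–3; at level 3 path labels are
effectively unique per function, so deduplication is a no-op there in
practice. Functions absent from the ontology accumulate under a reserved
`unclassified` category so totals stay conserved.

Exclusion lists (e.g. dropping the "Retron-type reverse transcriptase" role,
a known rRNA misannotation sink) match function ids, or names when an
ontology is supplied, case-sensitively; removed counts also leave the
annotated-read denominator.

## Normalization and RNA/DNA statistics

* **Relative abundance** = 100 × count / annotated reads; **CPM** = 1e6 ×
  count / annotated reads. The denominator is the dataset's *annotated* read
  total, never the sequenced total; reads mapped to unannotated ORFs are
  tracked separately and exposed (`CountTable.unannotated`), so the
  denominator policy is auditable.
* **Subsampling** draws exactly `depth` reads without replacement
  (multivariate hypergeometric via `numpy.random.Generator`), reproducible
  per seed; the comparison depth defaults to the smallest dataset total and
  is echoed in output metadata.
* **Expressed fraction** per category: among functions with ≥1 DNA read in
  the category, the share with ≥1 RNA read. The numerator is the
  RNA∩DNA intersection, so it is a subset of the denominator by
  construction; RNA-only functions never enter the ratio. Categories with no
  DNA-detected functions are reported as undefined (NaN), not 0. Percentages
  print at whole-percent, half-up rounding; full precision is kept
  internally.
* **Overlap statistics**: |RNA∩DNA|/|DNA| (share of genetic potential that
  is expressed) and |RNA∩DNA|/|RNA| (share of transcripts confirmed in the
  metagenome).
* **Crosstabs** apply the deduplicated rollup within each taxon row;
  UNASSIGNED queries are excluded from the matrix and their read total
  reported alongside.

Detection is presence/absence at ≥1 read. No differential-expression or
significance testing across datasets is attempted.

## Synthetic communities

The generator emits exactly the dialects the pipeline reads, plus truth
tables and a parameter-echoing metadata JSON. All randomness derives from one
master seed split per component with `numpy.random.SeedSequence`.

* **Taxonomy**: leaves all at the requested depth; intermediate level sizes
  grow geometrically, parents assigned round-robin over a random permutation
  so every internal node has children. Ranks follow the canonical
  domain→species ladder.
* **Catalog**: each gene gets one uniformly drawn leaf taxon and one
  function; functions are spread evenly over level-1 categories, and a
  configurable fraction receive a second membership path to exercise the
  deduplication rule.
* **Hit tables**: one true hit per query at `score_base + N(0, sd)`; each of
  `n_decoy_slots` (default 3) decoy slots fires with probability
  `offtarget_prob` and hits a random gene whose taxon lies within a
  configurable radius of the truth (an integer number of levels up, or a
  named rank), at a penalised score. The radius gives a controllable LCA
  "blur": decoys inside the score window drag assignments up to—but never
  past—the radius ancestor.
* **Counts**: DNA reads are multinomial over genes weighted by taxon
  abundance (split evenly within a taxon); expression is a Bernoulli(f)
  indicator with f set per level-1 category. The indicator is attached to
  the *function* (shared by all its member genes) rather than the gene:
  the expressed-fraction statistic counts functions, and per-gene indicators
  under multi-gene functions would shift the estimand above f. The two
  choices coincide in the common 1-gene-per-function configuration. RNA
  reads are multinomial over expressed genes, weighted by abundance × a
  per-taxon activity multiplier (emulating taxa over-represented in RNA
  relative to DNA).

What the generator does **not** emulate: sequence content (no reads or
proteins are emitted), alignment score distributions conditioned on identity,
mapping ambiguity, assembly chimerism, or rRNA contamination. Passing
recovery tests therefore validates the binning/rollup/statistics logic under
the stated noise model, not the upstream alignment machinery.

### Study sizes

The bundled recovery studies use: taxonomic recovery — 100 leaves at depth 7,
10,000 single-query genes, decoys confined within the genus at 0.7
probability per slot; expression recovery — 6 level-1 categories × 500
single-gene functions, DNA depth 60,000 reads (~20× per gene, so essentially
every function is DNA-detected, ≥200 per category guaranteed), RNA depth
30,000, f = 0.30, 100 replicates. At ~500 detected functions per category the
binomial standard error of the estimate is ~2.0 points, so a ±5-point band
captures ≈98–99% of per-category replicates.

## Numerical and design choices

* Both filter inequalities are strict, matching the thresholds' usual "more
  than" phrasing; the equality carve-out for the best hit exists only at
  `window_fraction = 1`.
* Whole-percent rounding is half-up (`floor(x + 0.5)`), not banker's
  rounding, to match the conventional presentation of expressed-fraction
  tables.
* Ranking ties (top-N) break lexicographically by key; function-assignment
  score ties break by subject id — both keep outputs stable across runs and
  platforms.
* TSV outputs carry a `#`-prefixed metadata block (thresholds, mode, seed,
  depth, version) so runs diff cleanly and every parameter affecting output
  is recorded; the manifest JSON echoes the full effective configuration.
* Degenerate inputs: empty hit groups are valid (UNASSIGNED); zero-total
  tables reject normalization with an argument error; depth outside
  [0, total] rejects subsampling; an empty taxon set rejects the LCA.

## Known limitations

* The rollup keys categories by label at the requested level; if the same
  level-2 label appeared under two different level-1 parents it would be
  treated as one category.
* `read_tabular_hits` materialises groups in memory; hit tables far beyond
  ~10⁷ rows would need a streaming grouper.
* The CLI's compare/pair-stats consume ORF-level count TSVs plus the subject
  metadata; BAM/SAM mapping output is out of scope (counts are consumed, not
  computed from alignments).
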