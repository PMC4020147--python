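# Methods

## Data model and token dialect

Haplotypes are difference lists against the rCRS (positions 1–16569,
1-based inclusive). The parser accepts the spellings that occur in real
submission tables: ref-prefixed (`A263G`) and bare (`263G`) substitutions,
IUPAC ambiguity codes as derived states for point heteroplasmy (`16214S`),
indexed insertions (`315.1C`, `309.2C`), and deletions written `16038DEL`,
`16038del`, `16038-` or `A16038-`. Parsing is case-insensitive and strips
whitespace inside numbers (`16 038`). The canonical formatter is the exact
inverse of the parser (`parse(format(v)) == v`, property-tested). No
re-alignment is performed anywhere: tokens are taken at the submitter's
alignment, because the C-tract convention check is supposed to *flag*
misalignment, not silently repair it.

Sequenced ranges are interval lists; an interval written start > end (the
control-region wrap `16024-576`) is split at the 16569/1 origin.

A FASTA reference is optional. Without one, per-position reference letters
are inferred from the consensus of ref-prefixed tokens across the table
(substitutions and deletions vote; ambiguous votes resolve to unknown).

## Plausibility checks

Five checks run per haplotype, in fixed order (range, reference bias,
double specification, indel notation, C-tract convention), with findings
ordered by sample, then check, then position — two runs on the same table
are byte-identical. The first four are `error` severity. The C-tract check
is a `warning` because only raw electropherograms can confirm it; its two
triggers are the concrete signals of 3′-convention violation: `C311T`
present without `315.1C`, and any HVS-2 insertion anchored between 303 and
315 at a position other than 309 or 315. No broader realignment engine is
attempted. Structurally broken indel tokens (`315.1`, `315.C`, `16038G-`)
are kept out of the parsed variant list but retained as raw tokens so the
notation check can name them; a token that is malformed in any other way is
a load error with its line number.

An insertion is a range violation iff its anchor position is uncovered —
the simplest defensible convention for a one-position anchor.

## Filter passage and reduction

Mutation-mode filters match position + kind + derived state (insertions
also by index); the reference letter is ignored for matching, so `263G` and
`A263G` are the same entry. Position-mode filters remove everything at a
listed position. By default a filter entry `A366G` does **not** remove the
heteroplasmic `366R`; with `match_iupac` (CLI `--match-iupac`) it does,
since `R` covers `G`. Exact matching is the default because a heteroplasmy
at a documented position is still an observation worth seeing in the
network.

Characters are built per substitution position, per (position, insertion
index), and per deletion position; insertions and deletions are
presence/absence characters. The baseline (non-carrier) state is the
reference letter where known — from the FASTA or the token consensus —
otherwise an explicit unknown-reference placeholder (`?`). Non-carriers are
never assigned the majority *derived* state: all non-carriers share the
(single, definite) rCRS state at that position by the definition of
difference coding, and conflating them with the commonest carrier state
would erase a real state distinction. Transitions against an unknown
baseline display as bare tokens (`320T`).

Samples whose range does not cover a character's position receive the
baseline state and a warning is logged; quasi-median closure over a
missing-data alphabet is not defined, and submission data sets share
common ranges in practice, so this affects planted range violations more
than ordinary columns. Constant characters are dropped.

Condensation merges characters that induce the identical partition of
samples into state classes (label-free comparison); the merged character's
weight is its member count, and its branch labels join the member
transitions with `+`, each oriented baseline → derived for display.
Identical reduced rows collapse into one row carrying all sample ids.

## Quasi-median closure and the network

The triple operation is implemented exactly as defined (per-character
majority, all three states when pairwise distinct; Cartesian product).
Closure runs as a worklist over triples containing at least one
newly-added vector; because set closure is order-independent, this is
equivalent to the naive all-triples fixpoint, which is kept as an
independent oracle in the test suite and the acceptance script (100 random
instances per run, ≤ 8 vectors, ≤ 6 characters, ≤ 4 states; instances are
capped at a 160-vector product bound to keep the cubic oracle tractable on
one CPU).

The hull can grow exponentially in the number of conflicting characters,
which is the scientific point — unfiltered recurrent mutations make
networks unreadable — so closure aborts above a node cap (default 20 000)
with an error naming the most state-rich condensed characters as filter
candidates, rather than producing an unusable graph.

Nodes are the hull vectors: `h1…hn` for sampled rows in first-appearance
order, `q1…` for virtual (closure-only) vectors in lexicographic order.
Edges connect vectors differing in exactly one condensed character, found
by bucketing vectors on the remaining coordinates (linear in hull size per
character). Edges sharing (character, state pair) form a parallel class.
Multi-state characters produce cliques among their states where they
conflict; edges are undirected and never oriented ancestrally.

"Torso" here means the post-filter network itself (default). An optional
`pruned` mode iteratively strips degree-1 *virtual* nodes — sampled
pendants always stay; both behaviors are exposed by name since usage of the
term varies.

Selection mirrors the interactive operations as batch operations: node
selection accentuates the node, incident edges and their far endpoints;
branch selection accentuates a parallel class and all endpoints; everything
else is dimmed. The map covers every element exactly once.

## Layout and export

Each condensed character *c* gets a fixed unit direction (angles evenly
spaced over the half-circle in character order) and each of its states an
integer offset; a node sits at the offset-weighted sum of directions.
Branch length scales with condensed weight by default. Parallel edges have
identical displacement *by construction* — the acceptance check verifies
agreement to 1e-9 canvas units. Overlap nudging is off by default because
moving node centres would trade exact parallelism for cosmetics; when
enabled it applies a deterministic perpendicular micro-offset in node-id
order to exactly coincident centres only, and never rotates character
directions.

SVG output is standalone SVG 1.1 with fixed 3-decimal coordinate
formatting, element ids equal to node/edge ids, node radius growing with
the square root of the haplotype count (switchable), and dimming via an
opacity attribute (default 0.25). Identical inputs give byte-identical
files. GraphML goes through networkx and round-trips nodes, edges, labels
and parallel classes; DOT is plain text for graph tooling; the JSON dump is
the lossless persistence format and is sufficient to re-render.

## Synthetic data generator

The generator emulates the *tabular consequences* of the documented error
modes, not their raw-signal causes. A table is a set of backbone lineages
(each a distinct set of "documented" variants drawn from a reserved
position pool, samples assigned round-robin), and the emitted filter list
contains exactly the backbone — so the post-filter network is fully
predicted by the planted extras. Plants cover: phantom mutations with a
given carrier count guaranteed to span ≥ 2 lineages; single-sample range
violations, reference-bias tokens, duplicated tokens and broken indel
notations; C-tract misreporting (`C311T` without `315.1C`); and
high-frequency deletions. Carriers are drawn from a seed-shuffled
without-replacement queue, so overlap between plants occurs exactly when
counts force it. The truth log records every expected QC finding and the
expected node membership groups (excluding tokens that cannot distinguish a
node: filtered, reference-restating, or unparseable ones).

Presets: `fig1b` (201 samples, five private novelties → six-node star,
one of them the heteroplasmic `16214S`), `datasetA_like` (320 samples,
`A366G` in 18 carriers of which 17 reduce identically, plus a `320T/320G`
phantom pair), `datasetB_like` (230 samples, a 173-carrier deletion at
16038 ≈ 75% and 106 samples ≈ 46% reporting `C311T` without `315.1C`).
These mirror the narrative scenarios of submission QC at realistic sample
sizes; they are synthetic stand-ins, not reproductions of any confidential
data set. What passing tests show is that the pipeline's structural laws
hold and that planted signals are recovered exactly; they cannot show
recovery of any real data set's content.

`conflict_quartet(k)` builds 2^k samples realizing all combinations of k
pairwise-incompatible binary characters — the closure stress input with a
known answer (2^k nodes, k·2^(k−1) edges).

## Numerical and degenerate-input choices

* Zero characters (everything filtered) → a single sampled node holding all
  samples; closure of a singleton is itself.
* Closure of an empty set is rejected; a node cap below the sampled row
  count raises the same explosion error as hull growth.
* Determinism everywhere: sorted iteration orders, fixed finding order,
  fixed float formatting, one seeded PRNG in the generator.
* Edge state pairs are stored sorted; display labels re-orient
  baseline → derived, so `A366G` never prints as `G366A`.

## Limitations

* No electropherogram or raw-lane analysis; flagged haplotypes are never
  auto-corrected.
* No median-joining/reduced-median construction, no haplogroup estimation,
  no frequency estimation.
* Missing data inside a character column is approximated by the baseline
  state (with a warning) rather than a dedicated missing symbol.
* GIF/EPS are not produced; SVG is the vector source of truth and converts
  externally.
* The TSV table dialect is this package's own documented format; it does
  not claim byte compatibility with any database's internal submission
  format.
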