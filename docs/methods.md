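# Methods

## The procedure

`nemadesc` generates one summary paragraph per gene from structured
annotations, in five stages: parse → bundle → build → gate → realize.
Every stage is deterministic; two runs on identical inputs produce
byte-identical txt/json/tsv outputs.

**Statement building.** Each annotation category yields at most one
intermediate `Statement` per gene (exceptions: GO statements, one per
(aspect, qualifier, evidence-class) group; human-ortholog function
transfer, one per template variant per selected ortholog). A statement
carries an ordered item list, the total count behind it, and qualifiers
(study types, ortholog symbol, source species). Item order is
first-seen input order throughout; duplicates are removed keeping the
first occurrence. No statement is ever emitted with an empty item list.

**GO phrasing.** Annotations whose evidence code is in the predicted
set {IEA, ISS, ISO, IBA, RCA} render as "Predicted to enable …" /
"Predicted to be involved in …"; all other codes render as "Enables …" /
"Is involved in …". The set is a parameter of `build_go_statements`;
the default partition follows the GO evidence-code taxonomy's
electronic/sequence-inference group. `contributes_to` annotations
render "Contributes to …" regardless of evidence class. Negated
(`NOT|…`) GAF qualifiers are dropped at parse time: a negative
annotation cannot support a positive summary sentence.

**Ortholog selection.** For *C. elegans* subjects, *all* human
orthologs attaining the maximal prediction-method count are kept and
their disease annotations merged (deduplicated union), with function
statements built per ortholog — ties are rare but must not be resolved
arbitrarily. For other species, exactly one nematode ortholog is chosen
by (method count, GO-annotation count) in lexicographic descending
order. Remaining ties break deterministically: *C. elegans* before all
other species, then species tag, then ortholog symbol, then gene id.
The symbol/id tie-breaks are engine choices made purely for
determinism; they carry no biological meaning.

**Transferred-function special case.** A transferred molecular-function
term whose name begins with "structural constituent" is rendered as a
standalone noun phrase ("A structural constituent of postsynaptic actin
cytoskeleton.") instead of joining the "enables" list; this matches the
production summaries' surface form for structural-constituent terms,
which read badly inside an "enables" conjunction.

**Gating.** Two profiles ship. Both block ortholog disease/function
transfer when the gene has any curated GO annotation (any aspect, any
evidence code). `strict` additionally blocks large-scale and domain
statements when either GO or curated expression data are present;
`ws292` (the default) blocks those only on GO presence, which is the
behavior production summaries exhibit (a gene with curated expression
still receives its domain sentence). "Expression data" here means
curated anatomy-ontology annotations only — large-scale
expression-enrichment records do not count, otherwise strategy-2
statements would block themselves. Categories derived from the gene's
own curated annotations (GO, curated expression) and the
orthology/process-transfer sentences are never gated. Gating is a pure
filter: it never reorders or rewrites statements.

**Realization.** Lists render as "a" / "a and b" / "a; b; and c".
Truncating categories (ortholog disease, ortholog function transfer,
gene regulation, chemical regulation) show at most `exemplar_count`
(default 3) exemplars in item order; the prefix is the spelled-out
count word below `several_threshold` (default 10) and "several" at or
above it. The threshold default is an engine choice consistent with
both observed surface forms (an exact word at seven, "several" for
larger unstated counts); it is configurable per run. Whether
"including" takes a preceding comma is a per-template flag
(`ortholog_disease` and `human_enables` do; the regulation templates do
not) — the flags encode observed usage without interpreting it.
Sentences are ordered by a fixed category order (GO function/process/
component, curated expression, ortholog disease, ortholog function
transfer, the three large-scale categories, domains, orthology, process
transfer), stable within a category, and joined with single spaces.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `profile` | `ws292` | gating rule set (see above) |
| `exemplar_count` | 3 | exemplars shown for truncated lists |
| `several_threshold` | 10 | counts ≥ this render "several"; below it, the count word |
| predicted evidence codes | IEA, ISS, ISO, IBA, RCA | "Predicted to …" phrasing |
| `category_order` | fixed list above | sentence order in the paragraph |

## Input handling and numerical choices

The OBO reader honors only `id`/`name`/`namespace`/`is_a` (other tags
are ignored with a warning; `relationship:` semantics are out of
scope), validates that the `is_a` graph is acyclic and that every
parent resolves, and is built on obonet/networkx. GAF 2.2 rows must
have exactly 17 columns; rows referencing terms absent from the loaded
ontology, or whose aspect letter contradicts the term's namespace, are
dropped with a logged warning and counted on the returned list's
`dropped` attribute rather than aborting the run. A missing GAF
qualifier defaults by aspect (F→enables, P→involved_in, C→located_in).
All identifiers are whitespace-trimmed and case-sensitive. TSV tables
are read via pandas with exact header checks; duplicate rows are
dropped. Annotations whose gene id matches no gene record are indexed
anyway (ortholog genes are looked up without being subject genes) but
reported as dangling references in the bundle and run log.

Count words cover 1–999, hyphenated tens ("twenty-one"), no "and"
("one hundred fifteen"); out-of-range counts raise. `realize_list`
refuses empty lists — builders guarantee non-empty items, so an empty
list reaching realization is a bug, not data.

## What the fixtures emulate — and what they do not

The four named fixtures are minimal reconstructions of the annotation
state behind four known production summaries (act-3, fem-2, abt-3,
Cjp-gid-1): each contains exactly the records needed to drive one path
through the engine, with filler entries (`disease-4`, `function-4
activity`, `gene-4`, `chemical-4`, …) in just the quantities that
trigger the truncated surface forms ("several diseases", "several
functions", "several genes", "seven chemicals"). They are frozen by
checksum. The seeded random bundles exercise every record category and
invariant at small scale. Neither emulates a real database release:
real annotation sets are orders of magnitude larger, have deep ontology
structure (the engine does no ancestor propagation or term trimming —
exemplar choice is order-based, not graph-based), and contain
inconsistencies the fixtures lack. Passing tests therefore demonstrate
rule correctness and determinism, not whole-release statistics;
database-wide summary counts are explicitly out of scope, though the
run manifest reports the same per-category count structure at run
scale.

## Known limitations

- No ontology-closure reasoning: annotations to descendant terms are
  not propagated or collapsed to informative ancestors.
- Fixed English templates only; no grammatical agreement beyond them.
- The orthology and large-scale tables are trusted inputs; the engine
  does not recompute orthology predictions or enrichment statistics.
- Disease statements are gated together with function-transfer
  statements (both fall under the GO-presence rule); a deployment that
  always shows disease implications would need a third profile.
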