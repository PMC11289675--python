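# nemadesc

Rule-based automated gene summaries for *Caenorhabditis* and other
nematode species.

Model-organism databases annotate genes with structured, controlled
vocabularies — Gene Ontology (GO) terms with evidence codes, Disease
Ontology terms via human orthologs, anatomy-ontology expression
annotations, orthology calls supported by multiple prediction methods,
collated microarray / tiling-array / RNA-seq results, and InterPro
protein domains. Reading those annotations requires familiarity with
each vocabulary; a short English paragraph does not. `nemadesc` turns a
bundle of such annotations into one deterministic summary paragraph per
gene, aimed at genes that *lack* curated functional annotation, using
three strategies:

1. **Orthology transfer.** For a *C. elegans* gene, the human orthologs
   supported by the most prediction methods contribute their disease
   implications and molecular activities ("Human ortholog(s) of this
   gene implicated in …", "Human ACTB enables …"). For the other nine
   nematode species, a single best ortholog — ranked by prediction-method
   count, then by its number of GO annotations — contributes its
   biological processes ("In C. elegans, fem-2 is involved in …").
2. **Large-scale data.** Collated high-throughput records yield
   expression-enrichment, gene-regulation and chemical-regulation
   sentences ("Is affected by seven chemicals including …").
3. **Protein domains.** InterPro domain annotations yield "Is predicted
   to encode a protein with the following domains: …".

Transferred and large-scale statements are *gated*: they enter a
summary only when the gene has no curated GO (and, under the `strict`
profile, no curated expression) data of its own, so that auto-generated
content never crowds out direct curation. Long lists collapse to three
exemplars behind a spelled-out count ("seven chemicals including …") or
"several" once the count reaches a threshold (default 10).

## Worked example

```sh
nemadesc fixtures --name fem2 --out demo
nemadesc generate --config demo/config.yaml
```

prints `genes: 1  summaries: 1` and writes `demo/out/summaries.txt`:

```
cbr-fem-2	fem-2
Predicted to enable protein serine/threonine phosphatase activity. Is an ortholog of C. elegans fem-2. In C. elegans, fem-2 is involved in male sex determination; masculinization of hermaphroditic germ-line; and nematode male tail tip morphogenesis.
```

Reading the paragraph back: the *C. briggsae* gene has a single
electronically inferred (IEA) GO molecular-function annotation, so the
first sentence is phrased "Predicted to enable …" rather than
"Enables …". Its best ortholog is *C. elegans* fem-2 (most prediction
methods among candidates), so the engine names the ortholog and
transfers that gene's three curated biological-process annotations into
the final sentence. A `manifest.json` sidecar records gene and summary
counts and per-category statement counts for the run
(`go_function: 1, orthology: 1, elegans_process_transfer: 1` here).

Packaged fixtures `act3`, `abt3` and `cjp_gid1` exercise the remaining
statement categories (curated expression, human-ortholog disease and
function transfer, the three large-scale sentence types, and protein
domains). `nemadesc fixtures --name all --out d` emits all four;
`nemadesc validate --config …` parses inputs and reports counts without
writing summaries.

## Inputs

A YAML config names the subject species, the gating profile and the
input files: a genes table (TSV), ontologies (minimal OBO: `[Term]`
stanzas with `id`, `name`, `namespace`, `is_a`), GO annotations
(GAF 2.2), and TSV tables for disease, curated anatomy expression,
orthology (with comma-separated prediction methods), large-scale
records and InterPro domains. See `nemadesc/pipeline.py` for the full
schema and `nemadesc/fixtures.py` for complete examples. Outputs are
txt, json and tsv, byte-identical across runs on identical inputs.

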