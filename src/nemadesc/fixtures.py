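"""Packaged input fixtures.

Four named fixtures emit complete, constant input file sets (mini OBO +
GAF + TSV tables + genes table + pipeline config) whose end-to-end output
under the default ``ws292`` gating profile reproduces one published
example summary each:

* ``act3``      — C. elegans act-3: curated expression, human-ortholog
                  disease/function transfer, domains, orthology.
* ``fem2``      — C. briggsae fem-2: one predicted GO function, ortholog
                  statement, process transfer from C. elegans.
* ``abt3``      — C. elegans abt-3: the three large-scale statements.
* ``cjp_gid1``  — C. japonica Cjp-gid-1: domains and orthology only.

Quantities that the published paragraphs imply but do not enumerate (the
diseases beyond the three printed exemplars, the extra transferred
functions, the regulator genes beyond the first three, the chemicals
beyond the first three) are filled with clearly synthetic names
(``disease-4``, ``function-4 activity``, ``gene-4``, ``chemical-4`` ...)
in just the numbers needed to trigger the printed surface forms
("several diseases", "several functions", "several genes", "seven
chemicals").

:func:`make_random_bundle` additionally builds seeded random annotation
bundles for property-based tests.
"""

from __future__ import annotations

import random
from pathlib import Path

from .data_model import (
    AnnotationBundle,
    DiseaseAnnotation,
    DomainRecord,
    ExpressionAnnotation,
    GeneRecord,
    GOAnnotation,
    LargeScaleRecord,
    Ontology,
    OntologyTerm,
    OrthologRecord,
    STUDY_TYPES,
    build_bundle,
)
from .errors import UnknownFixtureError

PAPER_FIXTURES = ("act3", "fem2", "abt3", "cjp_gid1")

#: fixture name -> (subject gene id, public name, expected paragraph)
EXPECTED_SUMMARIES: dict[str, tuple[str, str, str]] = {
    "act3": (
        "cel-act-3",
        "act-3",
        "Expressed in gonad and head. "
        "Human ortholog(s) of this gene implicated in several diseases, including "
        "Baraitser-Winter syndrome 1; Baraitser-Winter syndrome 2; and "
        "autosomal dominant nonsyndromic deafness 20. "
        "Human ACTB Contributes to nucleosomal DNA binding activity. "
        "Human ACTB enables several functions, including Tat protein binding activity; "
        "enzyme binding activity; and kinesin binding activity. "
        "A structural constituent of postsynaptic actin cytoskeleton. "
        "Is predicted to encode a protein with the following domains: Phosphorylation site; "
        "Actin; Actin family; and ATPase, nucleotide binding domain. "
        "Is an ortholog of human ACTB (actin beta).",
    ),
    "fem2": (
        "cbr-fem-2",
        "fem-2",
        "Predicted to enable protein serine/threonine phosphatase activity. "
        "Is an ortholog of C. elegans fem-2. "
        "In C. elegans, fem-2 is involved in male sex determination; "
        "masculinization of hermaphroditic germ-line; and "
        "nematode male tail tip morphogenesis.",
    ),
    "abt3": (
        "cel-abt-3",
        "abt-3",
        "Enriched in male based on RNA-seq studies. "
        "Is affected by several genes including eat-2; sir-2.1; and npr-1 based on "
        "RNA-seq; tiling array; and microarray studies. "
        "Is affected by seven chemicals including Tunicamycin; manganese chloride; and "
        "multi-walled carbon nanotube based on microarray and RNA-seq studies.",
    ),
    "cjp_gid1": (
        "cjp-gid-1",
        "Cjp-gid-1",
        "Is predicted to encode a protein with the following domains: SPRY domain; "
        "B30.2/SPRY domain superfamily; and Concanavalin A-like lectin/glucanase "
        "domain superfamily. "
        "Is an ortholog of C. elegans gid-1.",
    ),
}


def _obo(terms: list[tuple[str, str, str, list[str]]]) -> str:
    """Render (id, name, namespace, parents) tuples as a minimal OBO file."""
    chunks = ["format-version: 1.4\nontology: mini\n"]
    for term_id, name, namespace, parents in terms:
        stanza = [f"[Term]", f"id: {term_id}", f"name: {name}", f"namespace: {namespace}"]
        stanza += [f"is_a: {p}" for p in parents]
        chunks.append("\n".join(stanza) + "\n")
    return "\n".join(chunks)


def _gaf(rows: list[tuple[str, str, str, str, str, str]]) -> str:
    """Render (gene_id, symbol, qualifier, term, evidence, aspect) as GAF 2.2."""
    lines = ["!gaf-version: 2.2"]
    for gene_id, symbol, qualifier, term, evidence, aspect in rows:
        fields = [
            "FIX", gene_id, symbol, qualifier, term, "FIX:0000001", evidence,
            "", aspect, "", "", "gene", "taxon:6239", "20240101", "FIX", "", "",
        ]
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def _tsv(header: tuple[str, ...], rows: list[tuple[str, ...]]) -> str:
    lines = ["\t".join(header)]
    lines += ["\t".join(row) for row in rows]
    return "\n".join(lines) + "\n"


_MF_ROOT = ("GO:0000001", "molecular_function", "molecular_function", [])
_BP_ROOT = ("GO:0000002", "biological_process", "biological_process", [])
_CC_ROOT = ("GO:0000003", "cellular_component", "cellular_component", [])

_ACT3_ENABLES_PRINTED = (
    ("GO:0000011", "Tat protein binding activity"),
    ("GO:0000012", "enzyme binding activity"),
    ("GO:0000013", "kinesin binding activity"),
)
# synthetic filler functions 4..10 bring the enables total to ten, the
# point at which the rendering switches to "several functions"
_ACT3_ENABLES_FILLER = tuple(
    (f"GO:00000{13 + i}", f"function-{i + 3} activity") for i in range(1, 8)
)

_ACT3_DISEASES_PRINTED = (
    "Baraitser-Winter syndrome 1",
    "Baraitser-Winter syndrome 2",
    "autosomal dominant nonsyndromic deafness 20",
)
_ACT3_DISEASES_FILLER = tuple(f"disease-{i}" for i in range(4, 11))


def _act3_files() -> dict[str, str]:
    go_terms = [
        _MF_ROOT,
        ("GO:0000010", "nucleosomal DNA binding activity", "molecular_function", ["GO:0000001"]),
    ]
    for term_id, name in _ACT3_ENABLES_PRINTED + _ACT3_ENABLES_FILLER:
        go_terms.append((term_id, name, "molecular_function", ["GO:0000001"]))
    go_terms.append(
        ("GO:0000021", "structural constituent of postsynaptic actin cytoskeleton",
         "molecular_function", ["GO:0000001"])
    )

    gaf_rows = [("hsa-ACTB", "ACTB", "contributes_to", "GO:0000010", "IDA", "F")]
    gaf_rows += [
        ("hsa-ACTB", "ACTB", "enables", term_id, "IDA", "F")
        for term_id, _ in _ACT3_ENABLES_PRINTED + _ACT3_ENABLES_FILLER
    ]
    gaf_rows.append(("hsa-ACTB", "ACTB", "enables", "GO:0000021", "IDA", "F"))

    return {
        "genes.tsv": _tsv(
            ("gene_id", "public_name", "species"),
            [("cel-act-3", "act-3", "c_elegans"), ("hsa-ACTB", "ACTB", "human")],
        ),
        "mini-go.obo": _obo(go_terms),
        "annotations.gaf": _gaf(gaf_rows),
        "disease.tsv": _tsv(
            ("gene_id", "disease_term_name"),
            [("hsa-ACTB", d) for d in _ACT3_DISEASES_PRINTED + _ACT3_DISEASES_FILLER],
        ),
        "expression.tsv": _tsv(
            ("gene_id", "anatomy_term_name"),
            [("cel-act-3", "gonad"), ("cel-act-3", "head")],
        ),
        "orthology.tsv": _tsv(
            ("subject_gene_id", "subject_species", "ortholog_gene_id", "ortholog_symbol",
             "ortholog_full_name", "ortholog_species", "methods"),
            [
                ("cel-act-3", "c_elegans", "hsa-ACTB", "ACTB", "actin beta", "human",
                 "m1,m2,m3,m4,m5"),
                ("cel-act-3", "c_elegans", "hsa-POTEE", "POTEE",
                 "POTE ankyrin domain family member E", "human", "m1,m2"),
            ],
        ),
        "domains.tsv": _tsv(
            ("gene_id", "domain_name", "interpro_id"),
            [
                ("cel-act-3", "Phosphorylation site", "IPR-S001"),
                ("cel-act-3", "Actin", "IPR-S002"),
                ("cel-act-3", "Actin family", "IPR-S003"),
                ("cel-act-3", "ATPase, nucleotide binding domain", "IPR-S004"),
            ],
        ),
        "config.yaml": (
            "species: c_elegans\n"
            "profile: ws292\n"
            "inputs:\n"
            "  genes: genes.tsv\n"
            "  ontology: mini-go.obo\n"
            "  gaf: annotations.gaf\n"
            "  disease: disease.tsv\n"
            "  expression: expression.tsv\n"
            "  orthology: orthology.tsv\n"
            "  domains: domains.tsv\n"
            "out_dir: out\n"
            "formats: [txt, json, tsv]\n"
        ),
    }


def _fem2_files() -> dict[str, str]:
    go_terms = [
        _MF_ROOT,
        _BP_ROOT,
        ("GO:0000030", "protein serine/threonine phosphatase activity",
         "molecular_function", ["GO:0000001"]),
        ("GO:0000031", "male sex determination", "biological_process", ["GO:0000002"]),
        ("GO:0000032", "masculinization of hermaphroditic germ-line",
         "biological_process", ["GO:0000002"]),
        ("GO:0000033", "nematode male tail tip morphogenesis",
         "biological_process", ["GO:0000002"]),
    ]
    gaf_rows = [
        ("cbr-fem-2", "fem-2", "enables", "GO:0000030", "IEA", "F"),
        ("cel-fem-2", "fem-2", "involved_in", "GO:0000031", "IMP", "P"),
        ("cel-fem-2", "fem-2", "involved_in", "GO:0000032", "IMP", "P"),
        ("cel-fem-2", "fem-2", "involved_in", "GO:0000033", "IMP", "P"),
    ]
    return {
        "genes.tsv": _tsv(
            ("gene_id", "public_name", "species"),
            [("cbr-fem-2", "fem-2", "c_briggsae"), ("cel-fem-2", "fem-2", "c_elegans")],
        ),
        "mini-go.obo": _obo(go_terms),
        "annotations.gaf": _gaf(gaf_rows),
        "orthology.tsv": _tsv(
            ("subject_gene_id", "subject_species", "ortholog_gene_id", "ortholog_symbol",
             "ortholog_full_name", "ortholog_species", "methods"),
            [
                ("cbr-fem-2", "c_briggsae", "cel-fem-2", "fem-2", "", "c_elegans",
                 "m1,m2,m3,m4"),
                ("cbr-fem-2", "c_briggsae", "cre-fem-2", "fem-2", "", "c_remanei", "m1,m2"),
            ],
        ),
        "config.yaml": (
            "species: c_briggsae\n"
            "profile: ws292\n"
            "inputs:\n"
            "  genes: genes.tsv\n"
            "  ontology: mini-go.obo\n"
            "  gaf: annotations.gaf\n"
            "  orthology: orthology.tsv\n"
            "out_dir: out\n"
            "formats: [txt, json, tsv]\n"
        ),
    }


def _abt3_files() -> dict[str, str]:
    regulators = [
        ("eat-2", "RNA-seq,tiling array,microarray"),
        ("sir-2.1", "RNA-seq"),
        ("npr-1", "RNA-seq"),
    ] + [(f"gene-{i}", "microarray") for i in range(4, 11)]
    chemicals = [
        ("Tunicamycin", "microarray,RNA-seq"),
        ("manganese chloride", "microarray"),
        ("multi-walled carbon nanotube", "RNA-seq"),
    ] + [(f"chemical-{i}", "microarray") for i in range(4, 8)]

    rows = [("cel-abt-3", "expression_enrichment", "male", "RNA-seq")]
    rows += [("cel-abt-3", "gene_regulation", name, studies) for name, studies in regulators]
    rows += [("cel-abt-3", "chemical_regulation", name, studies) for name, studies in chemicals]
    return {
        "genes.tsv": _tsv(
            ("gene_id", "public_name", "species"), [("cel-abt-3", "abt-3", "c_elegans")]
        ),
        "large_scale.tsv": _tsv(("gene_id", "kind", "object_name", "study_types"), rows),
        "config.yaml": (
            "species: c_elegans\n"
            "profile: ws292\n"
            "inputs:\n"
            "  genes: genes.tsv\n"
            "  large_scale: large_scale.tsv\n"
            "out_dir: out\n"
            "formats: [txt, json, tsv]\n"
        ),
    }


def _cjp_gid1_files() -> dict[str, str]:
    return {
        "genes.tsv": _tsv(
            ("gene_id", "public_name", "species"),
            [("cjp-gid-1", "Cjp-gid-1", "c_japonica"), ("cel-gid-1", "gid-1", "c_elegans")],
        ),
        "domains.tsv": _tsv(
            ("gene_id", "domain_name", "interpro_id"),
            [
                ("cjp-gid-1", "SPRY domain", "IPR-S011"),
                ("cjp-gid-1", "B30.2/SPRY domain superfamily", "IPR-S012"),
                ("cjp-gid-1", "Concanavalin A-like lectin/glucanase domain superfamily",
                 "IPR-S013"),
            ],
        ),
        "orthology.tsv": _tsv(
            ("subject_gene_id", "subject_species", "ortholog_gene_id", "ortholog_symbol",
             "ortholog_full_name", "ortholog_species", "methods"),
            [("cjp-gid-1", "c_japonica", "cel-gid-1", "gid-1", "", "c_elegans", "m1,m2,m3")],
        ),
        "config.yaml": (
            "species: c_japonica\n"
            "profile: ws292\n"
            "inputs:\n"
            "  genes: genes.tsv\n"
            "  orthology: orthology.tsv\n"
            "  domains: domains.tsv\n"
            "out_dir: out\n"
            "formats: [txt, json, tsv]\n"
        ),
    }


_FIXTURE_BUILDERS = {
    "act3": _act3_files,
    "fem2": _fem2_files,
    "abt3": _abt3_files,
    "cjp_gid1": _cjp_gid1_files,
}


def paper_fixture_files(name: str) -> dict[str, str]:
    """The constant file contents of a named fixture (filename -> text)."""
    try:
        return _FIXTURE_BUILDERS[name]()
    except KeyError:
        raise UnknownFixtureError(name) from None


def make_paper_fixture(name: str, out_dir: str | Path) -> dict[str, Path]:
    """Write the named fixture's input files under *out_dir*.

    Returns filename -> written path; ``config.yaml`` is the entry point
    for :func:`nemadesc.pipeline.run_pipeline`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for filename, content in paper_fixture_files(name).items():
        path = out_dir / filename
        path.write_text(content, encoding="utf-8")
        written[filename] = path
    return written


# ---------------------------------------------------------------------------
# seeded random bundles for property-based tests

_RANDOM_SPECIES = ("c_elegans", "c_briggsae", "c_japonica", "c_remanei", "p_pacificus")
_EVIDENCE_CODES = ("IEA", "ISS", "IDA", "IMP", "EXP")


def _random_ontology(rng: random.Random, namespace: str, prefix: str, n_terms: int) -> Ontology:
    """A random is_a DAG: each term's parents are drawn from earlier terms."""
    terms: dict[str, OntologyTerm] = {}
    ids: list[str] = []
    for i in range(n_terms):
        term_id = f"{prefix}:{i:07d}"
        n_parents = 0 if not ids else rng.randint(0, min(2, len(ids)))
        parents = tuple(rng.sample(ids, n_parents))
        terms[term_id] = OntologyTerm(term_id, f"{namespace} term {i}", namespace, parents)
        ids.append(term_id)
    return Ontology(terms, namespace=namespace)


def make_random_bundle(
    seed: int,
    n_genes: int = 20,
    n_terms_per_namespace: int = 12,
    max_records_per_category: int = 4,
) -> AnnotationBundle:
    """A reproducible random AnnotationBundle exercising every category.

    The same seed always yields an identical bundle; size parameters
    bound per-gene record counts, not totals.
    """
    rng = random.Random(seed)
    namespaces = {
        "molecular_function": "RMF",
        "biological_process": "RBP",
        "cellular_component": "RCC",
    }
    ontologies = [
        _random_ontology(rng, ns, prefix, n_terms_per_namespace)
        for ns, prefix in namespaces.items()
    ]
    term_ids = {onto.namespace: list(onto.terms) for onto in ontologies}

    genes = [
        GeneRecord(f"rg-{i:04d}", f"rgene-{i}", rng.choice(_RANDOM_SPECIES))
        for i in range(n_genes)
    ]

    default_qualifier = {
        "molecular_function": "enables",
        "biological_process": "involved_in",
        "cellular_component": "located_in",
    }
    go_annotations = []
    expression = []
    orthologs = []
    large_scale = []
    domains = []
    for gene in genes:
        for _ in range(rng.randint(0, max_records_per_category)):
            aspect = rng.choice(list(namespaces))
            qualifier = default_qualifier[aspect]
            if aspect == "molecular_function" and rng.random() < 0.2:
                qualifier = "contributes_to"
            go_annotations.append(
                GOAnnotation(
                    gene_id=gene.gene_id,
                    term_id=rng.choice(term_ids[aspect]),
                    aspect=aspect,
                    evidence_code=rng.choice(_EVIDENCE_CODES),
                    qualifier=qualifier,
                )
            )
        anatomy_pool = ("gonad", "head", "intestine", "pharynx")
        for part in rng.sample(anatomy_pool, rng.randint(0, min(max_records_per_category, len(anatomy_pool)))):
            expression.append(ExpressionAnnotation(gene.gene_id, part))
        for j in range(rng.randint(0, max_records_per_category)):
            is_human = gene.species == "c_elegans" and rng.random() < 0.5
            ortholog_species = "human" if is_human else rng.choice(_RANDOM_SPECIES)
            n_methods = rng.randint(1, 10)
            orthologs.append(
                OrthologRecord(
                    subject_gene_id=gene.gene_id,
                    subject_species=gene.species,
                    ortholog_gene_id=f"ort-{gene.gene_id}-{j}",
                    ortholog_symbol=f"osym-{rng.randint(0, 999)}",
                    ortholog_full_name=f"ortholog full name {j}",
                    ortholog_species=ortholog_species,
                    methods=frozenset(f"m{k}" for k in range(n_methods)),
                )
            )
        for j in range(rng.randint(0, max_records_per_category)):
            n_studies = rng.randint(1, len(STUDY_TYPES))
            large_scale.append(
                LargeScaleRecord(
                    gene_id=gene.gene_id,
                    kind=rng.choice(("expression_enrichment", "gene_regulation", "chemical_regulation")),
                    object_name=f"object-{j}-{rng.randint(0, 99)}",
                    study_types=tuple(rng.sample(STUDY_TYPES, n_studies)),
                )
            )
        for k in range(rng.randint(0, max_records_per_category)):
            domains.append(
                DomainRecord(gene.gene_id, f"domain-{k}-{rng.randint(0, 99)}", f"IPR-R{k:03d}")
            )

    return build_bundle(
        genes,
        ontologies,
        go_annotations,
        [],
        expression,
        orthologs,
        large_scale,
        domains,
    )
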