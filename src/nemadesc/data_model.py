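"""Core record types and the per-species annotation bundle.

The bundle is the single in-memory container that statement builders
consult: it indexes every annotation category by gene id and records
dangling references (annotations whose gene id matches no gene record)
without failing, so that one malformed row cannot abort a whole run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import UnknownGeneError

GO_ASPECTS = ("molecular_function", "biological_process", "cellular_component")
NAMESPACES = GO_ASPECTS + ("disease", "anatomy")

QUALIFIERS = ("enables", "contributes_to", "involved_in", "located_in", "expressed_in")

LARGE_SCALE_KINDS = ("expression_enrichment", "gene_regulation", "chemical_regulation")
STUDY_TYPES = ("RNA-seq", "tiling array", "microarray")


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str
    namespace: str
    parent_ids: tuple[str, ...] = ()


@dataclass
class Ontology:
    """A validated is_a DAG of terms, possibly spanning several namespaces.

    A single OBO file may mix namespaces (the Gene Ontology ships all
    three aspects in one file); ``namespace`` is None in that case and the
    per-term namespace is authoritative.
    """

    terms: dict[str, OntologyTerm]
    namespace: str | None = None

    def __post_init__(self) -> None:
        spaces = {t.namespace for t in self.terms.values()}
        if self.namespace is None and len(spaces) == 1:
            self.namespace = next(iter(spaces))

    @property
    def namespaces(self) -> set[str]:
        return {t.namespace for t in self.terms.values()}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    public_name: str
    species: str


@dataclass(frozen=True)
class GOAnnotation:
    gene_id: str
    term_id: str
    aspect: str  # one of GO_ASPECTS
    evidence_code: str
    qualifier: str  # one of QUALIFIERS


@dataclass(frozen=True)
class DiseaseAnnotation:
    gene_id: str  # the human gene
    disease_term_name: str


@dataclass(frozen=True)
class ExpressionAnnotation:
    gene_id: str
    anatomy_term_name: str


@dataclass(frozen=True)
class OrthologRecord:
    subject_gene_id: str
    subject_species: str
    ortholog_gene_id: str
    ortholog_symbol: str
    ortholog_full_name: str
    ortholog_species: str
    methods: frozenset[str]

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError(
                f"ortholog record {self.subject_gene_id}->{self.ortholog_gene_id} "
                "has an empty prediction-method set"
            )


@dataclass(frozen=True)
class LargeScaleRecord:
    gene_id: str
    kind: str  # one of LARGE_SCALE_KINDS
    object_name: str  # tissue/stage/sex term, gene symbol, or chemical name
    study_types: tuple[str, ...]  # ordered, non-empty, values from STUDY_TYPES

    def __post_init__(self) -> None:
        if not self.study_types:
            raise ValueError(f"large-scale record for {self.gene_id} has no study types")


@dataclass(frozen=True)
class DomainRecord:
    gene_id: str
    domain_name: str
    interpro_id: str

    def __post_init__(self) -> None:
        if not self.domain_name:
            raise ValueError(f"domain record for {self.gene_id} has an empty name")


@dataclass
class AnnotationBundle:
    """All structured inputs for one run, indexed by gene id."""

    genes: dict[str, GeneRecord] = field(default_factory=dict)
    ontologies: dict[str, Ontology] = field(default_factory=dict)  # by namespace
    go_annotations: list[GOAnnotation] = field(default_factory=list)
    disease_annotations: list[DiseaseAnnotation] = field(default_factory=list)
    expression_annotations: list[ExpressionAnnotation] = field(default_factory=list)
    ortholog_records: list[OrthologRecord] = field(default_factory=list)
    large_scale_records: list[LargeScaleRecord] = field(default_factory=list)
    domain_records: list[DomainRecord] = field(default_factory=list)
    #: (category, gene_id) pairs for annotations whose gene id matched no gene
    dangling: list[tuple[str, str]] = field(default_factory=list)

    # per-gene indexes, filled by build_bundle
    _go_by_gene: dict[str, list[GOAnnotation]] = field(default_factory=dict, repr=False)
    _disease_by_gene: dict[str, list[DiseaseAnnotation]] = field(default_factory=dict, repr=False)
    _expression_by_gene: dict[str, list[ExpressionAnnotation]] = field(default_factory=dict, repr=False)
    _orthologs_by_gene: dict[str, list[OrthologRecord]] = field(default_factory=dict, repr=False)
    _large_scale_by_gene: dict[str, list[LargeScaleRecord]] = field(default_factory=dict, repr=False)
    _domains_by_gene: dict[str, list[DomainRecord]] = field(default_factory=dict, repr=False)

    def term_name(self, term_id: str) -> str:
        for onto in self.ontologies.values():
            term = onto.terms.get(term_id)
            if term is not None:
                return term.name
        return term_id  # fall back to the accession itself

    def _require_gene(self, gene_id: str) -> GeneRecord:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise UnknownGeneError(gene_id) from None

    def go_for(self, gene_id: str) -> list[GOAnnotation]:
        return self._go_by_gene.get(gene_id, [])

    def diseases_for(self, gene_id: str) -> list[DiseaseAnnotation]:
        return self._disease_by_gene.get(gene_id, [])

    def expression_for(self, gene_id: str) -> list[ExpressionAnnotation]:
        return self._expression_by_gene.get(gene_id, [])

    def orthologs_for(self, gene_id: str) -> list[OrthologRecord]:
        return self._orthologs_by_gene.get(gene_id, [])

    def large_scale_for(self, gene_id: str) -> list[LargeScaleRecord]:
        return self._large_scale_by_gene.get(gene_id, [])

    def domains_for(self, gene_id: str) -> list[DomainRecord]:
        return self._domains_by_gene.get(gene_id, [])

    def go_annotation_counts(self) -> Counter[str]:
        """Number of GO annotations per gene, any aspect and evidence."""
        return Counter(a.gene_id for a in self.go_annotations)


def build_bundle(
    genes: list[GeneRecord] | dict[str, GeneRecord],
    ontologies: list[Ontology] = (),
    go_annotations: list[GOAnnotation] = (),
    disease_annotations: list[DiseaseAnnotation] = (),
    expression_annotations: list[ExpressionAnnotation] = (),
    ortholog_records: list[OrthologRecord] = (),
    large_scale_records: list[LargeScaleRecord] = (),
    domain_records: list[DomainRecord] = (),
) -> AnnotationBundle:
    """Assemble and index an AnnotationBundle from parsed inputs.

    Ontologies are re-keyed by namespace: a mixed-namespace ontology (the
    usual shape of a GO file) is split into one Ontology per namespace.
    Annotations whose gene id resolves to no GeneRecord are still indexed
    (lookups by ortholog gene ids must work even when the ortholog itself
    is not a summarized gene) but subject-side references are reported in
    ``bundle.dangling``.
    """
    if isinstance(genes, dict):
        gene_map = dict(genes)
    else:
        gene_map = {g.gene_id: g for g in genes}

    by_namespace: dict[str, dict[str, OntologyTerm]] = {}
    for onto in ontologies:
        for term in onto.terms.values():
            by_namespace.setdefault(term.namespace, {})[term.term_id] = term

    bundle = AnnotationBundle(
        genes=gene_map,
        ontologies={ns: Ontology(terms, namespace=ns) for ns, terms in by_namespace.items()},
        go_annotations=list(go_annotations),
        disease_annotations=list(disease_annotations),
        expression_annotations=list(expression_annotations),
        ortholog_records=list(ortholog_records),
        large_scale_records=list(large_scale_records),
        domain_records=list(domain_records),
    )

    def index(records, key, target, category, check_dangling=True):
        for rec in records:
            gid = key(rec)
            target.setdefault(gid, []).append(rec)
            if check_dangling and gid not in gene_map:
                bundle.dangling.append((category, gid))

    index(bundle.go_annotations, lambda r: r.gene_id, bundle._go_by_gene, "go")
    # disease annotations attach to human ortholog genes, which commonly have
    # no GeneRecord of their own -- not a dangling reference
    index(bundle.disease_annotations, lambda r: r.gene_id, bundle._disease_by_gene,
          "disease", check_dangling=False)
    index(bundle.expression_annotations, lambda r: r.gene_id, bundle._expression_by_gene, "expression")
    index(bundle.ortholog_records, lambda r: r.subject_gene_id, bundle._orthologs_by_gene, "orthology")
    index(bundle.large_scale_records, lambda r: r.gene_id, bundle._large_scale_by_gene, "large_scale")
    index(bundle.domain_records, lambda r: r.gene_id, bundle._domains_by_gene, "domains")
    return bundle


def has_go_data(bundle: AnnotationBundle, gene_id: str) -> bool:
    """True iff the gene carries at least one GO annotation, any aspect."""
    bundle._require_gene(gene_id)
    return bool(bundle.go_for(gene_id))


def has_expression_data(bundle: AnnotationBundle, gene_id: str) -> bool:
    """True iff the gene carries curated anatomy expression annotations.

    Large-scale expression-enrichment records deliberately do not count:
    they gate on, not against, themselves.
    """
    bundle._require_gene(gene_id)
    return bool(bundle.expression_for(gene_id))
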