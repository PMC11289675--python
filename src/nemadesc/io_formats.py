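"""Readers for the engine's input files.

Three dialects are supported:

* a minimal OBO subset for ontologies ([Term] stanzas with id, name,
  namespace and is_a; everything else is ignored with a warning),
* GAF 2.2 for GO annotations (17 tab-separated columns, ``!`` comments),
* fixed-schema TSV tables for disease, curated expression, orthology,
  large-scale and protein-domain records.

Parsing is deterministic and order-preserving; structural problems raise
the structured errors from :mod:`nemadesc.errors`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

from .data_model import (
    LARGE_SCALE_KINDS,
    NAMESPACES,
    QUALIFIERS,
    STUDY_TYPES,
    DiseaseAnnotation,
    DomainRecord,
    ExpressionAnnotation,
    GeneRecord,
    GOAnnotation,
    Ontology,
    OntologyTerm,
    OrthologRecord,
    LargeScaleRecord,
)
from .errors import (
    DanglingParentError,
    MissingColumnError,
    OntologyCycleError,
    TableFormatError,
    UnknownSchemaError,
)

logger = logging.getLogger(__name__)

_OBO_KNOWN_TAGS = {"name", "namespace", "is_a"}

GAF_COLUMNS = 17
_ASPECT_BY_LETTER = {"F": "molecular_function", "P": "biological_process", "C": "cellular_component"}
_DEFAULT_QUALIFIER = {
    "molecular_function": "enables",
    "biological_process": "involved_in",
    "cellular_component": "located_in",
}

#: schema name -> required column order
TSV_SCHEMAS: dict[str, tuple[str, ...]] = {
    "genes": ("gene_id", "public_name", "species"),
    "disease": ("gene_id", "disease_term_name"),
    "expression": ("gene_id", "anatomy_term_name"),
    "orthology": (
        "subject_gene_id",
        "subject_species",
        "ortholog_gene_id",
        "ortholog_symbol",
        "ortholog_full_name",
        "ortholog_species",
        "methods",
    ),
    "large_scale": ("gene_id", "kind", "object_name", "study_types"),
    "domains": ("gene_id", "domain_name", "interpro_id"),
}


def parse_obo(path: str | Path) -> Ontology:
    """Read an OBO file (restricted dialect) into a validated Ontology.

    Only ``id``, ``name``, ``namespace`` and ``is_a`` are honored; other
    tags are ignored with a logged warning.  The is_a graph must be a DAG
    and every parent must be defined in the file.
    """
    path = Path(path)
    graph = obonet.read_obo(path)

    # nodes that appear only as is_a targets carry no attributes
    defined = {n for n, data in graph.nodes(data=True) if "name" in data}
    for node in graph.nodes:
        if node not in defined:
            raise DanglingParentError(node)

    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise OntologyCycleError(cycle[0][0])

    terms: dict[str, OntologyTerm] = {}
    for term_id, data in graph.nodes(data=True):
        unknown = set(data) - _OBO_KNOWN_TAGS
        if unknown:
            logger.warning("%s: ignoring OBO tags %s on %s", path.name, sorted(unknown), term_id)
        namespace = str(data.get("namespace", "")).strip()
        if namespace not in NAMESPACES:
            raise TableFormatError(str(path), f"term {term_id} has unsupported namespace {namespace!r}")
        terms[term_id] = OntologyTerm(
            term_id=term_id.strip(),
            name=str(data["name"]).strip(),
            namespace=namespace,
            parent_ids=tuple(data.get("is_a", [])),
        )
    return Ontology(terms)


class GafAnnotations(list):
    """Parsed GAF rows; ``dropped`` counts rows removed by validation."""

    dropped: int = 0


def parse_gaf(path: str | Path, ontology: Ontology) -> GafAnnotations:
    """Read a GAF 2.2 file, resolving term ids against *ontology*.

    Rows whose term id is absent from the ontology, or whose aspect letter
    contradicts the term's namespace, are dropped with a warning and
    counted on the returned list's ``dropped`` attribute.
    """
    path = Path(path)
    annotations = GafAnnotations()
    with path.open(encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) != GAF_COLUMNS:
                raise TableFormatError(
                    str(path), f"expected {GAF_COLUMNS} columns, found {len(fields)}", line=lineno
                )
            gene_id = fields[1].strip()
            qualifier_raw = fields[3].strip()
            term_id = fields[4].strip()
            evidence = fields[6].strip()
            aspect_letter = fields[8].strip()

            aspect = _ASPECT_BY_LETTER.get(aspect_letter)
            if aspect is None:
                raise TableFormatError(str(path), f"unknown aspect letter {aspect_letter!r}", line=lineno)

            term = ontology.terms.get(term_id)
            if term is None:
                logger.warning("%s:%d: dropping row, unknown term %s", path.name, lineno, term_id)
                annotations.dropped += 1
                continue
            if term.namespace != aspect:
                logger.warning(
                    "%s:%d: dropping row, aspect %s contradicts namespace %s of %s",
                    path.name, lineno, aspect_letter, term.namespace, term_id,
                )
                annotations.dropped += 1
                continue

            # GAF 2.2 qualifiers may be negated ("NOT|enables"); negated
            # annotations never feed a positive summary statement
            if qualifier_raw.startswith("NOT|") or qualifier_raw == "NOT":
                annotations.dropped += 1
                continue
            if qualifier_raw in QUALIFIERS:
                qualifier = qualifier_raw
            else:
                if qualifier_raw:
                    logger.warning(
                        "%s:%d: unknown qualifier %r, defaulting by aspect", path.name, lineno, qualifier_raw
                    )
                qualifier = _DEFAULT_QUALIFIER[aspect]

            annotations.append(
                GOAnnotation(
                    gene_id=gene_id,
                    term_id=term_id,
                    aspect=aspect,
                    evidence_code=evidence,
                    qualifier=qualifier,
                )
            )
    return annotations


def _split_csv(value: str) -> tuple[str, ...]:
    return tuple(part.strip() for part in str(value).split(",") if part.strip())


def parse_tsv_table(path: str | Path, schema: str) -> list:
    """Read one of the fixed-schema TSV tables into typed records.

    Duplicate rows are dropped (first occurrence wins); record order
    otherwise follows file order.
    """
    path = Path(path)
    if schema not in TSV_SCHEMAS:
        raise UnknownSchemaError(schema)
    columns = TSV_SCHEMAS[schema]

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in columns:
        if column not in frame.columns:
            raise MissingColumnError(str(path), column)
    frame = frame[list(columns)].map(lambda v: str(v).strip())
    frame = frame.drop_duplicates(keep="first")

    records: list = []
    for lineno, row in zip(frame.index + 2, frame.itertuples(index=False)):
        values = dict(zip(columns, row))
        if schema == "genes":
            records.append(GeneRecord(values["gene_id"], values["public_name"], values["species"]))
        elif schema == "disease":
            records.append(DiseaseAnnotation(values["gene_id"], values["disease_term_name"]))
        elif schema == "expression":
            records.append(ExpressionAnnotation(values["gene_id"], values["anatomy_term_name"]))
        elif schema == "orthology":
            methods = frozenset(_split_csv(values["methods"]))
            if not methods:
                raise TableFormatError(str(path), "empty prediction-method set", line=lineno)
            records.append(
                OrthologRecord(
                    subject_gene_id=values["subject_gene_id"],
                    subject_species=values["subject_species"],
                    ortholog_gene_id=values["ortholog_gene_id"],
                    ortholog_symbol=values["ortholog_symbol"],
                    ortholog_full_name=values["ortholog_full_name"],
                    ortholog_species=values["ortholog_species"],
                    methods=methods,
                )
            )
        elif schema == "large_scale":
            kind = values["kind"]
            if kind not in LARGE_SCALE_KINDS:
                raise TableFormatError(str(path), f"unknown large-scale kind {kind!r}", line=lineno)
            study_types = _split_csv(values["study_types"])
            if not study_types:
                raise TableFormatError(str(path), "empty study-type list", line=lineno)
            for study in study_types:
                if study not in STUDY_TYPES:
                    raise TableFormatError(str(path), f"unknown study type {study!r}", line=lineno)
            records.append(LargeScaleRecord(values["gene_id"], kind, values["object_name"], study_types))
        elif schema == "domains":
            if not values["domain_name"]:
                raise TableFormatError(str(path), "empty domain name", line=lineno)
            records.append(DomainRecord(values["gene_id"], values["domain_name"], values["interpro_id"]))
    return records
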