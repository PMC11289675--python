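"""Statement builders and category gating.

A Statement is an intermediate, category-tagged unit of summary content:
an ordered item list plus the total count behind it (items may later be
truncated to exemplars at rendering time), plus template-specific
qualifiers such as study types or the source ortholog symbol.

Building and gating are strictly separated: builders emit every statement
the data supports; :func:`apply_gating` filters them afterwards according
to a profile, never mutating statement content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .data_model import (
    AnnotationBundle,
    GOAnnotation,
    has_expression_data,
    has_go_data,
)
from .ortholog_selection import RankedOrthologSet
from .species import display_name

logger = logging.getLogger(__name__)

CATEGORIES = (
    "go_function",
    "go_process",
    "go_component",
    "curated_expression",
    "ortholog_disease",
    "ortholog_function_transfer",
    "largescale_enrichment",
    "largescale_gene_regulation",
    "largescale_chemical_regulation",
    "protein_domain",
    "orthology",
    "elegans_process_transfer",
)

#: evidence codes rendered with "Predicted to ..." phrasing
PREDICTED_EVIDENCE_CODES = frozenset({"IEA", "ISS", "ISO", "IBA", "RCA"})

_CATEGORY_BY_ASPECT = {
    "molecular_function": "go_function",
    "biological_process": "go_process",
    "cellular_component": "go_component",
}

# (qualifier, evidence class) -> template id for direct GO statements
_GO_TEMPLATES = {
    ("enables", "predicted"): "predicted_enables",
    ("enables", "experimental"): "exp_enables",
    ("contributes_to", "predicted"): "contributes_to",
    ("contributes_to", "experimental"): "contributes_to",
    ("involved_in", "predicted"): "predicted_involved_in",
    ("involved_in", "experimental"): "exp_involved_in",
    ("located_in", "predicted"): "predicted_located_in",
    ("located_in", "experimental"): "exp_located_in",
    ("expressed_in", "predicted"): "predicted_expressed_in",
    ("expressed_in", "experimental"): "exp_expressed_in",
}

#: transferred term names beginning with this prefix are rendered as a
#: bare noun-phrase sentence ("A structural constituent of ...") instead
#: of joining the enables list
STRUCTURAL_CONSTITUENT_PREFIX = "structural constituent"


@dataclass(frozen=True)
class Statement:
    gene_id: str
    category: str  # one of CATEGORIES
    template_id: str
    items: tuple[str, ...]
    total_count: int
    qualifiers: tuple[str, ...] = ()
    prefix_word: str | None = None  # filled at realization time

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown statement category {self.category!r}")
        if self.total_count < len(self.items):
            raise ValueError("total_count smaller than the number of items")
        if not self.items:
            raise ValueError("statement with empty item list")


@dataclass(frozen=True)
class GatingProfile:
    """Which data presence blocks which statement category.

    A category is removed when ANY of its blocking conditions holds for
    the gene.  ``strict`` encodes the literal transfer rules (large-scale
    and domain statements blocked by either GO or curated expression
    data); ``ws292`` relaxes those two groups to GO-only blocking, which
    is the behavior the production summaries exhibit, and is the default.
    """

    name: str
    rules: dict[str, frozenset[str]] = field(default_factory=dict)


def _profile(name: str, largescale_block: frozenset[str]) -> GatingProfile:
    rules = {
        "ortholog_disease": frozenset({"has_go"}),
        "ortholog_function_transfer": frozenset({"has_go"}),
        "largescale_enrichment": largescale_block,
        "largescale_gene_regulation": largescale_block,
        "largescale_chemical_regulation": largescale_block,
        "protein_domain": largescale_block,
    }
    return GatingProfile(name=name, rules=rules)


STRICT_PROFILE = _profile("strict", frozenset({"has_go", "has_expression"}))
WS292_PROFILE = _profile("ws292", frozenset({"has_go"}))
PROFILES = {"strict": STRICT_PROFILE, "ws292": WS292_PROFILE}


def _dedup(items) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for item in items:
        seen.setdefault(item, None)
    return tuple(seen)


def evidence_class(code: str, predicted_codes: frozenset[str] = PREDICTED_EVIDENCE_CODES) -> str:
    return "predicted" if code in predicted_codes else "experimental"


def build_go_statements(
    bundle: AnnotationBundle,
    gene_id: str,
    predicted_codes: frozenset[str] = PREDICTED_EVIDENCE_CODES,
) -> list[Statement]:
    """One statement per (aspect, qualifier, evidence class) group.

    Groups appear in first-annotation order; items are distinct term
    names in annotation order.
    """
    bundle._require_gene(gene_id)
    groups: dict[tuple[str, str, str], list[GOAnnotation]] = {}
    for ann in bundle.go_for(gene_id):
        key = (ann.aspect, ann.qualifier, evidence_class(ann.evidence_code, predicted_codes))
        groups.setdefault(key, []).append(ann)

    statements = []
    for (aspect, qualifier, ev_class), anns in groups.items():
        items = _dedup(bundle.term_name(a.term_id) for a in anns)
        statements.append(
            Statement(
                gene_id=gene_id,
                category=_CATEGORY_BY_ASPECT[aspect],
                template_id=_GO_TEMPLATES[(qualifier, ev_class)],
                items=items,
                total_count=len(items),
            )
        )
    return statements


def build_curated_expression_statement(bundle: AnnotationBundle, gene_id: str) -> Statement | None:
    records = bundle.expression_for(gene_id)
    if not records:
        return None
    items = _dedup(r.anatomy_term_name for r in records)
    return Statement(
        gene_id=gene_id,
        category="curated_expression",
        template_id="expressed_in_anatomy",
        items=items,
        total_count=len(items),
    )


def build_ortholog_transfer_statements(
    bundle: AnnotationBundle,
    gene_id: str,
    ranked: RankedOrthologSet,
    predicted_codes: frozenset[str] = PREDICTED_EVIDENCE_CODES,
) -> list[Statement]:
    """Disease and molecular-activity statements from best human orthologs.

    One disease statement is built from the deduplicated union over all
    selected human genes; function statements are built per human gene
    (contributes_to first, then enables).  Transferred term names that
    begin with "structural constituent" become standalone noun-phrase
    statements rather than list entries.
    """
    if not ranked:
        return []
    statements: list[Statement] = []

    disease_items = _dedup(
        d.disease_term_name
        for record in ranked.selected
        for d in bundle.diseases_for(record.ortholog_gene_id)
    )
    if disease_items:
        statements.append(
            Statement(
                gene_id=gene_id,
                category="ortholog_disease",
                template_id="ortholog_disease",
                items=disease_items,
                total_count=len(disease_items),
            )
        )

    for record in ranked.selected:
        annotations = [
            a for a in bundle.go_for(record.ortholog_gene_id) if a.aspect == "molecular_function"
        ]
        contributes = _dedup(
            bundle.term_name(a.term_id) for a in annotations if a.qualifier == "contributes_to"
        )
        enables_all = _dedup(
            bundle.term_name(a.term_id) for a in annotations if a.qualifier == "enables"
        )
        enables = tuple(
            t for t in enables_all if not t.startswith(STRUCTURAL_CONSTITUENT_PREFIX)
        )
        structural = tuple(
            t for t in enables_all if t.startswith(STRUCTURAL_CONSTITUENT_PREFIX)
        )
        if contributes:
            statements.append(
                Statement(
                    gene_id=gene_id,
                    category="ortholog_function_transfer",
                    template_id="human_contributes",
                    items=contributes,
                    total_count=len(contributes),
                    qualifiers=(record.ortholog_symbol,),
                )
            )
        if enables:
            statements.append(
                Statement(
                    gene_id=gene_id,
                    category="ortholog_function_transfer",
                    template_id="human_enables",
                    items=enables,
                    total_count=len(enables),
                    qualifiers=(record.ortholog_symbol,),
                )
            )
        for term in structural:
            statements.append(
                Statement(
                    gene_id=gene_id,
                    category="ortholog_function_transfer",
                    template_id="structural_constituent",
                    items=(term,),
                    total_count=1,
                    qualifiers=(record.ortholog_symbol,),
                )
            )
    return statements


def build_elegans_transfer_statement(
    bundle: AnnotationBundle, gene_id: str, ranked: RankedOrthologSet
) -> Statement | None:
    """Biological processes of the best nematode ortholog, as one sentence."""
    if not ranked:
        return None
    record = ranked.selected[0]
    processes = _dedup(
        bundle.term_name(a.term_id)
        for a in bundle.go_for(record.ortholog_gene_id)
        if a.aspect == "biological_process"
    )
    if not processes:
        return None
    return Statement(
        gene_id=gene_id,
        category="elegans_process_transfer",
        template_id="process_transfer",
        items=processes,
        total_count=len(processes),
        qualifiers=(display_name(record.ortholog_species), record.ortholog_symbol),
    )


def _study_type_union(records) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for record in records:
        for study in record.study_types:
            seen.setdefault(study, None)
    return tuple(seen)


def build_large_scale_statements(bundle: AnnotationBundle, gene_id: str) -> list[Statement]:
    """Up to three statements from collated high-throughput records."""
    bundle._require_gene(gene_id)
    records = bundle.large_scale_for(gene_id)
    plan = (
        ("expression_enrichment", "largescale_enrichment", "enrichment"),
        ("gene_regulation", "largescale_gene_regulation", "gene_regulation"),
        ("chemical_regulation", "largescale_chemical_regulation", "chemical_regulation"),
    )
    statements = []
    for kind, category, template_id in plan:
        of_kind = [r for r in records if r.kind == kind]
        if not of_kind:
            continue
        items = _dedup(r.object_name for r in of_kind)
        statements.append(
            Statement(
                gene_id=gene_id,
                category=category,
                template_id=template_id,
                items=items,
                total_count=len(items),
                qualifiers=_study_type_union(of_kind),
            )
        )
    return statements


def build_domain_statement(bundle: AnnotationBundle, gene_id: str) -> Statement | None:
    records = bundle.domains_for(gene_id)
    if not records:
        return None
    items = _dedup(r.domain_name for r in records)
    return Statement(
        gene_id=gene_id,
        category="protein_domain",
        template_id="protein_domain",
        items=items,
        total_count=len(items),
    )


def build_orthology_statement(
    bundle: AnnotationBundle, gene_id: str, ranked: RankedOrthologSet
) -> Statement | None:
    """"Is an ortholog of ..." — human orthologs get their full name appended."""
    if not ranked:
        return None
    items = []
    for record in ranked.selected:
        entry = f"{display_name(record.ortholog_species)} {record.ortholog_symbol}"
        if record.ortholog_species == "human" and record.ortholog_full_name:
            entry += f" ({record.ortholog_full_name})"
        items.append(entry)
    return Statement(
        gene_id=gene_id,
        category="orthology",
        template_id="orthology",
        items=tuple(items),
        total_count=len(items),
    )


def apply_gating(
    statements: list[Statement],
    gene_id: str,
    bundle: AnnotationBundle,
    profile: GatingProfile,
) -> list[Statement]:
    """Filter statements whose category is blocked for this gene.

    Pure filter: surviving statements are the same objects, in the same
    order.  Direct-annotation categories (go_*, curated_expression,
    orthology, elegans_process_transfer) are never gated.
    """
    conditions = {
        "has_go": has_go_data(bundle, gene_id),
        "has_expression": has_expression_data(bundle, gene_id),
    }
    kept = []
    for statement in statements:
        blockers = profile.rules.get(statement.category, frozenset())
        if any(conditions[b] for b in blockers):
            logger.debug(
                "gating[%s]: dropping %s statement for %s", profile.name, statement.category, gene_id
            )
            continue
        kept.append(statement)
    return kept


def with_prefix(statement: Statement, prefix_word: str | None) -> Statement:
    """Return a copy of *statement* with the realized prefix recorded."""
    return replace(statement, prefix_word=prefix_word)
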