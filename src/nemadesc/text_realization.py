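"""Surface realization: Statements -> English sentences -> GeneSummary.

List grammar follows the house style of WormBase descriptions: two items
join with "and", three or more join with semicolons and a final "; and".
Long lists in truncating categories collapse to the first few exemplars
behind a count word ("seven chemicals including ...") or "several" once
the count reaches a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import CountRangeError, EmptyListError, UnknownTemplateError
from .statement_generation import CATEGORIES, Statement, with_prefix

DEFAULT_CATEGORY_ORDER: tuple[str, ...] = CATEGORIES

DEFAULT_TRUNCATING = frozenset(
    {
        "ortholog_disease",
        "ortholog_function_transfer",
        "largescale_gene_regulation",
        "largescale_chemical_regulation",
    }
)

#: template ids whose truncated form reads ", including" (with comma)
DEFAULT_COMMA_TEMPLATES = frozenset({"ortholog_disease", "human_enables"})


@dataclass(frozen=True)
class RealizationConfig:
    exemplar_count: int = 3
    several_threshold: int = 10
    category_order: tuple[str, ...] = DEFAULT_CATEGORY_ORDER
    truncating_categories: frozenset[str] = DEFAULT_TRUNCATING
    comma_templates: frozenset[str] = DEFAULT_COMMA_TEMPLATES

    def __post_init__(self) -> None:
        if self.exemplar_count < 1:
            raise ValueError("exemplar_count must be >= 1")
        if self.several_threshold <= self.exemplar_count:
            raise ValueError("several_threshold must exceed exemplar_count")


@dataclass(frozen=True)
class GeneSummary:
    gene_id: str
    public_name: str
    species: str
    sentences: tuple[str, ...]
    categories: tuple[str, ...]  # parallel to sentences
    text: str


def realize_list(items: list[str] | tuple[str, ...]) -> str:
    """Join items: "a"; "a and b"; "a; b; and c"."""
    items = list(items)
    if not items:
        raise EmptyListError()
    if len(items) == 1:
        return items[0]
    if len(items) == 2:
        return f"{items[0]} and {items[1]}"
    return "; ".join(items[:-1]) + "; and " + items[-1]


_ONES = (
    "zero", "one", "two", "three", "four", "five", "six", "seven", "eight",
    "nine", "ten", "eleven", "twelve", "thirteen", "fourteen", "fifteen",
    "sixteen", "seventeen", "eighteen", "nineteen",
)
_TENS = ("", "", "twenty", "thirty", "forty", "fifty", "sixty", "seventy", "eighty", "ninety")


def count_word(n: int) -> str:
    """Lowercase English cardinal for 1 <= n <= 999 ("twenty-one")."""
    if not isinstance(n, int) or not 1 <= n <= 999:
        raise CountRangeError(n)
    if n < 20:
        return _ONES[n]
    if n < 100:
        tens, rest = divmod(n, 10)
        return _TENS[tens] + (f"-{_ONES[rest]}" if rest else "")
    hundreds, rest = divmod(n, 100)
    word = f"{_ONES[hundreds]} hundred"
    return word + (f" {count_word(rest)}" if rest else "")


def truncate_items(statement: Statement, config: RealizationConfig) -> tuple[str, list[str]]:
    """Decide the (prefix, shown exemplars) pair for a statement.

    Non-truncating categories, and truncating ones whose total fits in
    the exemplar budget, show everything with no prefix.  Otherwise the
    first ``exemplar_count`` items are shown behind a spelled-out count,
    or "several" once the total reaches ``several_threshold``.
    """
    if statement.category not in config.truncating_categories:
        return "", list(statement.items)
    if statement.total_count <= config.exemplar_count:
        return "", list(statement.items)
    shown = list(statement.items[: config.exemplar_count])
    if statement.total_count >= config.several_threshold:
        return "several", shown
    return count_word(statement.total_count), shown


def _studies_clause(statement: Statement) -> str:
    return realize_list(list(statement.qualifiers)) + " studies"


# Each entry: (base form, truncated form). "{inc}" is replaced per the
# comma flag; {items}, {prefix}, {studies}, {q0}, {q1} are filled in.
_TEMPLATES: dict[str, tuple[str, str | None]] = {
    "predicted_enables": ("Predicted to enable {items}.", None),
    "exp_enables": ("Enables {items}.", None),
    "contributes_to": ("Contributes to {items}.", None),
    "predicted_involved_in": ("Predicted to be involved in {items}.", None),
    "exp_involved_in": ("Is involved in {items}.", None),
    "predicted_located_in": ("Predicted to be located in {items}.", None),
    "exp_located_in": ("Located in {items}.", None),
    "predicted_expressed_in": ("Predicted to be expressed in {items}.", None),
    "exp_expressed_in": ("Is expressed in {items}.", None),
    "expressed_in_anatomy": ("Expressed in {items}.", None),
    "ortholog_disease": (
        "Human ortholog(s) of this gene implicated in {items}.",
        "Human ortholog(s) of this gene implicated in {prefix} diseases{inc} {items}.",
    ),
    "human_contributes": ("Human {q0} Contributes to {items}.", None),
    "human_enables": (
        "Human {q0} enables {items}.",
        "Human {q0} enables {prefix} functions{inc} {items}.",
    ),
    "structural_constituent": ("A {items}.", None),
    "enrichment": ("Enriched in {items} based on {studies}.", None),
    "gene_regulation": (
        "Is affected by {items} based on {studies}.",
        "Is affected by {prefix} genes{inc} {items} based on {studies}.",
    ),
    "chemical_regulation": (
        "Is affected by {items} based on {studies}.",
        "Is affected by {prefix} chemicals{inc} {items} based on {studies}.",
    ),
    "protein_domain": ("Is predicted to encode a protein with the following domains: {items}.", None),
    "orthology": ("Is an ortholog of {items}.", None),
    "process_transfer": ("In {q0}, {q1} is involved in {items}.", None),
}


def realize_statement(statement: Statement, config: RealizationConfig | None = None) -> str:
    """Render one statement to a complete sentence."""
    config = config or RealizationConfig()
    if statement.template_id not in _TEMPLATES:
        raise UnknownTemplateError(statement.template_id)
    base, truncated = _TEMPLATES[statement.template_id]

    prefix, shown = truncate_items(statement, config)
    template = truncated if (prefix and truncated) else base
    inc = ", including" if statement.template_id in config.comma_templates else " including"

    fields = {
        "items": realize_list(shown),
        "prefix": prefix,
        "inc": inc,
    }
    if "{studies}" in template:
        fields["studies"] = _studies_clause(statement)
    for i, qualifier in enumerate(statement.qualifiers):
        fields[f"q{i}"] = qualifier
    return template.replace("{inc}", inc).format(**fields)


def assemble_summary(
    gene, statements: list[Statement], config: RealizationConfig | None = None
) -> GeneSummary:
    """Order statements by category and join their sentences with spaces.

    The category sort is stable: statements within a category keep their
    build order, so the assembled text does not depend on the order in
    which categories were built.
    """
    config = config or RealizationConfig()
    order = {category: i for i, category in enumerate(config.category_order)}
    ranked = sorted(statements, key=lambda s: order.get(s.category, len(order)))
    realized = []
    for statement in ranked:
        prefix, _ = truncate_items(statement, config)
        realized.append((with_prefix(statement, prefix or None), realize_statement(statement, config)))
    sentences = tuple(text for _, text in realized)
    return GeneSummary(
        gene_id=gene.gene_id,
        public_name=gene.public_name,
        species=gene.species,
        sentences=sentences,
        categories=tuple(st.category for st, _ in realized),
        text=" ".join(sentences),
    )
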