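"""Structured exceptions raised by the summary engine.

Every error carries the identifying piece of data (term id, column name,
line number, ...) as an attribute so callers can react programmatically
instead of parsing messages.
"""

from __future__ import annotations


class NemadescError(Exception):
    """Base class for all engine errors."""


class OntologyCycleError(NemadescError):
    """The is_a graph of an ontology file contains a cycle."""

    def __init__(self, member: str):
        self.member = member
        super().__init__(f"ontology is_a graph contains a cycle through {member!r}")


class DanglingParentError(NemadescError):
    """An is_a line references a term id that is not defined in the file."""

    def __init__(self, term_id: str):
        self.term_id = term_id
        super().__init__(f"is_a references undefined term {term_id!r}")


class TableFormatError(NemadescError):
    """A tabular input file violates its schema."""

    def __init__(self, path: str, message: str, line: int | None = None):
        self.path = path
        self.line = line
        where = f"{path}:{line}" if line is not None else path
        super().__init__(f"{where}: {message}")


class MissingColumnError(NemadescError):
    """A required column is absent from a TSV header."""

    def __init__(self, path: str, column: str):
        self.path = path
        self.column = column
        super().__init__(f"{path}: missing required column {column!r}")


class UnknownSchemaError(NemadescError):
    def __init__(self, schema: str):
        self.schema = schema
        super().__init__(f"unknown table schema {schema!r}")


class UnknownGeneError(NemadescError):
    def __init__(self, gene_id: str):
        self.gene_id = gene_id
        super().__init__(f"gene {gene_id!r} not present in bundle")


class UnknownSpeciesError(NemadescError):
    def __init__(self, tag: str):
        self.tag = tag
        super().__init__(f"unknown species tag {tag!r}")


class UnknownFixtureError(NemadescError):
    def __init__(self, name: str):
        self.name = name
        super().__init__(f"unknown fixture {name!r}")


class UnknownTemplateError(NemadescError):
    def __init__(self, template_id: str):
        self.template_id = template_id
        super().__init__(f"no template registered for {template_id!r}")


class EmptyListError(NemadescError):
    """realize_list was handed nothing to render."""

    def __init__(self) -> None:
        super().__init__("cannot realize an empty item list")


class CountRangeError(NemadescError):
    def __init__(self, n: int):
        self.n = n
        super().__init__(f"count {n} outside the supported range 1..999")


class OutputDirectoryError(NemadescError):
    def __init__(self, path: str, reason: str):
        self.path = path
        super().__init__(f"cannot write outputs under {path!r}: {reason}")


class PipelineStageError(NemadescError):
    """Wraps any error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
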