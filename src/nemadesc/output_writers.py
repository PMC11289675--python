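"""Serialization of summaries (txt / json / tsv) and table writers.

Outputs are byte-deterministic for identical inputs: summaries are
sorted by gene id, encoding is UTF-8, newlines are "\\n".  The run
manifest sidecar additionally carries a timestamp and is therefore the
one file excluded from byte-for-byte reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from .data_model import (
    DiseaseAnnotation,
    DomainRecord,
    ExpressionAnnotation,
    GeneRecord,
    LargeScaleRecord,
    OrthologRecord,
)
from .errors import OutputDirectoryError, UnknownSchemaError
from .io_formats import TSV_SCHEMAS
from .text_realization import GeneSummary

FORMATS = ("txt", "json", "tsv")


@dataclass
class RunManifest:
    config_digest: str = ""
    input_files: list[str] = field(default_factory=list)
    gene_count: int = 0
    summary_count: int = 0
    statement_counts: dict[str, int] = field(default_factory=dict)
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.summary_count > self.gene_count:
            raise ValueError("summary count exceeds gene count")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"


def write_outputs(
    summaries: list[GeneSummary],
    out_dir: str | Path,
    formats=FORMATS,
    *,
    config_digest: str = "",
    input_files: list[str] | None = None,
    gene_count: int | None = None,
) -> RunManifest:
    """Write summaries in the requested formats plus a manifest sidecar.

    txt: one block per gene ("gene_id<TAB>public_name", the summary
    paragraph, then a blank line).  tsv: four-column table.  json: array
    of objects with the same four keys, sorted by gene id.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("", encoding="utf-8")
        probe.unlink()
    except OSError as exc:
        raise OutputDirectoryError(str(out_dir), str(exc)) from exc

    unknown = set(formats) - set(FORMATS)
    if unknown:
        raise UnknownSchemaError(",".join(sorted(unknown)))

    ordered = sorted(summaries, key=lambda s: s.gene_id)

    if "txt" in formats:
        blocks = [f"{s.gene_id}\t{s.public_name}\n{s.text}\n\n" for s in ordered]
        (out_dir / "summaries.txt").write_text("".join(blocks), encoding="utf-8")
    if "tsv" in formats:
        lines = ["gene_id\tpublic_name\tspecies\tdescription"]
        lines += [f"{s.gene_id}\t{s.public_name}\t{s.species}\t{s.text}" for s in ordered]
        (out_dir / "summaries.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    if "json" in formats:
        payload = [
            {
                "gene_id": s.gene_id,
                "public_name": s.public_name,
                "species": s.species,
                "description": s.text,
            }
            for s in ordered
        ]
        (out_dir / "summaries.json").write_text(
            json.dumps(payload, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
        )

    statement_counts = Counter(category for s in ordered for category in s.categories)
    manifest = RunManifest(
        config_digest=config_digest,
        input_files=sorted(input_files or []),
        gene_count=gene_count if gene_count is not None else len(ordered),
        summary_count=len(ordered),
        statement_counts=dict(sorted(statement_counts.items())),
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    (out_dir / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return manifest


def _record_row(schema: str, record) -> list[str]:
    if schema == "genes":
        return [record.gene_id, record.public_name, record.species]
    if schema == "disease":
        return [record.gene_id, record.disease_term_name]
    if schema == "expression":
        return [record.gene_id, record.anatomy_term_name]
    if schema == "orthology":
        return [
            record.subject_gene_id,
            record.subject_species,
            record.ortholog_gene_id,
            record.ortholog_symbol,
            record.ortholog_full_name,
            record.ortholog_species,
            ",".join(sorted(record.methods)),
        ]
    if schema == "large_scale":
        return [record.gene_id, record.kind, record.object_name, ",".join(record.study_types)]
    if schema == "domains":
        return [record.gene_id, record.domain_name, record.interpro_id]
    raise UnknownSchemaError(schema)


def write_tsv_table(records: list, schema: str, path: str | Path) -> None:
    """Inverse of :func:`nemadesc.io_formats.parse_tsv_table`."""
    if schema not in TSV_SCHEMAS:
        raise UnknownSchemaError(schema)
    lines = ["\t".join(TSV_SCHEMAS[schema])]
    lines += ["\t".join(_record_row(schema, record)) for record in records]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_RECORD_SCHEMAS = {
    GeneRecord: "genes",
    DiseaseAnnotation: "disease",
    ExpressionAnnotation: "expression",
    OrthologRecord: "orthology",
    LargeScaleRecord: "large_scale",
    DomainRecord: "domains",
}


def schema_for_record(record) -> str:
    return _RECORD_SCHEMAS[type(record)]
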