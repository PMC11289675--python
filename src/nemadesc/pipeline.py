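"""End-to-end pipeline: parse -> bundle -> build -> gate -> realize -> write.

The run is configured by a small YAML file::

    species: c_elegans          # subject species receiving summaries
    profile: ws292              # gating profile (ws292 | strict)
    inputs:
      genes: genes.tsv          # required
      ontology: mini-go.obo     # one path or a list
      gaf: annotations.gaf
      disease: disease.tsv
      expression: expression.tsv
      orthology: orthology.tsv
      large_scale: large_scale.tsv
      domains: domains.tsv
    out_dir: out
    formats: [txt, json, tsv]
    realization:                # optional overrides
      exemplar_count: 3
      several_threshold: 10

Relative input paths resolve against the config file's directory.  Genes
of the configured species are summarized in gene-id order; genes whose
gated statement list is empty produce no summary.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .data_model import AnnotationBundle, build_bundle
from .errors import NemadescError, PipelineStageError
from .io_formats import parse_gaf, parse_obo, parse_tsv_table
from .ortholog_selection import (
    select_best_human_orthologs,
    select_best_nematode_ortholog,
)
from .output_writers import FORMATS, RunManifest, write_outputs
from .species import ELEGANS, check_species
from .statement_generation import (
    PROFILES,
    GatingProfile,
    Statement,
    apply_gating,
    build_curated_expression_statement,
    build_domain_statement,
    build_elegans_transfer_statement,
    build_go_statements,
    build_large_scale_statements,
    build_ortholog_transfer_statements,
    build_orthology_statement,
)
from .text_realization import GeneSummary, RealizationConfig, assemble_summary

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    species: str
    profile: str = "ws292"
    inputs: dict[str, object] = field(default_factory=dict)
    out_dir: Path = Path("out")
    formats: tuple[str, ...] = FORMATS
    realization: RealizationConfig = field(default_factory=RealizationConfig)
    config_path: Path | None = None

    @classmethod
    def from_yaml(cls, config_path: str | Path) -> "PipelineConfig":
        config_path = Path(config_path)
        raw = yaml.safe_load(config_path.read_text(encoding="utf-8")) or {}
        base = config_path.parent

        inputs = {}
        for key, value in (raw.get("inputs") or {}).items():
            if isinstance(value, list):
                inputs[key] = [base / v for v in value]
            else:
                inputs[key] = base / value

        realization_kwargs = raw.get("realization") or {}
        return cls(
            species=check_species(str(raw["species"])),
            profile=str(raw.get("profile", "ws292")),
            inputs=inputs,
            out_dir=base / raw.get("out_dir", "out"),
            formats=tuple(raw.get("formats", FORMATS)),
            realization=RealizationConfig(**realization_kwargs),
            config_path=config_path,
        )


def build_statements(
    bundle: AnnotationBundle,
    gene_id: str,
    go_counts=None,
) -> list[Statement]:
    """All statements the data supports for one gene, ungated.

    Build order fixes the within-category order of the final summary.
    """
    gene = bundle.genes[gene_id]
    statements: list[Statement] = []
    statements += build_go_statements(bundle, gene_id)

    curated = build_curated_expression_statement(bundle, gene_id)
    if curated:
        statements.append(curated)

    if gene.species == ELEGANS:
        ranked = select_best_human_orthologs(bundle, gene_id)
        statements += build_ortholog_transfer_statements(bundle, gene_id, ranked)
    else:
        if go_counts is None:
            go_counts = bundle.go_annotation_counts()
        ranked = select_best_nematode_ortholog(bundle, gene_id, go_counts)
        transfer = build_elegans_transfer_statement(bundle, gene_id, ranked)
        if transfer:
            statements.append(transfer)

    statements += build_large_scale_statements(bundle, gene_id)

    domain = build_domain_statement(bundle, gene_id)
    if domain:
        statements.append(domain)

    orthology = build_orthology_statement(bundle, gene_id, ranked)
    if orthology:
        statements.append(orthology)
    return statements


def summarize_gene(
    bundle: AnnotationBundle,
    gene_id: str,
    profile: GatingProfile,
    realization: RealizationConfig | None = None,
    go_counts=None,
) -> GeneSummary:
    statements = build_statements(bundle, gene_id, go_counts=go_counts)
    gated = apply_gating(statements, gene_id, bundle, profile)
    return assemble_summary(bundle.genes[gene_id], gated, realization or RealizationConfig())


def load_bundle(config: PipelineConfig) -> AnnotationBundle:
    """Parse every configured input file into an AnnotationBundle."""
    inputs = config.inputs

    def stage(name, fn, *args):
        try:
            return fn(*args)
        except NemadescError:
            raise
        except Exception as exc:  # noqa: BLE001 - wrap with stage name
            raise PipelineStageError(name, exc) from exc

    ontology_paths = inputs.get("ontology", [])
    if isinstance(ontology_paths, (str, Path)):
        ontology_paths = [ontology_paths]
    ontologies = [stage("parse_obo", parse_obo, p) for p in ontology_paths]

    genes = stage("parse_genes", parse_tsv_table, inputs["genes"], "genes")
    for gene in genes:
        check_species(gene.species)

    go_annotations = []
    if "gaf" in inputs:
        merged_terms = {tid: t for onto in ontologies for tid, t in onto.terms.items()}
        from .data_model import Ontology

        go_annotations = stage("parse_gaf", parse_gaf, inputs["gaf"], Ontology(merged_terms))
        if go_annotations.dropped:
            logger.info("parse_gaf: dropped %d rows", go_annotations.dropped)

    def table(key, schema):
        if key not in inputs:
            return []
        return stage(f"parse_{schema}", parse_tsv_table, inputs[key], schema)

    bundle = stage(
        "build_bundle",
        build_bundle,
        genes,
        ontologies,
        list(go_annotations),
        table("disease", "disease"),
        table("expression", "expression"),
        table("orthology", "orthology"),
        table("large_scale", "large_scale"),
        table("domains", "domains"),
    )
    if bundle.dangling:
        logger.info("bundle: %d dangling gene references", len(bundle.dangling))
    return bundle


def run_pipeline(
    config_path: str | Path,
    out_dir: str | Path | None = None,
    formats: tuple[str, ...] | None = None,
    profile: str | None = None,
) -> RunManifest:
    """Execute the full pipeline described by a YAML config file."""
    config = PipelineConfig.from_yaml(config_path)
    if out_dir is not None:
        config.out_dir = Path(out_dir)
    if formats is not None:
        config.formats = tuple(formats)
    if profile is not None:
        config.profile = profile

    gating = PROFILES[config.profile]
    bundle = load_bundle(config)

    subject_ids = sorted(
        gid for gid, gene in bundle.genes.items() if gene.species == config.species
    )
    go_counts = bundle.go_annotation_counts()
    summaries = []
    for gene_id in subject_ids:
        summary = summarize_gene(bundle, gene_id, gating, config.realization, go_counts)
        if summary.sentences:
            summaries.append(summary)

    digest = ""
    if config.config_path is not None:
        digest = hashlib.sha256(config.config_path.read_bytes()).hexdigest()
    input_files = [str(p) for v in config.inputs.values() for p in (v if isinstance(v, list) else [v])]
    return write_outputs(
        summaries,
        config.out_dir,
        config.formats,
        config_digest=digest,
        input_files=input_files,
        gene_count=len(subject_ids),
    )
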