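"""Statement builders and the gating rules."""

import itertools

import pytest

from nemadesc.data_model import (
    DiseaseAnnotation,
    DomainRecord,
    ExpressionAnnotation,
    GeneRecord,
    GOAnnotation,
    LargeScaleRecord,
    OrthologRecord,
    build_bundle,
)
from nemadesc.ortholog_selection import (
    RankedOrthologSet,
    select_best_human_orthologs,
    select_best_nematode_ortholog,
)
from nemadesc.statement_generation import (
    PROFILES,
    apply_gating,
    build_curated_expression_statement,
    build_domain_statement,
    build_elegans_transfer_statement,
    build_go_statements,
    build_large_scale_statements,
    build_ortholog_transfer_statements,
    build_orthology_statement,
)


def gene(gene_id="g1", species="c_elegans"):
    return GeneRecord(gene_id, gene_id, species)


def go(gene_id, term_id, aspect="molecular_function", evidence="IEA", qualifier="enables"):
    return GOAnnotation(gene_id, term_id, aspect, evidence, qualifier)


class TestGoStatements:
    def test_no_annotations_no_statements(self):
        bundle = build_bundle([gene()])
        assert build_go_statements(bundle, "g1") == []

    def test_fem2_fixture_predicted_enable(self, fixture_bundles):
        (statement,) = build_go_statements(fixture_bundles["fem2"], "cbr-fem-2")
        assert statement.template_id == "predicted_enables"
        assert statement.items == ("protein serine/threonine phosphatase activity",)

    def test_group_counts_match_brute_force(self):
        """Grouping over (aspect, qualifier, evidence class) against a
        brute-force group-by computed here from first principles."""
        annotations = [
            go("g1", f"T:{i}", aspect=a, evidence=e, qualifier=q)
            for i, (a, e, q) in enumerate(
                itertools.product(
                    ("molecular_function", "biological_process"),
                    ("IEA", "IDA", "ISS"),
                    ("enables", "involved_in"),
                )
            )
        ]
        bundle = build_bundle([gene()], go_annotations=annotations)
        statements = build_go_statements(bundle, "g1")

        def ev_class(code):
            return "pred" if code in {"IEA", "ISS", "ISO", "IBA", "RCA"} else "exp"

        expected_groups = {
            (a.aspect, a.qualifier, ev_class(a.evidence_code)) for a in annotations
        }
        assert len(statements) == len(expected_groups)

    def test_five_iea_annotations_one_statement(self):
        annotations = [go("g1", f"T:{i}") for i in range(5)]
        bundle = build_bundle([gene()], go_annotations=annotations)
        (statement,) = build_go_statements(bundle, "g1")
        assert statement.total_count == 5
        assert len(statement.items) == 5


class TestCuratedExpression:
    def test_absent_without_records(self):
        assert build_curated_expression_statement(build_bundle([gene()]), "g1") is None

    def test_act3_items_in_input_order(self, fixture_bundles):
        statement = build_curated_expression_statement(fixture_bundles["act3"], "cel-act-3")
        assert statement.items == ("gonad", "head")

    def test_duplicate_rows_deduplicated(self):
        records = [
            ExpressionAnnotation("g1", "gonad"),
            ExpressionAnnotation("g1", "gonad"),
            ExpressionAnnotation("g1", "head"),
        ]
        bundle = build_bundle([gene()], expression_annotations=records)
        statement = build_curated_expression_statement(bundle, "g1")
        assert statement.items == ("gonad", "head")


def human_ortholog(subject, symbol, gene_id, n_methods=5):
    return OrthologRecord(
        subject_gene_id=subject,
        subject_species="c_elegans",
        ortholog_gene_id=gene_id,
        ortholog_symbol=symbol,
        ortholog_full_name=f"{symbol} name",
        ortholog_species="human",
        methods=frozenset(f"m{i}" for i in range(n_methods)),
    )


class TestOrthologTransfer:
    def test_empty_ranked_set_builds_nothing(self):
        bundle = build_bundle([gene()])
        empty = RankedOrthologSet("g1", (), "human_max_methods")
        assert build_ortholog_transfer_statements(bundle, "g1", empty) == []

    def test_act3_statement_shapes(self, fixture_bundles):
        bundle = fixture_bundles["act3"]
        ranked = select_best_human_orthologs(bundle, "cel-act-3")
        statements = build_ortholog_transfer_statements(bundle, "cel-act-3", ranked)
        by_template = {s.template_id: s for s in statements}
        assert by_template["ortholog_disease"].total_count == 10
        assert by_template["ortholog_disease"].items[:3] == (
            "Baraitser-Winter syndrome 1",
            "Baraitser-Winter syndrome 2",
            "autosomal dominant nonsyndromic deafness 20",
        )
        assert by_template["human_contributes"].items == ("nucleosomal DNA binding activity",)
        assert by_template["human_enables"].total_count == 10
        assert by_template["structural_constituent"].items == (
            "structural constituent of postsynaptic actin cytoskeleton",
        )
        # fixed within-category order: contributes, enables, structural
        templates = [s.template_id for s in statements if s.category == "ortholog_function_transfer"]
        assert templates == ["human_contributes", "human_enables", "structural_constituent"]

    def test_tied_orthologs_merge_disease_union(self):
        orthologs = [
            human_ortholog("g1", "A1", "h1"),
            human_ortholog("g1", "A2", "h2"),
        ]
        diseases = [
            DiseaseAnnotation("h1", "shared disease"),
            DiseaseAnnotation("h1", "only-h1 disease"),
            DiseaseAnnotation("h2", "shared disease"),
            DiseaseAnnotation("h2", "only-h2 disease"),
        ]
        bundle = build_bundle([gene()], ortholog_records=orthologs, disease_annotations=diseases)
        ranked = select_best_human_orthologs(bundle, "g1")
        statements = build_ortholog_transfer_statements(bundle, "g1", ranked)
        (disease_statement,) = [s for s in statements if s.category == "ortholog_disease"]
        # deduplicated union, first-seen order
        assert disease_statement.items == (
            "shared disease", "only-h1 disease", "only-h2 disease",
        )


class TestElegansTransfer:
    def test_empty_ranked_absent(self):
        bundle = build_bundle([gene(species="c_briggsae")])
        empty = RankedOrthologSet("g1", (), "nematode_methods_then_go")
        assert build_elegans_transfer_statement(bundle, "g1", empty) is None

    def test_fem2_three_processes(self, fixture_bundles):
        bundle = fixture_bundles["fem2"]
        ranked = select_best_nematode_ortholog(bundle, "cbr-fem-2", bundle.go_annotation_counts())
        statement = build_elegans_transfer_statement(bundle, "cbr-fem-2", ranked)
        assert statement.items == (
            "male sex determination",
            "masculinization of hermaphroditic germ-line",
            "nematode male tail tip morphogenesis",
        )
        assert statement.qualifiers == ("C. elegans", "fem-2")

    def test_built_even_when_gating_would_drop_other_categories(self, fixture_bundles):
        """Building and gating are separate: the fem2 subject has GO data,
        yet the transfer statement is still built (it is never gated)."""
        bundle = fixture_bundles["fem2"]
        ranked = select_best_nematode_ortholog(bundle, "cbr-fem-2", bundle.go_annotation_counts())
        statement = build_elegans_transfer_statement(bundle, "cbr-fem-2", ranked)
        gated = apply_gating([statement], "cbr-fem-2", bundle, PROFILES["strict"])
        assert gated == [statement]


class TestLargeScale:
    def test_no_records_no_statements(self):
        assert build_large_scale_statements(build_bundle([gene()]), "g1") == []

    def test_abt3_three_statements(self, fixture_bundles):
        statements = build_large_scale_statements(fixture_bundles["abt3"], "cel-abt-3")
        by_category = {s.category: s for s in statements}
        assert len(statements) == 3
        enrichment = by_category["largescale_enrichment"]
        assert enrichment.items == ("male",)
        assert enrichment.qualifiers == ("RNA-seq",)
        chemical = by_category["largescale_chemical_regulation"]
        assert chemical.total_count == 7
        assert chemical.qualifiers == ("microarray", "RNA-seq")

    def test_object_dedup_and_study_union_order(self):
        records = [
            LargeScaleRecord("g1", "gene_regulation", "x-1", ("RNA-seq",)),
            LargeScaleRecord("g1", "gene_regulation", "x-1", ("microarray",)),
            LargeScaleRecord("g1", "gene_regulation", "x-2", ("tiling array", "RNA-seq")),
        ]
        bundle = build_bundle([gene()], large_scale_records=records)
        (statement,) = build_large_scale_statements(bundle, "g1")
        assert statement.items == ("x-1", "x-2")
        assert statement.total_count == 2
        assert statement.qualifiers == ("RNA-seq", "microarray", "tiling array")


class TestDomainsAndOrthology:
    def test_domains_absent_without_records(self):
        assert build_domain_statement(build_bundle([gene()]), "g1") is None

    def test_cjp_three_domains(self, fixture_bundles):
        statement = build_domain_statement(fixture_bundles["cjp_gid1"], "cjp-gid-1")
        assert statement.items == (
            "SPRY domain",
            "B30.2/SPRY domain superfamily",
            "Concanavalin A-like lectin/glucanase domain superfamily",
        )

    def test_act3_four_domains_untruncated(self, fixture_bundles):
        statement = build_domain_statement(fixture_bundles["act3"], "cel-act-3")
        assert len(statement.items) == 4
        assert statement.total_count == 4

    def test_orthology_statement_forms(self, fixture_bundles):
        act3 = fixture_bundles["act3"]
        ranked = select_best_human_orthologs(act3, "cel-act-3")
        statement = build_orthology_statement(act3, "cel-act-3", ranked)
        assert statement.items == ("human ACTB (actin beta)",)

        cjp = fixture_bundles["cjp_gid1"]
        ranked = select_best_nematode_ortholog(cjp, "cjp-gid-1", {})
        statement = build_orthology_statement(cjp, "cjp-gid-1", ranked)
        assert statement.items == ("C. elegans gid-1",)

    def test_orthology_absent_when_ranked_empty(self):
        bundle = build_bundle([gene()])
        empty = RankedOrthologSet("g1", (), "human_max_methods")
        assert build_orthology_statement(bundle, "g1", empty) is None


# --- gating ------------------------------------------------------------------

GATED = (
    "ortholog_disease",
    "ortholog_function_transfer",
    "largescale_enrichment",
    "largescale_gene_regulation",
    "largescale_chemical_regulation",
    "protein_domain",
)
UNGATED = ("go_function", "curated_expression", "orthology", "elegans_process_transfer")


def bundle_for_state(has_go: bool, has_expression: bool):
    annotations = [go("g1", "T:1")] if has_go else []
    expression = [ExpressionAnnotation("g1", "gonad")] if has_expression else []
    return build_bundle([gene()], go_annotations=annotations, expression_annotations=expression)


def all_category_statements(bundle):
    """One synthetic statement per category, built through real builders."""
    from nemadesc.statement_generation import Statement

    statements = []
    for category, template in [
        ("go_function", "predicted_enables"),
        ("curated_expression", "expressed_in_anatomy"),
        ("ortholog_disease", "ortholog_disease"),
        ("ortholog_function_transfer", "human_enables"),
        ("largescale_enrichment", "enrichment"),
        ("largescale_gene_regulation", "gene_regulation"),
        ("largescale_chemical_regulation", "chemical_regulation"),
        ("protein_domain", "protein_domain"),
        ("orthology", "orthology"),
        ("elegans_process_transfer", "process_transfer"),
    ]:
        statements.append(
            Statement("g1", category, template, ("item",), 1, qualifiers=("q", "r"))
        )
    return statements


def expected_survivors(profile_name, has_go, has_expression):
    survivors = set(UNGATED)
    if not has_go:
        survivors |= {"ortholog_disease", "ortholog_function_transfer"}
        largescale_blocked = has_expression if profile_name == "strict" else False
        if not largescale_blocked:
            survivors |= {
                "largescale_enrichment",
                "largescale_gene_regulation",
                "largescale_chemical_regulation",
                "protein_domain",
            }
    return survivors


@pytest.mark.parametrize("profile_name", ["strict", "ws292"])
@pytest.mark.parametrize("has_go,has_expression", list(itertools.product([False, True], repeat=2)))
def test_gating_truth_table(profile_name, has_go, has_expression):
    bundle = bundle_for_state(has_go, has_expression)
    statements = all_category_statements(bundle)
    survivors = apply_gating(statements, "g1", bundle, PROFILES[profile_name])
    assert {s.category for s in survivors} == expected_survivors(
        profile_name, has_go, has_expression
    )


def test_gating_filters_without_mutating():
    bundle = bundle_for_state(True, True)
    statements = all_category_statements(bundle)
    survivors = apply_gating(statements, "g1", bundle, PROFILES["strict"])
    for statement in survivors:
        assert statement in statements  # same objects, not copies
    order = [statements.index(s) for s in survivors]
    assert order == sorted(order)


def test_builders_never_emit_empty_items():
    from nemadesc.fixtures import make_random_bundle
    from nemadesc.pipeline import build_statements

    bundle = make_random_bundle(seed=11, n_genes=30)
    for gene_id in bundle.genes:
        for statement in build_statements(bundle, gene_id):
            assert statement.items
            assert statement.total_count >= len(statement.items)
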