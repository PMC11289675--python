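"""Best-ortholog selection.

Two criteria are implemented, mirroring how summaries are sourced:

* For C. elegans genes, *all* human orthologs supported by the maximal
  number of prediction methods are kept (ties are kept, their annotations
  later merged).
* For the other nematode species, a single best ortholog is chosen from
  related nematodes by (method count, GO-annotation count of the ortholog
  gene), with deterministic tie-breaks: C. elegans before other species,
  then species tag, then ortholog symbol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .data_model import AnnotationBundle, OrthologRecord
from .species import ELEGANS, HUMAN, species_sort_key


@dataclass(frozen=True)
class RankedOrthologSet:
    subject_gene_id: str
    selected: tuple[OrthologRecord, ...]
    criterion: str  # "human_max_methods" | "nematode_methods_then_go"

    def __bool__(self) -> bool:
        return bool(self.selected)


def select_best_human_orthologs(bundle: AnnotationBundle, gene_id: str) -> RankedOrthologSet:
    """All human orthologs attaining the maximal prediction-method count.

    Returned records are ordered lexicographically by ortholog symbol, so
    the selection is invariant under input permutation.
    """
    bundle._require_gene(gene_id)
    candidates = [r for r in bundle.orthologs_for(gene_id) if r.ortholog_species == HUMAN]
    if not candidates:
        return RankedOrthologSet(gene_id, (), "human_max_methods")
    best = max(len(r.methods) for r in candidates)
    selected = sorted(
        (r for r in candidates if len(r.methods) == best),
        key=lambda r: (r.ortholog_symbol, r.ortholog_gene_id),
    )
    return RankedOrthologSet(gene_id, tuple(selected), "human_max_methods")


def select_best_nematode_ortholog(
    bundle: AnnotationBundle,
    gene_id: str,
    go_annotation_counts: Mapping[str, int],
) -> RankedOrthologSet:
    """The single best nematode ortholog for a non-elegans subject gene.

    Candidates are ranked by prediction-method count, then by the number
    of GO annotations carried by the ortholog gene (method count
    dominates); remaining ties fall to species priority (C. elegans
    first, then species tag) and ortholog symbol.
    """
    bundle._require_gene(gene_id)
    candidates = [r for r in bundle.orthologs_for(gene_id) if r.ortholog_species != HUMAN]
    if not candidates:
        return RankedOrthologSet(gene_id, (), "nematode_methods_then_go")

    def rank_key(record: OrthologRecord):
        return (
            -len(record.methods),
            -go_annotation_counts.get(record.ortholog_gene_id, 0),
            species_sort_key(record.ortholog_species),
            record.ortholog_symbol,
            record.ortholog_gene_id,
        )

    winner = min(candidates, key=rank_key)
    return RankedOrthologSet(gene_id, (winner,), "nematode_methods_then_go")
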