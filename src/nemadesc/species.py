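"""Species registry: tags used in input tables and their display names.

The registry covers the ten WormBase nematode species that receive
automated summaries plus human, which appears only as an ortholog species.
Display names are the forms used inside rendered sentences ("C. elegans",
"human"); tags are the stable lowercase identifiers used in input files.
"""

from __future__ import annotations

from .errors import UnknownSpeciesError

ELEGANS = "c_elegans"
HUMAN = "human"

#: tag -> display name
SPECIES: dict[str, str] = {
    "c_elegans": "C. elegans",
    "c_brenneri": "C. brenneri",
    "c_briggsae": "C. briggsae",
    "c_japonica": "C. japonica",
    "c_remanei": "C. remanei",
    "p_pacificus": "P. pacificus",
    "b_malayi": "B. malayi",
    "o_volvulus": "O. volvulus",
    "s_ratti": "S. ratti",
    "t_muris": "T. muris",
    "human": "human",
}


def display_name(tag: str) -> str:
    try:
        return SPECIES[tag]
    except KeyError:
        raise UnknownSpeciesError(tag) from None


def check_species(tag: str) -> str:
    """Validate a species tag, returning it unchanged."""
    if tag not in SPECIES:
        raise UnknownSpeciesError(tag)
    return tag


def species_sort_key(tag: str) -> tuple[int, str]:
    """C. elegans ranks before every other species; the rest alphabetical."""
    return (0 if tag == ELEGANS else 1, tag)
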