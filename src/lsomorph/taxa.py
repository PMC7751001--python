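"""Species metadata: taxon names and binary locomotor-lifestyle flags."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidInputError

#: locomotor-lifestyle categories, in canonical column order; "float" is the
#: CSV column for the attribute ``float_``
FLAG_COLUMNS = ("terrestrial", "perching", "fly", "float", "dive")


def flag_attr(column: str) -> str:
    """Attribute name on :class:`SpeciesRecord` for a flag column."""
    if column not in FLAG_COLUMNS:
        raise InvalidInputError(f"unknown locomotor flag {column!r}; expected one of {FLAG_COLUMNS}")
    return "float_" if column == "float" else column


@dataclass(frozen=True)
class SpeciesRecord:
    """One species with yes/no locomotor-lifestyle categorisations.

    Flags record whether a locomotor mode is central to the species'
    lifestyle (not mere capability): e.g. a swift flies but neither perches
    nor walks.  ``species_id`` is the binomial with an underscore
    (``Apus_pacificus``) so it can double as a phylogeny tip label.
    """

    species_id: str
    order: str = ""
    family: str = ""
    terrestrial: bool = False
    perching: bool = False
    fly: bool = False
    float_: bool = False
    dive: bool = False

    def flag(self, column: str) -> bool:
        return bool(getattr(self, flag_attr(column)))
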