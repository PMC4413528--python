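"""A small built-in table of known fungal secondary metabolites.

Used by the synthetic-data generator to plant compounds with real molecular
formulas, so the dereplication stage has genuine masses to recover. Formulas
are standard literature values for well-characterized Aspergillus/Penicillium
metabolites; the first entry is terezine D, the stable astechrome biosynthetic
intermediate.

This is a convenience fixture, not a dereplication database: real screens
should load a comprehensive compound table via the CSV interface.
"""

from __future__ import annotations

from .derep import CompoundRecord

#: (name, molecular formula) pairs.
FUNGAL_METABOLITES: tuple[tuple[str, str], ...] = (
    ("terezine D", "C19H23N3O2"),
    ("sterigmatocystin", "C18H12O6"),
    ("lovastatin", "C24H36O5"),
    ("geodin", "C17H12O7"),
    ("asperfuranone", "C19H22O5"),
    ("emodin", "C15H10O5"),
    ("citrinin", "C13H14O5"),
    ("gliotoxin", "C13H14N2O4S2"),
    ("fumagillin", "C26H34O7"),
    ("aflatoxin B1", "C17H12O6"),
    ("asperthecin", "C15H8O8"),
    ("austinol", "C25H30O8"),
    ("butyrolactone I", "C24H24O7"),
    ("terretonin", "C26H32O9"),
    ("territrem B", "C29H34O9"),
    ("questin", "C16H12O5"),
    ("penicillic acid", "C8H10O4"),
    ("mycophenolic acid", "C17H20O6"),
    ("ochratoxin A", "C20H18ClNO6"),
    ("cyclopiazonic acid", "C20H20N2O3"),
    ("fumitremorgin C", "C22H25N3O3"),
    ("chaetoglobosin A", "C32H36N2O5"),
    ("paxilline", "C27H33NO4"),
    ("aspyridone A", "C17H21NO4"),
)


def builtin_database(source: str = "builtin") -> list[CompoundRecord]:
    """Return the built-in metabolite table as compound records."""
    return [CompoundRecord(name=n, formula=f, source=source) for n, f in FUNGAL_METABOLITES]
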