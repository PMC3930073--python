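"""Canonical naming for the 16 US EPA priority PAH analytes.

PAH names in the literature vary in bracket style ("Benz[a]anthracene" vs
"benzo(a)anthracene"), hyphenation and capitalisation.  All package-internal
lookups go through :func:`canonical_name`, which collapses these variants to
a single key so that concentration tables and PEF tables from different
sources join correctly.
"""

from __future__ import annotations

import re

# Display names, in the conventional elution/ring-count order.
EPA16: tuple[str, ...] = (
    "Naphthalene",
    "Acenaphthylene",
    "Acenaphthene",
    "Fluorene",
    "Phenanthrene",
    "Anthracene",
    "Fluoranthene",
    "Pyrene",
    "Benz[a]anthracene",
    "Chrysene",
    "Benzo[b]fluoranthene",
    "Benzo[k]fluoranthene",
    "Benzo[a]pyrene",
    "Indeno[1,2,3-cd]pyrene",
    "Dibenz[a,h]anthracene",
    "Benzo[g,h,i]perylene",
)

_STRIP = re.compile(r"[\s\[\]\(\),\.\-_]+")


def canonical_name(name: str) -> str:
    """Return a canonical lookup key for a PAH analyte name.

    Lowercases, strips brackets/hyphens/spaces and collapses the
    "benzo"/"benz" spelling variants, so e.g. ``Benz[a]anthracene`` and
    ``benzo(a)anthracene`` map to the same key.
    """
    key = _STRIP.sub("", name.strip().lower())
    # "benzo[a]pyrene" -> "benzapyrene"; "dibenzo[a,h]anthracene" -> "dibenzahanthracene"
    key = key.replace("benzo", "benz")
    return key


CANONICAL_EPA16: frozenset[str] = frozenset(canonical_name(n) for n in EPA16)

_DISPLAY: dict[str, str] = {canonical_name(n): n for n in EPA16}

BENZO_A_PYRENE = canonical_name("Benzo[a]pyrene")


def display_name(canonical: str) -> str:
    """Conventional display spelling for a canonical key (falls back to the key)."""
    return _DISPLAY.get(canonical, canonical)


def is_epa16(name: str) -> bool:
    return canonical_name(name) in CANONICAL_EPA16
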