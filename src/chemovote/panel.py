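"""The analyte panel: cannabinoids, terpenes, and the total-terpenes aggregate.

All concentrations throughout the package are percent dry weight (% w/w).
Cannabinoid values are "total potential" figures (acid + neutral forms combined,
as reported by the testing labs); no decarboxylation arithmetic is performed.

Analyte names are canonicalized against this panel. Lab reports mix Greek
letters with ASCII stand-ins ("α-Terpinene" vs "a-Terpinene") and vary in
case and hyphenation, so :func:`canonical_analyte` normalizes all of those
to a single spelling before any value is stored.
"""

from __future__ import annotations

CANNABINOIDS: tuple[str, ...] = (
    "Δ9-Tetrahydrocannabinol",
    "Cannabidiol",
    "Cannabigerol",
    "Cannabichromene",
)

TOTAL_TERPENES = "Total terpenes"

TERPENES: tuple[str, ...] = (
    "α-Pinene",
    "Camphene",
    "Sabinene",
    "β-Pinene",
    "Myrcene",
    "α-Phellandrene",
    "3-Carene",
    "D-Limonene",
    "Eucalyptol",
    "β-Ocimene",
    "Terpinolene",
    "α-Terpinene",
    "γ-Terpinene",
    "Sabinene hydrate",
    "Fenchone",
    "Linalool",
    "Fenchol",
    "Borneol",
    "α-Terpineol",
    "Geraniol",
    "γ-Terpineol",
    "Nerol",
    "β-Caryophyllene",
    "Caryophyllene oxide",
    "Humulene",
    "Valencene",
    "trans-Nerolidol",
    "Cedrol",
    "Guaiol",
    "α-Bisabolol",
)

#: Full reporting panel in canonical (report-table) order.
PANEL: tuple[str, ...] = CANNABINOIDS + (TOTAL_TERPENES,) + TERPENES

#: Terpene analytes a GC-MS panel may omit depending on the lab's method
#: (used as the default per-lot coverage mask in the simulator).
OPTIONAL_GCMS_TERPENES: frozenset[str] = frozenset(
    {"trans-Nerolidol", "Eucalyptol", "γ-Terpinene", "α-Terpinene"}
)


class UnknownAnalyteError(KeyError):
    """Raised when a name cannot be matched to the configured panel."""


_GREEK_TO_ASCII = str.maketrans({"α": "a", "β": "b", "γ": "y", "Δ": "d", "δ": "d"})


def _norm(name: str) -> str:
    s = name.strip().casefold().translate(_GREEK_TO_ASCII)
    for ch in (" ", "-", "_", "."):
        s = s.replace(ch, "")
    return s


_ALIASES = {
    "thc": "Δ9-Tetrahydrocannabinol",
    "d9thc": "Δ9-Tetrahydrocannabinol",
    "delta9thc": "Δ9-Tetrahydrocannabinol",
    "delta9tetrahydrocannabinol": "Δ9-Tetrahydrocannabinol",
    "cbd": "Cannabidiol",
    "cbg": "Cannabigerol",
    "cbc": "Cannabichromene",
    "limonene": "D-Limonene",
    "betacaryophyllene": "β-Caryophyllene",
    "alphahumulene": "Humulene",
    "nerolidol": "trans-Nerolidol",
    "transnerolidol": "trans-Nerolidol",
    "1,8cineole": "Eucalyptol",
}

_LOOKUP: dict[str, str] = {}
for _name in PANEL:
    _LOOKUP[_norm(_name)] = _name
for _alias, _name in _ALIASES.items():
    _LOOKUP.setdefault(_norm(_alias), _name)


def canonical_analyte(name: str) -> str:
    """Return the canonical panel spelling for ``name``.

    Raises
    ------
    UnknownAnalyteError
        If the name does not match any panel analyte or known alias.
    """
    try:
        return _LOOKUP[_norm(name)]
    except KeyError:
        raise UnknownAnalyteError(
            f"unknown analyte {name!r}: not in the configured panel"
        ) from None


def is_terpene(name: str) -> bool:
    """True for individual terpenes (the total-terpenes aggregate excluded)."""
    return canonical_analyte(name) in TERPENES


def is_cannabinoid(name: str) -> bool:
    return canonical_analyte(name) in CANNABINOIDS


def panel_sort_key(name: str):
    """Sort key placing analytes in canonical panel order; unknowns last."""
    try:
        return (0, PANEL.index(canonical_analyte(name)))
    except UnknownAnalyteError:
        return (1, name)
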