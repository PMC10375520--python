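"""Supported elements and the covalent radius table.

The environment database covers the 12 elements found in small-molecule
organic crystals with predicted shifts: H, C, N, O, S, F, P, Cl, Na, Ca,
Mg, K.  The radius table (Cordero-style single-bond covalent radii, Å) is
shipped as a packaged data file and may be extended at run time.
"""

from __future__ import annotations

import json
from importlib import resources

__all__ = ["SUPPORTED_ELEMENTS", "covalent_radii", "covalent_radius"]


def _load_radii() -> dict[str, float]:
    with resources.files("shiftmaps.data").joinpath("covalent_radii.json").open() as fh:
        return {k: float(v) for k, v in json.load(fh).items()}


#: element symbol -> covalent radius in Å
covalent_radii: dict[str, float] = _load_radii()

#: the default set of supported element symbols
SUPPORTED_ELEMENTS: frozenset[str] = frozenset(covalent_radii)


def covalent_radius(element: str, table: dict[str, float] | None = None) -> float:
    """Covalent radius in Å for *element*, from *table* or the packaged default."""
    tab = covalent_radii if table is None else table
    try:
        return tab[element]
    except KeyError:
        raise KeyError(f"no covalent radius for element {element!r}") from None
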