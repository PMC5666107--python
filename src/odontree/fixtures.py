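"""The 23-family loricarioid/siluriform reference dataset.

This bundles the family-level time-calibrated tree and the two morphological
character matrices (trunk dermal bony plates, odontode cover) used for the
ancestral-state reconstructions.

Provenance of node ages: the crown ages of the Loricarioidei clades and the
two deepest siluriform splits come from the published analysis (source
``"primary"``); crown ages inside the outgroup (Siluroidei) were only
published as supplementary material and are represented here by placeholder
values consistent with the published clade structure and the siluriform
chronogram literature (source ``"placeholder"``).  Reports generated from
this fixture must carry that flag through.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .charmatrix import CharacterMatrix
from .treeio import Chronogram, CladeAgeTable, build_chronogram

__all__ = [
    "LORICARIOID_FAMILIES",
    "OUTGROUP_FAMILIES",
    "NAMED_CLADES",
    "FixtureBundle",
    "loricarioid_fixture",
]

LORICARIOID_FAMILIES = [
    "Nematogenyidae",
    "Trichomycteridae",
    "Callichthyidae",
    "Loricariidae",
    "Scoloplacidae",
    "Astroblepidae",
]

OUTGROUP_FAMILIES = [
    "Diplomystidae",
    "Doradidae",
    "Auchenipteridae",
    "Aspredinidae",
    "Pseudopimelodidae",
    "Pimelodidae",
    "Heptapteridae",
    "Ariidae",
    "Amphiliidae",
    "Schilbeidae",
    "Mochokidae",
    "Ictaluridae",
    "Sisoridae",
    "Erethistidae",
    "Akysidae",
    "Amblycipitidae",
    "Bagridae",
]

#: families with trunk dermal bony plates present
PLATE_PRESENT = {
    "Amphiliidae",
    "Aspredinidae",
    "Callichthyidae",
    "Doradidae",
    "Loricariidae",
    "Scoloplacidae",
    "Sisoridae",
}

#: default 4-state odontode codes (0 none, 1 head only, 2 trunk only, 3 both)
DEFAULT_ODONTODE_CODES = {
    "Loricariidae": "3",
    "Astroblepidae": "3",
    "Callichthyidae": "3",
    "Scoloplacidae": "3",
    "Nematogenyidae": "2",
    "Trichomycteridae": "1",
}

TOPOLOGY = (
    "(((Nematogenyidae,Trichomycteridae),"
    "(Callichthyidae,(Loricariidae,(Scoloplacidae,Astroblepidae)))),"
    "(Diplomystidae,"
    "((((Doradidae,Auchenipteridae),Aspredinidae),"
    "((Pseudopimelodidae,(Pimelodidae,Heptapteridae)),Ariidae)),"
    "(Amphiliidae,(Schilbeidae,(Mochokidae,(Ictaluridae,"
    "((Sisoridae,Erethistidae),(Akysidae,(Amblycipitidae,Bagridae))))))))));"
)

#: clade name -> tips whose MRCA defines the clade
NAMED_CLADES: dict[str, tuple[str, ...]] = {
    "Siluriformes": ("Loricariidae", "Bagridae"),
    "Diplomystidae+Siluroidei": ("Diplomystidae", "Bagridae"),
    "Siluroidei": ("Doradidae", "Bagridae"),
    "Loricarioidei": ("Nematogenyidae", "Loricariidae"),
    "Nematogenyidae+Trichomycteridae": ("Nematogenyidae", "Trichomycteridae"),
    "CSAL": ("Callichthyidae", "Loricariidae"),
    "SAL": ("Loricariidae", "Scoloplacidae"),
    "Scoloplacidae+Astroblepidae": ("Scoloplacidae", "Astroblepidae"),
    "Doradidae+Auchenipteridae+Aspredinidae": ("Doradidae", "Aspredinidae"),
    "Doradidae+Auchenipteridae": ("Doradidae", "Auchenipteridae"),
}

# (defining tips, age Ma, source)
_AGE_ENTRIES: list[tuple[tuple[str, str], float, str]] = [
    # published crown ages
    (("Loricariidae", "Bagridae"), 146.7, "primary"),        # Siluriformes root
    (("Diplomystidae", "Bagridae"), 142.2, "primary"),
    (("Nematogenyidae", "Loricariidae"), 123.8, "primary"),  # Loricarioidei
    (("Nematogenyidae", "Trichomycteridae"), 114.0, "primary"),
    (("Callichthyidae", "Loricariidae"), 117.2, "primary"),  # CSAL
    (("Loricariidae", "Scoloplacidae"), 97.4, "primary"),    # SAL
    (("Scoloplacidae", "Astroblepidae"), 92.1, "primary"),
    # supplementary-sourced outgroup crowns: placeholder values
    (("Doradidae", "Bagridae"), 133.0, "placeholder"),       # Siluroidei
    (("Doradidae", "Ariidae"), 118.0, "placeholder"),
    (("Doradidae", "Aspredinidae"), 96.0, "placeholder"),
    (("Doradidae", "Auchenipteridae"), 76.0, "placeholder"),
    (("Pseudopimelodidae", "Ariidae"), 105.0, "placeholder"),
    (("Pseudopimelodidae", "Heptapteridae"), 94.0, "placeholder"),
    (("Pimelodidae", "Heptapteridae"), 78.0, "placeholder"),
    (("Amphiliidae", "Bagridae"), 126.0, "placeholder"),
    (("Schilbeidae", "Bagridae"), 119.0, "placeholder"),
    (("Mochokidae", "Bagridae"), 112.0, "placeholder"),
    (("Ictaluridae", "Bagridae"), 105.0, "placeholder"),
    (("Sisoridae", "Bagridae"), 96.0, "placeholder"),
    (("Sisoridae", "Erethistidae"), 70.0, "placeholder"),
    (("Akysidae", "Bagridae"), 84.0, "placeholder"),
    (("Amblycipitidae", "Bagridae"), 68.0, "placeholder"),
]


@dataclass
class FixtureBundle:
    tree: Chronogram
    plates: CharacterMatrix
    odontodes: CharacterMatrix
    ages: CladeAgeTable

    def __iter__(self):
        return iter((self.tree, self.plates, self.odontodes))


def fixture_age_table() -> CladeAgeTable:
    table = CladeAgeTable()
    for tips, age, source in _AGE_ENTRIES:
        table.add(tips, age, source=source)
    return table


def loricarioid_fixture(
    odontode_overrides: Mapping[str, str] | None = None,
) -> FixtureBundle:
    """Build the 23-family chronogram and both character matrices.

    ``odontode_overrides`` replaces individual 4-state odontode codes (the
    per-family head-odontode scoring is supplementary-sourced, so e.g. the
    Nematogenyidae code is legitimately revisable).
    """
    ages = fixture_age_table()
    tree = build_chronogram(TOPOLOGY, ages)

    families = LORICARIOID_FAMILIES + OUTGROUP_FAMILIES
    plates = CharacterMatrix(
        name="trunk_dermal_bony_plates",
        alphabet=["0", "1"],
        assignments={f: ("1" if f in PLATE_PRESENT else "0") for f in families},
    )
    codes = dict(DEFAULT_ODONTODE_CODES)
    if odontode_overrides:
        codes.update(odontode_overrides)
    odontodes = CharacterMatrix(
        name="odontode_cover",
        alphabet=["0", "1", "2", "3"],
        assignments={f: codes.get(f, "0") for f in families},
    )
    return FixtureBundle(tree=tree, plates=plates, odontodes=odontodes, ages=ages)
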