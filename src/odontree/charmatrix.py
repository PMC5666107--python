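"""Discrete morphological character matrices.

Two characters are central here: presence/absence of trunk dermal bony
plates (binary) and odontode body cover (four states: 0 none, 1 head only,
2 trunk only, 3 head and trunk).  The missing marker is ``"?"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "MISSING",
    "CharacterMatrix",
    "FamilyTraitRecord",
    "encode_odontode_state",
    "read_matrix",
    "write_matrix",
]

MISSING = "?"


@dataclass
class CharacterMatrix:
    """One discrete character scored across taxa.

    ``alphabet`` is the ordered list of state symbols; assignments map each
    taxon to a symbol from the alphabet or the missing marker.
    """

    name: str
    alphabet: list[str]
    assignments: dict[str, str] = field(default_factory=dict)
    missing: str = MISSING

    def __post_init__(self) -> None:
        if len(self.alphabet) < 2:
            raise ValueError("state alphabet must have at least 2 symbols")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet symbols must be unique")
        for taxon, state in self.assignments.items():
            self._check_state(taxon, state)

    def _check_state(self, taxon: str, state: str) -> None:
        if state != self.missing and state not in self.alphabet:
            raise ValueError(
                f"taxon {taxon!r} has unknown state symbol {state!r} "
                f"(alphabet {self.alphabet})"
            )

    def __setitem__(self, taxon: str, state: str) -> None:
        self._check_state(taxon, state)
        self.assignments[taxon] = state

    def __getitem__(self, taxon: str) -> str:
        return self.assignments[taxon]

    @property
    def taxa(self) -> list[str]:
        return list(self.assignments)

    def state_index(self, taxon: str) -> int | None:
        """Alphabet index of the taxon's state, or None if missing."""
        state = self.assignments[taxon]
        if state == self.missing:
            return None
        return self.alphabet.index(state)

    def as_indices(self) -> dict[str, int | None]:
        return {t: self.state_index(t) for t in self.assignments}

    def relabelled(self, permutation: Mapping[str, str]) -> "CharacterMatrix":
        """Apply a state-symbol permutation consistently (alphabet order kept)."""
        new_assign = {
            t: (s if s == self.missing else permutation[s])
            for t, s in self.assignments.items()
        }
        return CharacterMatrix(self.name, list(self.alphabet), new_assign, self.missing)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.name == other.name
            and self.alphabet == other.alphabet
            and self.assignments == other.assignments
            and self.missing == other.missing
        )


@dataclass(frozen=True)
class FamilyTraitRecord:
    """Raw presence flags for one family (True/False/None=unknown)."""

    family: str
    head_odontodes: bool | None
    trunk_odontodes: bool | None
    trunk_plates: bool | None

    def odontode_state(self) -> str:
        return encode_odontode_state(self.head_odontodes, self.trunk_odontodes)

    def plate_state(self) -> str:
        if self.trunk_plates is None:
            return MISSING
        return "1" if self.trunk_plates else "0"


def encode_odontode_state(head: bool | None, trunk: bool | None) -> str:
    """Fold head/trunk odontode presence flags into the 4-state code.

    0 = no odontodes, 1 = head only, 2 = trunk only, 3 = head and trunk.
    An unknown flag yields the missing marker rather than an error.
    """
    if head is None or trunk is None:
        return MISSING
    return str((1 if head else 0) + (2 if trunk else 0))


# ------------------------------------------------------------------------ io
def _read_csv(text: str, name: str, alphabet: list[str]) -> CharacterMatrix:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].lower().replace(" ", "") != "taxon,state":
        raise ValueError("CSV character matrix must start with header 'taxon,state'")
    matrix = CharacterMatrix(name=name, alphabet=alphabet)
    for ln in lines[1:]:
        taxon, state = (part.strip() for part in ln.split(",", 1))
        matrix[taxon] = state
    return matrix


def _write_csv(matrix: CharacterMatrix) -> str:
    out = ["taxon,state"]
    out.extend(f"{t},{s}" for t, s in matrix.assignments.items())
    return "\n".join(out) + "\n"


def _write_nexus(matrix: CharacterMatrix) -> str:
    symbols = "".join(matrix.alphabet)
    rows = "\n".join(
        f"    {taxon.replace(' ', '_')} {state}"
        for taxon, state in matrix.assignments.items()
    )
    return (
        "#NEXUS\n"
        "BEGIN CHARACTERS;\n"
        f"  [character: {matrix.name}]\n"
        f"  DIMENSIONS NTAX={len(matrix.assignments)} NCHAR=1;\n"
        f"  FORMAT DATATYPE=STANDARD SYMBOLS=\"{symbols}\" MISSING={matrix.missing};\n"
        "  MATRIX\n"
        f"{rows}\n"
        "  ;\n"
        "END;\n"
    )


def _read_nexus(text: str, name: str) -> CharacterMatrix:
    m = re.search(r'SYMBOLS\s*=\s*"([^"]+)"', text, re.IGNORECASE)
    if not m:
        raise ValueError("NEXUS CHARACTERS block lacks a SYMBOLS declaration")
    alphabet = list(m.group(1).replace(" ", ""))
    miss = MISSING
    mm = re.search(r"MISSING\s*=\s*(\S)", text, re.IGNORECASE)
    if mm:
        miss = mm.group(1)
    name_m = re.search(r"\[character:\s*([^\]]+)\]", text)
    if name_m:
        name = name_m.group(1).strip()
    body = re.search(r"MATRIX(.*?);", text, re.DOTALL | re.IGNORECASE)
    if not body:
        raise ValueError("NEXUS CHARACTERS block lacks a MATRIX")
    matrix = CharacterMatrix(name=name, alphabet=alphabet, missing=miss)
    for ln in body.group(1).splitlines():
        ln = ln.strip()
        if not ln:
            continue
        taxon, state = ln.rsplit(None, 1)
        matrix[taxon] = state
    return matrix


def write_matrix(matrix: CharacterMatrix, path: str, format: str = "csv") -> None:
    fmt = format.lower()
    if fmt == "csv":
        text = _write_csv(matrix)
    elif fmt == "nexus":
        text = _write_nexus(matrix)
    else:
        raise ValueError(f"unknown format {format!r} (use 'csv' or 'nexus')")
    with open(path, "w") as fh:
        fh.write(text)


def read_matrix(
    path: str,
    format: str = "csv",
    name: str = "character",
    alphabet: list[str] | None = None,
) -> CharacterMatrix:
    with open(path) as fh:
        text = fh.read()
    fmt = format.lower()
    if fmt == "csv":
        if alphabet is None:
            # infer: all non-missing symbols seen, sorted
            symbols = sorted(
                {ln.split(",", 1)[1].strip() for ln in text.splitlines()[1:] if ln.strip()}
                - {MISSING}
            )
            alphabet = symbols if len(symbols) >= 2 else ["0", "1"]
        return _read_csv(text, name, alphabet)
    if fmt == "nexus":
        return _read_nexus(text, name)
    raise ValueError(f"unknown format {format!r} (use 'csv' or 'nexus')")
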