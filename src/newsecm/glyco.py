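"""Elemental compositions and azido-glycan modification masses.

The metabolic label Ac4GalNAz installs an azido-GalNAc (GalNAz) residue
on O-glycosylation sites of newly synthesized glycoproteins. In the
open-modification database search, the label appears on serine/threonine
in two forms: the bare glycan residue, and the glycan after
copper-catalyzed azide–alkyne cycloaddition (CuAAC) with the
alkyne-PEG4-desthiobiotin capture reagent. CuAAC conserves every atom of
both reactants, so the clicked modification's composition is the
element-wise sum of the two.

Compositions used:

* GalNAz glycan residue (HexNAc residue with one acetyl hydrogen
  replaced by an azide): C8H12N4O5, monoisotopic +244.0808 Da.
* Alkyne-PEG4-desthiobiotin reagent: C21H37N3O6.
* Clicked adduct: C29H49N7O11, monoisotopic +671.3490 Da.

Atomic monoisotopic masses are pinned to 7+ significant figures so the
4-decimal-place delta masses are stable.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

__all__ = ["MONOISOTOPIC_MASS", "ElementalComposition", "monoisotopic_mass",
           "compose", "ModificationSpec", "modification_specs",
           "GALNAZ_RESIDUE", "ALKYNE_PEG4_DESTHIOBIOTIN"]

#: Monoisotopic atomic masses, Da (most abundant isotope).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740,
    "O": 15.9949146,
    "S": 31.97207117,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """Element symbol -> atom count, with monoisotopic mass arithmetic."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-style formula like ``"C8H12N4O5"``."""
        counts: Counter[str] = Counter()
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            counts[m.group(1)] += int(m.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls.from_dict(counts)

    @classmethod
    def from_dict(cls, counts) -> "ElementalComposition":
        clean = {}
        for el, n in dict(counts).items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol {el!r}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative atom count for {el}")
            if n:
                clean[el] = n
        order = list(MONOISOTOPIC_MASS)
        return cls(tuple((el, clean[el]) for el in order if el in clean))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.counts)

    @property
    def n_atoms(self) -> int:
        return sum(n for _, n in self.counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = Counter(dict(self.counts))
        merged.update(dict(other.counts))
        return ElementalComposition.from_dict(merged)

    def formula(self) -> str:
        return "".join(f"{el}{n if n != 1 else ''}" for el, n in self.counts)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.formula()


def monoisotopic_mass(composition) -> float:
    """Monoisotopic mass (Da) of a composition, formula string, or dict."""
    if isinstance(composition, str):
        composition = ElementalComposition.from_formula(composition)
    elif isinstance(composition, dict):
        composition = ElementalComposition.from_dict(composition)
    return composition.mass


def compose(a, b) -> ElementalComposition:
    """Element-wise sum of two compositions (CuAAC conserves all atoms)."""
    if isinstance(a, str):
        a = ElementalComposition.from_formula(a)
    if isinstance(b, str):
        b = ElementalComposition.from_formula(b)
    return a + b


GALNAZ_RESIDUE = ElementalComposition.from_formula("C8H12N4O5")
ALKYNE_PEG4_DESTHIOBIOTIN = ElementalComposition.from_formula("C21H37N3O6")


@dataclass(frozen=True)
class ModificationSpec:
    """A custom search-engine modification on specific residues."""

    name: str
    target_residues: frozenset[str]
    composition: ElementalComposition
    delta_mass: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.delta_mass is None:
            object.__setattr__(self, "delta_mass", self.composition.mass)
        if abs(self.delta_mass - self.composition.mass) > 5e-5:
            raise ValueError(
                f"delta mass {self.delta_mass} inconsistent with composition "
                f"{self.composition.formula()} ({self.composition.mass:.4f})")

    def to_text(self) -> str:
        """One definition block suitable for a custom-modification list."""
        residues = "/".join(sorted(self.target_residues))
        return (f"NAME\t{self.name}\n"
                f"RESIDUES\t{residues}\n"
                f"COMPOSITION\t{self.composition.formula()}\n"
                f"MONOISOTOPIC_MASS\t{self.delta_mass:.4f}\n")


def modification_specs() -> list[ModificationSpec]:
    """The two azido-glycan label modifications used in the search.

    Both target serine/threonine: the bare GalNAz glycan residue and the
    GalNAz residue clicked to alkyne-PEG4-desthiobiotin.
    """
    bare = ModificationSpec(
        name="GalNAz glycan on S/T",
        target_residues=frozenset({"S", "T"}),
        composition=GALNAZ_RESIDUE,
    )
    clicked = ModificationSpec(
        name="GalNAz + alkyne-PEG4-desthiobiotin on S/T",
        target_residues=frozenset({"S", "T"}),
        composition=GALNAZ_RESIDUE + ALKYNE_PEG4_DESTHIOBIOTIN,
    )
    return [bare, clicked]


def export_modifications(path) -> None:
    """Write the custom-modification definitions as a text block."""
    with open(path, "w") as fh:
        for spec in modification_specs():
            fh.write(spec.to_text() + "\n")
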