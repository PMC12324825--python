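"""Isoprenoid quinone species and their closed-form neutral formulas.

A quinone species is identified by its class (menaquinone, ubiquinone,
plastoquinone or methyl-plastoquinone), the number of isoprene units in the
side chain ``n`` and the number of chain double bonds ``m`` — the customary
"n:m" notation. The neutral molecular formula follows deterministically:

=====================  ==========  ======================  ===
class                  C           H                       O
=====================  ==========  ======================  ===
menaquinone            11 + 5n     8n + 8 + 2(n − m)       2
ubiquinone             9 + 5n      8n + 10 + 2(n − m)      4
plastoquinone          8 + 5n      8n + 8 + 2(n − m)       2
methyl-plastoquinone   9 + 5n      8n + 10 + 2(n − m)      2
=====================  ==========  ======================  ===

Methyl-plastoquinone is a plastoquinone carrying one extra ring methyl
(hence +CH2 relative to plastoquinone of the same chain).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .composition import ElementalComposition
from .constants import ELECTRON_MASS, MONOISOTOPIC_MASS

__all__ = [
    "QuinoneClass",
    "QuinoneSpecies",
    "quinone_formula",
    "predict_hydrogenated",
    "headgroup_fragment",
]

H2_MASS = 2 * MONOISOTOPIC_MASS["H"]  # 2.01565 Da, one chain double bond reduced


class QuinoneClass(str, Enum):
    MENAQUINONE = "menaquinone"
    UBIQUINONE = "ubiquinone"
    PLASTOQUINONE = "plastoquinone"
    METHYL_PLASTOQUINONE = "methyl-plastoquinone"

    @property
    def abbreviation(self) -> str:
        return _ABBREV[self]


_ABBREV = {
    QuinoneClass.MENAQUINONE: "MK",
    QuinoneClass.UBIQUINONE: "UQ",
    QuinoneClass.PLASTOQUINONE: "PQ",
    QuinoneClass.METHYL_PLASTOQUINONE: "Methyl-PQ",
}

# (carbon base, hydrogen base, oxygens); C = base + 5n, H = base + 10n − 2m
_FORMULA_COEFF = {
    QuinoneClass.MENAQUINONE: (11, 8, 2),
    QuinoneClass.UBIQUINONE: (9, 10, 4),
    QuinoneClass.PLASTOQUINONE: (8, 8, 2),
    QuinoneClass.METHYL_PLASTOQUINONE: (9, 10, 2),
}


@dataclass(frozen=True, order=True)
class QuinoneSpecies:
    """One quinone homologue: class + chain length ``n`` + unsaturation ``m``."""

    quinone_class: QuinoneClass
    n: int
    m: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"chain length n must be >= 1, got {self.n}")
        if not 0 <= self.m <= self.n:
            raise ValueError(
                f"chain double bonds m must satisfy 0 <= m <= n, got m={self.m}, n={self.n}"
            )

    @property
    def name(self) -> str:
        """Display name in the field's "n:m" notation, e.g. ``"Methyl-PQ 9:9"``."""
        return f"{self.quinone_class.abbreviation} {self.n}:{self.m}"

    def formula(self) -> ElementalComposition:
        return quinone_formula(self.quinone_class, self.n, self.m)

    def protonated_formula(self) -> ElementalComposition:
        """Formula of the [M+H]+ ion (the AEC convention of the report tables)."""
        return self.formula() + {"H": 1}


def quinone_formula(cls: QuinoneClass, n: int, m: int) -> ElementalComposition:
    """Neutral molecular formula of a quinone homologue.

    Parameters
    ----------
    cls
        Quinone class.
    n
        Isoprene units in the side chain (>= 1).
    m
        Chain double bonds (0 <= m <= n).
    """
    if n < 1 or not 0 <= m <= n:
        raise ValueError(f"invalid chain spec n={n}, m={m} (need n >= 1, 0 <= m <= n)")
    c0, h0, n_oxygen = _FORMULA_COEFF[QuinoneClass(cls)]
    return ElementalComposition(C=c0 + 5 * n, H=h0 + 10 * n - 2 * m, O=n_oxygen)


def predict_hydrogenated(sp: QuinoneSpecies) -> tuple[QuinoneSpecies, float]:
    """Chain-saturated product of catalytic hydrogenation and its mass shift.

    Hydrogenation adds H2 across each isoprenoid chain double bond (m → 0,
    +2.01565 Da per bond); the ring carbonyl system is treated as unreduced.
    """
    saturated = QuinoneSpecies(sp.quinone_class, sp.n, 0)
    return saturated, H2_MASS * sp.m


_HEADGROUP = {
    QuinoneClass.PLASTOQUINONE: ElementalComposition(C=9, H=11, O=2),
    QuinoneClass.METHYL_PLASTOQUINONE: ElementalComposition(C=10, H=13, O=2),
}


def headgroup_fragment(sp: QuinoneSpecies) -> tuple[ElementalComposition, float]:
    """Benzylic headgroup fragment cation and its m/z.

    The diagnostic MS2 fragment is the quinone head ring with its methyl
    substituents plus one chain methylene: C9H11O2+ for plastoquinone,
    C10H13O2+ for methyl-plastoquinone (+CH2 for the extra ring methyl).
    """
    try:
        frag = _HEADGROUP[sp.quinone_class]
    except KeyError:
        raise ValueError(
            "headgroup fragment is defined for plastoquinone and "
            f"methyl-plastoquinone only, not {sp.quinone_class.value}"
        ) from None
    return frag, frag.mass - ELECTRON_MASS
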