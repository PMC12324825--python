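"""Positive-mode ESI adducts and ion m/z arithmetic.

Only the three singly charged adducts seen for isoprenoid quinones in
positive ESI are supported: [M+H]+, [M+NH4]+ and [M+Na]+. The delta mass of
an adduct is the monoisotopic mass of the attached group minus one electron.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .composition import ElementalComposition
from .constants import ELECTRON_MASS

__all__ = ["Adduct", "ADDUCTS", "adduct_mz"]


@dataclass(frozen=True)
class Adduct:
    name: str
    delta_composition: ElementalComposition
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge != 1:
            raise ValueError("only singly charged (+1) adducts are supported")

    @property
    def delta_mass(self) -> float:
        return self.delta_composition.mass - self.charge * ELECTRON_MASS


ADDUCTS: dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", ElementalComposition(H=1)),
    "[M+NH4]+": Adduct("[M+NH4]+", ElementalComposition(N=1, H=4)),
    "[M+Na]+": Adduct("[M+Na]+", ElementalComposition(Na=1)),
}


def get_adduct(name: str) -> Adduct:
    try:
        return ADDUCTS[name]
    except KeyError:
        raise ValueError(
            f"unsupported adduct {name!r}; supported: {', '.join(ADDUCTS)}"
        ) from None


def adduct_mz(ec: ElementalComposition, a: Adduct | str) -> float:
    """m/z of a singly charged adduct ion of the neutral molecule ``ec``."""
    if isinstance(a, str):
        a = get_adduct(a)
    return ec.mass + a.delta_mass
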