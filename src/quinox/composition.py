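"""Elemental compositions with exact monoisotopic mass semantics.

An :class:`ElementalComposition` is an immutable element→count map supporting
the small amount of arithmetic needed for adduct and fragment bookkeeping
(addition, subtraction that refuses to go negative) and exact monoisotopic
mass evaluation. Only the elements found in isoprenoid quinones and their
ESI adducts (C, H, N, O, Na) are supported; an unknown symbol raises
:class:`UnknownElementError` naming the offending symbol.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping

from .constants import MONOISOTOPIC_MASS

__all__ = [
    "ElementalComposition",
    "UnknownElementError",
    "composition_mass",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)_?(\d*)_?")


class UnknownElementError(ValueError):
    """An element symbol without a known monoisotopic mass."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(
            f"unknown element symbol {symbol!r}; known elements: "
            + ", ".join(sorted(MONOISOTOPIC_MASS))
        )


class ElementalComposition(Mapping[str, int]):
    """Immutable map of element symbol → atom count.

    Parameters
    ----------
    counts
        Element→count mapping, or keyword arguments. All counts must be
        non-negative integers and at least one must be positive.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kw:
            for sym, cnt in source.items():
                merged[sym] = merged.get(sym, 0) + int(cnt)
        for sym, cnt in merged.items():
            if sym not in MONOISOTOPIC_MASS:
                raise UnknownElementError(sym)
            if cnt < 0:
                raise ValueError(f"negative count for element {sym}: {cnt}")
        merged = {s: c for s, c in merged.items() if c > 0}
        if not merged:
            raise ValueError("composition must contain at least one atom")
        self._counts = merged

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a molecular formula such as ``"C54H82O2"`` or ``"C_54_H_83_O_2"``."""
        text = formula.strip().strip("+")
        counts: dict[str, int] = {}
        pos = 0
        while pos < len(text):
            m = _FORMULA_TOKEN.match(text, pos)
            if m is None or m.end() == pos:
                raise ValueError(f"cannot parse formula {formula!r} at {text[pos:]!r}")
            sym, digits = m.group(1), m.group(2)
            if sym not in MONOISOTOPIC_MASS:
                raise UnknownElementError(sym)
            counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
            pos = m.end()
        return cls(counts)

    # Mapping interface
    def __getitem__(self, sym: str) -> int:
        return self._counts[sym]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, sym: str, default: int = 0) -> int:  # type: ignore[override]
        return self._counts.get(sym, default)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da (sum of count × atomic monoisotopic mass)."""
        return sum(MONOISOTOPIC_MASS[s] * c for s, c in self._counts.items())

    def __add__(self, other: Mapping[str, int]) -> "ElementalComposition":
        counts = dict(self._counts)
        for sym, cnt in other.items():
            counts[sym] = counts.get(sym, 0) + cnt
        return ElementalComposition(counts)

    def __sub__(self, other: Mapping[str, int]) -> "ElementalComposition":
        counts = dict(self._counts)
        for sym, cnt in other.items():
            new = counts.get(sym, 0) - cnt
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative count for {sym} "
                    f"({counts.get(sym, 0)} - {cnt})"
                )
            counts[sym] = new
        return ElementalComposition(counts)

    def formula(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        order = sorted(
            self._counts, key=lambda s: (s != "C", s != "H", s)
        )
        return "".join(
            f"{s}{self._counts[s]}" if self._counts[s] != 1 else s for s in order
        )

    def __repr__(self) -> str:
        return f"ElementalComposition({self.formula()!r})"

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalComposition):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {s: c for s, c in other.items() if c}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))


def composition_mass(ec: ElementalComposition) -> float:
    """Monoisotopic mass of a composition, in Da."""
    return ec.mass
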