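"""Formula arithmetic and multi-adduct exact-mass annotation.

Soft plasma ionization produces several molecular adducts per neutral
compound M.  Putative annotation therefore matches each observed m/z
against the theoretical m/z of every (compound, adduct) combination in a
compound database, within a ppm tolerance.  All cations here are singly
charged, and the electron mass is subtracted from every cation mass: at
3-decimal printing this matters above m/z ~100 (e.g. monoterpenes at
137.132 rather than 137.133).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _ptmass

from .errors import FormulaError

__all__ = [
    "ElementalFormula",
    "AdductSpec",
    "AnnotationHit",
    "ADDUCTS",
    "ELECTRON_MASS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "annotate",
]

#: Monoisotopic (most abundant isotope) atomic masses, Da.
ELEMENT_MASS: dict[str, float] = {
    el: _ptmass.nist_mass[el][0][0]
    for el in ("C", "H", "N", "O", "S", "Si", "P", "F", "Cl", "Br", "I", "Na", "K")
}

ELECTRON_MASS: float = _ptmass.nist_mass["e*"][0][0]  # 0.000549 Da

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Elemental composition as a symbol -> count mapping."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for el, n in self.counts.items():
            if el not in ELEMENT_MASS:
                raise FormulaError(f"unsupported element {el!r}")
            if n < 1:
                raise FormulaError(f"non-positive count for element {el!r}")

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __str__(self) -> str:  # Hill order: C, H, then alphabetical
        keys = sorted(self.counts, key=lambda e: (e != "C", e != "H", e))
        return "".join(f"{e}{self.counts[e] if self.counts[e] > 1 else ''}" for e in keys)


def parse_formula(s: str) -> ElementalFormula:
    """Parse a Hill-style formula string, allowing parenthesised groups.

    ``"C3H6O"`` -> C3 H6 O1; ``"[Si(CH3)2O]2"`` (brackets treated like
    parentheses) -> Si2 C4 H12 O2.  Raises :class:`FormulaError` with the
    offending position for unknown symbols or unbalanced groups.
    """
    s = s.strip()
    if not s:
        raise FormulaError("empty formula", position=0)
    stack: list[dict[str, int]] = [{}]
    i = 0
    n = len(s)
    while i < n:
        c = s[i]
        if c in "([":
            stack.append({})
            i += 1
        elif c in ")]":
            if len(stack) == 1:
                raise FormulaError(f"unbalanced {c!r}", position=i)
            group = stack.pop()
            i += 1
            m = re.match(r"\d+", s[i:])
            mult = int(m.group()) if m else 1
            if m:
                i += m.end()
            for el, cnt in group.items():
                stack[-1][el] = stack[-1].get(el, 0) + cnt * mult
        elif c.isupper():
            m = re.match(r"([A-Z][a-z]?)(\d*)", s[i:])
            sym, digits = m.group(1), m.group(2)
            if sym not in ELEMENT_MASS and sym[:1] in ELEMENT_MASS:
                sym, digits = sym[:1], ""  # e.g. "CH" is C followed by H
                m = re.match(r"([A-Z])(\d*)", s[i:])
                digits = m.group(2)
            if sym not in ELEMENT_MASS:
                raise FormulaError(f"unknown element {sym!r}", position=i)
            cnt = int(digits) if digits else 1
            if cnt < 1:
                raise FormulaError(f"zero count for {sym!r}", position=i)
            stack[-1][sym] = stack[-1].get(sym, 0) + cnt
            i += m.end()
        else:
            raise FormulaError(f"unexpected character {c!r}", position=i)
    if len(stack) != 1:
        raise FormulaError("unbalanced '('", position=n)
    return ElementalFormula(stack[0])


def monoisotopic_mass(f: ElementalFormula | str) -> float:
    """Monoisotopic mass in Da: sum of most-abundant-isotope atomic masses."""
    if isinstance(f, str):
        f = parse_formula(f)
    return float(sum(ELEMENT_MASS[el] * n for el, n in f.counts.items()))


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged cationic adduct with a fixed mass offset from M."""

    name: str
    mass_delta: float  # Da added to the neutral monoisotopic mass
    charge: int = 1


_mH = ELEMENT_MASS["H"]
_mO = ELEMENT_MASS["O"]
_mN = ELEMENT_MASS["N"]

#: The five adduct types observed under cold-plasma ionization.
#: [M-OH]+ is water loss from the protonated ion.
ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", _mH - ELECTRON_MASS),
    "[M]+": AdductSpec("[M]+", -ELECTRON_MASS),
    "[M-H]+": AdductSpec("[M-H]+", -_mH - ELECTRON_MASS),
    "[M-OH]+": AdductSpec("[M-OH]+", -_mO - _mH - ELECTRON_MASS),
    "[M+NH4]+": AdductSpec("[M+NH4]+", _mN + 4 * _mH - ELECTRON_MASS),
}


def adduct_mz(f: ElementalFormula | str, adduct: AdductSpec | str) -> float:
    """Theoretical m/z of a singly charged adduct of formula ``f``."""
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    if adduct.charge != 1:
        raise ValueError("only singly charged adducts are supported")
    return monoisotopic_mass(f) + adduct.mass_delta


@dataclass(frozen=True)
class AnnotationHit:
    """One putative (feature, compound, adduct) match."""

    feature_mz: float
    compound: "CompoundRecord"  # noqa: F821 - imported lazily to avoid a cycle
    adduct: AdductSpec
    theoretical_mz: float
    ppm_error: float


def annotate(
    feature_mz: "np.ndarray | list[float]",
    db,
    adducts: "list[AdductSpec | str] | None" = None,
    tol_ppm: float = 10.0,
) -> list[AnnotationHit]:
    """Match feature m/z values against a compound database.

    Every (compound, adduct) pair whose theoretical m/z lies within
    ``tol_ppm`` of a feature yields one hit; a feature may collect many
    hits.  Hits are returned sorted by absolute ppm error.

    Parameters
    ----------
    feature_mz : observed feature m/z values.
    db : sequence of :class:`~breathomics.io.CompoundRecord`.
    adducts : adduct specs or names; defaults to all five supported types.
    tol_ppm : maximum relative mass deviation, ppm (default 10).
    """
    specs = [ADDUCTS[a] if isinstance(a, str) else a for a in (adducts or ADDUCTS.values())]
    feats = np.asarray(feature_mz, dtype=float)
    # precompute all theoretical m/z in one sorted array for binary search
    theo, meta = [], []
    for rec in db:
        try:
            m = monoisotopic_mass(rec.formula)
        except FormulaError:
            continue
        for spec in specs:
            theo.append(m + spec.mass_delta)
            meta.append((rec, spec))
    theo = np.asarray(theo)
    order = np.argsort(theo)
    theo_sorted = theo[order]
    hits: list[AnnotationHit] = []
    for fmz in feats:
        tol = tol_ppm * 1e-6 * fmz
        lo = np.searchsorted(theo_sorted, fmz - tol, side="left")
        hi = np.searchsorted(theo_sorted, fmz + tol, side="right")
        for k in order[lo:hi]:
            t = theo[k]
            ppm = (fmz - t) / t * 1e6
            if abs(ppm) <= tol_ppm:
                rec, spec = meta[k]
                hits.append(AnnotationHit(float(fmz), rec, spec, float(t), float(ppm)))
    hits.sort(key=lambda h: abs(h.ppm_error))
    return hits
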