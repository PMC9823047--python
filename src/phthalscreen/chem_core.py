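"""Exact-mass and molecular-formula arithmetic for CHO anions.

Monophthalate metabolites observed in negative electrospray are deprotonated
even-electron species [M-H]- built from carbon, hydrogen and oxygen only.
This module provides the mass arithmetic for such compositions (optionally
with 13C substitutions, for isotope-labelled internal standards), ring-and-
double-bond-equivalent (RDBE) bookkeeping, and brute-force enumeration of
candidate ion compositions for an observed accurate mass under the elemental
restrictions appropriate for phthalate monoesters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MASS_H",
    "MASS_C12",
    "MASS_C13",
    "MASS_O",
    "MASS_ELECTRON",
    "MASS_PROTON",
    "ElementalFormula",
    "CompositionConstraints",
    "DiagnosticIonSet",
    "FormulaMatch",
    "monoisotopic_mass",
    "anion_mz",
    "neutral_mass_from_anion_mz",
    "rdbe_neutral",
    "enumerate_formulas",
]

# CODATA/IUPAC monoisotopic masses, Da.
MASS_H = 1.00782503207
MASS_C12 = 12.0
MASS_C13 = 13.00335483507
MASS_O = 15.99491461956
MASS_ELECTRON = 0.00054857990
#: Mass of H+ (a proton): the difference between a neutral M and its [M-H]- anion m/z.
MASS_PROTON = MASS_H - MASS_ELECTRON

_FORMULA_RE = re.compile(
    r"^(?:C(?P<c>\d*))?(?:\[13C\](?P<c13>\d*))?(?:H(?P<h>\d*))?(?:O(?P<o>\d*))?$"
)


@dataclass(frozen=True, order=True)
class ElementalFormula:
    """A CHO composition; ``n_carbon13`` of the ``n_carbon`` carbons are 13C.

    The same type represents both neutral molecules and ion compositions;
    which one is meant is a property of the call site (e.g. :func:`anion_mz`
    takes the *ion* composition C7H5O2 for the m/z 121.0295 fragment).
    """

    n_carbon: int
    n_hydrogen: int
    n_oxygen: int
    n_carbon13: int = 0

    def __post_init__(self) -> None:
        for name in ("n_carbon", "n_hydrogen", "n_oxygen", "n_carbon13"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_carbon13 > self.n_carbon:
            raise ValueError(
                f"n_carbon13 ({self.n_carbon13}) exceeds n_carbon ({self.n_carbon})"
            )

    def hill(self) -> str:
        """Hill-notation string; 13C substitutions written as ``[13C]n``.

        A formula with 8 carbons of which 4 are labelled renders as
        ``C4[13C]4H6O4`` (the leading C count is the remaining 12C).
        """
        parts = []
        n12 = self.n_carbon - self.n_carbon13
        if n12:
            parts.append(f"C{n12 if n12 > 1 else ''}")
        if self.n_carbon13:
            parts.append(f"[13C]{self.n_carbon13 if self.n_carbon13 > 1 else ''}")
        if self.n_hydrogen:
            parts.append(f"H{self.n_hydrogen if self.n_hydrogen > 1 else ''}")
        if self.n_oxygen:
            parts.append(f"O{self.n_oxygen if self.n_oxygen > 1 else ''}")
        return "".join(parts) or ""

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse ``C10H10O4`` / ``C4[13C]4H6O4`` style strings."""
        m = _FORMULA_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse CHO formula {text!r}")

        def count(g: str | None) -> int:
            if g is None:
                return 0
            return int(g) if g else 1

        c13 = count(m.group("c13"))
        return cls(
            n_carbon=count(m.group("c")) + c13,
            n_hydrogen=count(m.group("h")),
            n_oxygen=count(m.group("o")),
            n_carbon13=c13,
        )

    def deprotonated(self) -> "ElementalFormula":
        """Ion composition of the [M-H]- anion of this neutral."""
        if self.n_hydrogen < 1:
            raise ValueError("cannot deprotonate a hydrogen-free formula")
        return replace(self, n_hydrogen=self.n_hydrogen - 1)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass in Da; each 13C replaces one 12C."""
    return (
        (formula.n_carbon - formula.n_carbon13) * MASS_C12
        + formula.n_carbon13 * MASS_C13
        + formula.n_hydrogen * MASS_H
        + formula.n_oxygen * MASS_O
    )


def anion_mz(formula: ElementalFormula) -> float:
    """m/z of the singly charged anion with this *ion* composition.

    The electron gained by the anion is included, so e.g. C7H5O2 gives
    121.0295 at four decimals.
    """
    return monoisotopic_mass(formula) + MASS_ELECTRON


def neutral_mass_from_anion_mz(mz: float) -> float:
    """Neutral monoisotopic mass M reconstructed from an observed [M-H]- m/z."""
    return mz + MASS_PROTON


def rdbe_neutral(ion_formula: ElementalFormula) -> float:
    """RDBE of the neutral M reconstructed from a CHO [M-H]- ion composition.

    The neutral adds one hydrogen back: RDBE = C - (H_ion + 1)/2 + 1.
    Integer-valued whenever the neutral is an even-electron CHO molecule.
    """
    return ion_formula.n_carbon - (ion_formula.n_hydrogen + 1) / 2.0 + 1.0


@dataclass(frozen=True)
class CompositionConstraints:
    """Elemental-composition restrictions for monophthalate [M-H]- ions.

    Bounds are inclusive. Carbon/hydrogen/oxygen ranges apply to the *ion*
    composition; the RDBE window applies to the reconstructed neutral.
    ``min_spectral_fit`` is an isotope-pattern score used by some vendor
    software; it is carried as run metadata but never evaluated here.
    """

    c_min: int = 8
    c_max: int = 30
    h_min: int = 6
    h_max: int = 60
    o_min: int = 4
    o_max: int = 10
    charge: int = -1
    rdbe_min: float = 6.0
    rdbe_max: float = 12.0
    mass_tol_ppm: float = 5.0
    snr_min: float = 3.0
    min_spectral_fit: float = 10.0  # recorded only, not evaluated

    def __post_init__(self) -> None:
        if not (self.c_min <= self.c_max and self.h_min <= self.h_max
                and self.o_min <= self.o_max and self.rdbe_min <= self.rdbe_max):
            raise ValueError("constraint minima must not exceed maxima")
        if self.mass_tol_ppm <= 0:
            raise ValueError("mass_tol_ppm must be positive")
        if self.charge != -1:
            raise ValueError("only singly charged anions are supported")

    @classmethod
    def from_dict(cls, d: dict) -> "CompositionConstraints":
        return cls(**d)


@dataclass(frozen=True)
class DiagnosticIonSet:
    """Diagnostic fragment m/z values of the monophthalate skeleton.

    ``native_trio`` are the benzoate / phthalic-anhydride / phthalate
    fragments common to most phthalate monoesters; ``supplementary`` is the
    additional ion characteristic of pure-alkyl-chain monoesters (it flags a
    subclass but never counts toward the two-of-three rule). The labelled
    trio is the ring-labelled counterpart used to trace isotope-labelled
    internal standards; those values are configured constants.
    """

    native_trio: tuple[float, float, float] = (121.0295, 147.0088, 165.0193)
    supplementary: float = 134.0377
    labelled_trio: tuple[float, float, float] = (124.0397, 151.0223, 169.0329)
    match_tol_ppm: float = 5.0

    def __post_init__(self) -> None:
        if len(self.native_trio) != 3 or len(self.labelled_trio) != 3:
            raise ValueError("diagnostic trios must have exactly 3 members")
        if any(m <= 0 for m in (*self.native_trio, self.supplementary,
                                *self.labelled_trio)):
            raise ValueError("diagnostic m/z values must be positive")


@dataclass(frozen=True)
class FormulaMatch:
    """One enumerated ion composition with its mass error."""

    formula: ElementalFormula
    ppm_error: float

    @property
    def neutral(self) -> ElementalFormula:
        return replace(self.formula, n_hydrogen=self.formula.n_hydrogen + 1)


def enumerate_formulas(
    observed_mz: float,
    constraints: CompositionConstraints | None = None,
) -> list[FormulaMatch]:
    """Enumerate CHO ion compositions matching an observed [M-H]- m/z.

    Scans the full (C, H, O) grid within the constraint bounds (hydrogen
    bound applied to the ion's hydrogen count) and keeps compositions that

    * match ``observed_mz`` within ``mass_tol_ppm``,
    * have neutral RDBE within [rdbe_min, rdbe_max], and
    * deprotonate from an even-electron neutral, i.e. have odd ion hydrogen
      count (the operative form of the even-electron rule for CHO anions).

    Returns matches sorted by absolute ppm error, ties broken by fewer
    oxygens then lexicographic (C, H). An empty list means the ion fails the
    elemental restriction — it is a filter outcome, not an error.
    """
    if observed_mz <= 0:
        raise ValueError("observed_mz must be positive")
    cons = constraints if constraints is not None else CompositionConstraints()

    c = np.arange(cons.c_min, cons.c_max + 1)
    o = np.arange(cons.o_min, cons.o_max + 1)
    # odd ion-H values within the (inclusive) hydrogen bounds
    h_lo = cons.h_min if cons.h_min % 2 == 1 else cons.h_min + 1
    h = np.arange(h_lo, cons.h_max + 1, 2)
    if h.size == 0:
        return []

    C, H, O = np.meshgrid(c, h, o, indexing="ij")
    mass = C * MASS_C12 + H * MASS_H + O * MASS_O + MASS_ELECTRON
    ppm = (mass - observed_mz) / observed_mz * 1e6
    rdbe = C - (H + 1) / 2.0 + 1.0
    keep = (np.abs(ppm) <= cons.mass_tol_ppm) & (rdbe >= cons.rdbe_min) & (
        rdbe <= cons.rdbe_max
    )

    matches = [
        FormulaMatch(
            ElementalFormula(int(ci), int(hi), int(oi)), float(ppm_i)
        )
        for ci, hi, oi, ppm_i in zip(
            C[keep], H[keep], O[keep], ppm[keep]
        )
    ]
    matches.sort(
        key=lambda m: (
            abs(m.ppm_error),
            m.formula.n_oxygen,
            m.formula.n_carbon,
            m.formula.n_hydrogen,
        )
    )
    return matches
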