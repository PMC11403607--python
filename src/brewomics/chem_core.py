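"""Exact-mass arithmetic and molecular-formula assignment over the CHNOSPCl space.

Implements the compositional layer of a direct-infusion ultrahigh-resolution
MS workflow: monoisotopic masses, the deprotonated-ion ([M-H]-) convention,
combinatorial formula enumeration under plausibility constraints, van Krevelen
(H/C vs O/C) compound-class regions, in-silico deglycosylation and accurate-mass
library matching.

Conventions
-----------
All neutral masses are monoisotopic sums of IUPAC atomic masses. Negative-mode
ion m/z includes the electron mass::

    m/z([M-H]-) = M_neutral - (m_H - m_e) = M_neutral - 1.00727645 Da

so that e.g. the bisulfate anion HSO4- computes to 96.9601 Th.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ELEMENTS = ("C", "H", "N", "O", "S", "P", "Cl")

#: Monoisotopic atomic masses, Da (IUPAC/CODATA, >=6 decimals).
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 0.00054857990907
#: Mass removed on deprotonation of the neutral (H atom minus one electron).
DEPROTONATION_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

_MASS_VEC = np.array([MONOISOTOPIC_MASS[e] for e in ELEMENTS])

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Invalid molecular formula or ion request."""


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """Element-count vector over C, H, N, O, S, P, Cl."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0
    P: int = 0
    Cl: int = 0

    def __post_init__(self) -> None:
        counts = self.counts()
        if any(v < 0 for v in counts.values()):
            raise FormulaError(f"negative element count in {counts}")
        if sum(counts.values()) == 0:
            raise FormulaError("formula must contain at least one atom")

    def counts(self) -> dict[str, int]:
        return {e: getattr(self, e) for e in ELEMENTS}

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse a formula string such as ``C18H32SO6`` (any element order)."""
        s = text.strip()
        if not s:
            raise FormulaError("empty formula string")
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(s):
            if m.start() != pos or not m.group(0):
                break
            el, num = m.group(1), m.group(2)
            if el not in ELEMENTS:
                raise FormulaError(f"unsupported element {el!r} in {text!r}")
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(s):
            raise FormulaError(f"cannot parse formula {text!r}")
        return cls(**counts)

    def hill(self) -> str:
        """Hill-order string: C, H, then remaining elements alphabetically."""
        parts = []
        order = ["C", "H"] + sorted(e for e in ELEMENTS if e not in ("C", "H"))
        for e in order:
            n = getattr(self, e)
            if n == 1:
                parts.append(e)
            elif n > 1:
                parts.append(f"{e}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    @property
    def hc(self) -> float:
        if self.C == 0:
            raise FormulaError("H/C undefined for carbon-free formula")
        return self.H / self.C

    @property
    def oc(self) -> float:
        if self.C == 0:
            raise FormulaError("O/C undefined for carbon-free formula")
        return self.O / self.C

    @property
    def dbe(self) -> float:
        return dbe(self)

    def heteroatoms(self) -> int:
        """Total non-CH atom count (N + O + S + P + Cl)."""
        return self.N + self.O + self.S + self.P + self.Cl

    def combine(self, other: "MolecularFormula") -> "MolecularFormula":
        return MolecularFormula(
            **{e: getattr(self, e) + getattr(other, e) for e in ELEMENTS}
        )


@dataclass(frozen=True)
class IonSpec:
    """Ion convention. Only the deprotonated anion [M-H]- is supported."""

    adduct: str = "[M-H]-"
    charge: int = -1

    def __post_init__(self) -> None:
        if self.adduct != "[M-H]-" or self.charge != -1:
            raise FormulaError(f"unsupported ion {self.adduct} charge {self.charge}")


DEFAULT_ION = IonSpec()


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da."""
    return float(sum(n * MONOISOTOPIC_MASS[e] for e, n in formula.counts().items()))


def ion_mz(formula: MolecularFormula, ion: IonSpec = DEFAULT_ION) -> float:
    """m/z of the deprotonated anion, electron mass included."""
    if formula.H < 1:
        raise FormulaError(f"{formula.hill()} has no H to lose for {ion.adduct}")
    return monoisotopic_mass(formula) - DEPROTONATION_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def dbe(formula: MolecularFormula) -> float:
    """Ring-plus-double-bond equivalents; half-integer values mark radicals."""
    f = formula
    return f.C + 1 + (f.N + f.P) / 2 - (f.H + f.Cl) / 2


def van_krevelen(formula: MolecularFormula) -> tuple[float, float]:
    """(O/C, H/C) elemental ratios for van Krevelen mapping."""
    return (formula.oc, formula.hc)


# ---------------------------------------------------------------------------
# formula enumeration
# ---------------------------------------------------------------------------

#: Default per-element (min, max) bounds; sized for m/z <= 1000.
DEFAULT_BOUNDS: dict[str, tuple[int, int]] = {
    "C": (1, 66),
    "H": (0, 126),
    "N": (0, 6),
    "O": (0, 30),
    "S": (0, 3),
    "P": (0, 2),
    "Cl": (0, 2),
}


@dataclass(frozen=True)
class Constraints:
    """Plausibility filters applied during enumeration (golden-rules style)."""

    hc_min: float = 0.2
    hc_max: float = 3.1
    oc_max: float = 1.5
    require_integer_dbe: bool = True
    dbe_min: float = 0.0
    dbe_max: float = 40.0


DEFAULT_CONSTRAINTS = Constraints()

#: Default element space for *unique* formula annotation: CHO, CHNO (N<=3)
#: and CHOS/CHNOS (S<=1), the composition classes of fermented beverages.
#: Without isotopologue verification, exotic multi-heteroatom alternatives
#: (P, Cl, N4S2, ...) form sub-0.2-ppm mass doublets with common CHO
#: compositions; widen the bounds explicitly to search beyond this space.
ANNOTATION_BOUNDS: dict[str, tuple[int, int]] = {
    **DEFAULT_BOUNDS, "N": (0, 3), "S": (0, 1), "P": (0, 0), "Cl": (0, 0),
}


@dataclass(frozen=True)
class FormulaCandidate:
    formula: MolecularFormula
    theoretical_mz: float
    ppm: float
    dbe: float


def _bounds_key(bounds: dict[str, tuple[int, int]]) -> tuple:
    return tuple((e, *bounds[e]) for e in ELEMENTS)


@lru_cache(maxsize=8)
def _hydrogen_free_grid(key: tuple, ckey: tuple) -> dict:
    """H-free element grid with precomputed per-row hydrogen admissibility.

    For every (C,N,O,S,P,Cl) combination the H-independent constraints are
    folded into a static admissible H range [h_lo, h_hi] and an H parity
    (integer-DBE) target, so a query only has to round the residual mass.
    Rows whose H range is empty or which fail O/C are dropped up front.
    """
    b = {e: (lo, hi) for e, lo, hi in key}
    cons = Constraints(*ckey)
    axes = [np.arange(b[e][0], b[e][1] + 1) for e in ("C", "N", "O", "S", "P", "Cl")]
    mesh = np.meshgrid(*axes, indexing="ij")
    counts = np.stack([m.ravel() for m in mesh], axis=1)
    c, n, o, s, p, cl = (counts[:, i] for i in range(6))

    h_lo = np.maximum(b["H"][0], np.ceil(cons.hc_min * c - 1e-9)).astype(np.int64)
    h_lo = np.maximum(h_lo, 1)  # [M-H]- needs an H
    h_hi = np.minimum(b["H"][1], np.floor(cons.hc_max * c + 1e-9)).astype(np.int64)
    # DBE >= dbe_min: H <= 2C + 2 + N + P - Cl - 2*dbe_min
    h_hi = np.minimum(h_hi, 2 * c + 2 + n + p - cl - int(np.ceil(2 * cons.dbe_min)))
    # DBE <= dbe_max: H >= 2C + 2 + N + P - Cl - 2*dbe_max
    h_lo = np.maximum(h_lo, 2 * c + 2 + n + p - cl - int(np.floor(2 * cons.dbe_max)))
    parity = (n + p + cl) % 2  # H parity giving integer DBE

    keep = (c >= 1) & (o <= cons.oc_max * c + 1e-9) & (h_lo <= h_hi)
    counts = counts[keep]
    masses = counts @ np.array(
        [MONOISOTOPIC_MASS[e] for e in ("C", "N", "O", "S", "P", "Cl")]
    )
    order = np.argsort(masses)
    return {
        "counts": np.ascontiguousarray(counts[order]),
        "mass": masses[order],
        "h_lo": h_lo[keep][order],
        "h_hi": h_hi[keep][order],
        "parity": parity[keep][order],
        "check_parity": cons.require_integer_dbe,
    }


def enumerate_formulas(
    mz: float,
    tol_ppm: float,
    bounds: dict[str, tuple[int, int]] | None = None,
    ion: IonSpec = DEFAULT_ION,
    constraints: Constraints = DEFAULT_CONSTRAINTS,
) -> list[FormulaCandidate]:
    """All formulas whose [M-H]- ion lies within ``tol_ppm`` of ``mz``.

    Exhaustive over the bound box. Because every element mass other than H
    exceeds the tolerance window, the H count of a candidate is determined by
    rounding the residual mass, which reduces the search to the H-free grid.

    Candidates are ranked by \\|ppm\\| ascending, then fewer heteroatoms
    (N+O+S+P+Cl), then Hill-order string.
    """
    if mz <= 0:
        raise ValueError("mz must be positive")
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    for e in ELEMENTS:
        bounds.setdefault(e, (0, 0))

    ckey = (constraints.hc_min, constraints.hc_max, constraints.oc_max,
            constraints.require_integer_dbe, constraints.dbe_min,
            constraints.dbe_max)
    grid = _hydrogen_free_grid(_bounds_key(bounds), ckey)
    m_target = mz + DEPROTONATION_MASS
    tol_da = tol_ppm * 1e-6 * mz
    m_h = MONOISOTOPIC_MASS["H"]

    # mass window on the sorted H-free masses: base = M - h*m_H for some
    # admissible h, so base lies within [M - Hmax*m_H - tol, M - m_H + tol]
    base_all = grid["mass"]
    lo_idx = np.searchsorted(base_all, m_target - bounds["H"][1] * m_h - tol_da)
    hi_idx = np.searchsorted(base_all, m_target - m_h + tol_da)
    sl = slice(lo_idx, hi_idx)
    base_mass = base_all[sl]
    counts = grid["counts"][sl]

    # residual mass -> candidate H count (unique: tol_da << m_H)
    h = np.rint((m_target - base_mass) / m_h).astype(np.int64)
    ok = (h >= grid["h_lo"][sl]) & (h <= grid["h_hi"][sl])
    if grid["check_parity"]:
        ok &= h % 2 == grid["parity"][sl]
    theo = base_mass + h * m_h - DEPROTONATION_MASS
    ok &= np.abs(theo - mz) <= tol_da

    out: list[FormulaCandidate] = []
    for i in np.nonzero(ok)[0]:
        row = counts[i]
        f = MolecularFormula(
            C=int(row[0]), H=int(h[i]), N=int(row[1]), O=int(row[2]),
            S=int(row[3]), P=int(row[4]), Cl=int(row[5]),
        )
        out.append(
            FormulaCandidate(
                formula=f,
                theoretical_mz=float(theo[i]),
                ppm=ppm_error(mz, float(theo[i])),
                dbe=dbe(f),
            )
        )
    out.sort(key=lambda cand: (abs(cand.ppm), cand.formula.heteroatoms(), cand.formula.hill()))
    return out


# ---------------------------------------------------------------------------
# van Krevelen compound-class regions
# ---------------------------------------------------------------------------

_PREDICATES = {
    "cho_only": lambda f: f.N == 0 and f.S == 0 and f.P == 0 and f.Cl == 0,
    "requires_s": lambda f: f.S >= 1,
    "requires_n": lambda f: f.N >= 1,
    "requires_n2": lambda f: f.N >= 2,
    "any": lambda f: True,
}


@dataclass(frozen=True)
class CompoundClassRegion:
    """A rectangular H/C x O/C box plus a heteroatom predicate."""

    label: str
    hc_min: float
    hc_max: float
    oc_min: float
    oc_max: float
    predicate: str = "any"

    def __post_init__(self) -> None:
        if self.hc_min > self.hc_max or self.oc_min > self.oc_max:
            raise ValueError(f"empty region box for {self.label!r}")
        if self.predicate not in _PREDICATES:
            raise ValueError(f"unknown predicate {self.predicate!r}")

    def contains(self, formula: MolecularFormula) -> bool:
        hc, oc = formula.hc, formula.oc
        return (
            self.hc_min <= hc <= self.hc_max
            and self.oc_min <= oc <= self.oc_max
            and _PREDICATES[self.predicate](formula)
        )


#: Priority-ordered default region table (conventional literature boxes).
DEFAULT_REGIONS: tuple[CompoundClassRegion, ...] = (
    CompoundClassRegion("sulfonolipid-like", 1.5, 2.3, 0.0, 0.35, "requires_s"),
    CompoundClassRegion("lipid-like", 1.5, 2.3, 0.0, 0.35, "cho_only"),
    CompoundClassRegion("carbohydrate-like", 1.5, 2.3, 0.65, 1.05, "cho_only"),
    CompoundClassRegion("polyphenol/glycoside-like", 0.6, 1.5, 0.35, 0.9, "cho_only"),
    CompoundClassRegion("amino-sugar/Maillard-conjugate-like", 0.8, 2.0, 0.2, 0.8, "requires_n"),
    CompoundClassRegion("peptide-like", 1.0, 2.0, 0.1, 0.45, "requires_n2"),
)

UNCLASSIFIED = "unclassified"


def classify_compound_class(
    formula: MolecularFormula,
    regions: Sequence[CompoundClassRegion] = DEFAULT_REGIONS,
) -> str:
    """Label of the first matching region in priority order, else 'unclassified'."""
    for region in regions:
        if region.contains(formula):
            return region.label
    return UNCLASSIFIED


def load_regions(path: str | Path) -> list[CompoundClassRegion]:
    """Read a region table from JSON (list of objects) or delimited text.

    Text columns: label, hc_min, hc_max, oc_min, oc_max, predicate.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        rows = json.loads(text)
        return [CompoundClassRegion(**row) for row in rows]
    regions = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[\t,;]\s*|\s{2,}|\t", line)
        if len(parts) < 6:
            parts = line.split()
        label, hc_min, hc_max, oc_min, oc_max, predicate = parts[:6]
        regions.append(
            CompoundClassRegion(label, float(hc_min), float(hc_max),
                                float(oc_min), float(oc_max), predicate)
        )
    return regions


# ---------------------------------------------------------------------------
# deglycosylation and library matching
# ---------------------------------------------------------------------------

def _residue_mass(formula: str) -> float:
    return monoisotopic_mass(MolecularFormula.parse(formula))


#: Glycosidic residue masses (sugar minus H2O), Da.
DEFAULT_RESIDUES: dict[str, float] = {
    "hexose": _residue_mass("C6H10O5"),       # 162.0528
    "pentose": _residue_mass("C5H8O4"),       # 132.0423
    "deoxyhexose": _residue_mass("C6H10O4"),  # 146.0579
}


@dataclass(frozen=True)
class DeglycosylationCandidate:
    aglycone_mz: float
    residue: str
    multiplicity: int


def deglycosylate(
    mz: float,
    residues: dict[str, float] | None = None,
    max_multiplicity: int = 3,
    floor_mz: float = 100.0,
) -> list[DeglycosylationCandidate]:
    """Candidate aglycone m/z values after stripping 1..k sugar residues."""
    residues = DEFAULT_RESIDUES if residues is None else residues
    if not residues:
        raise ValueError("residue set must not be empty")
    out = []
    for name, r in sorted(residues.items()):
        for k in range(1, max_multiplicity + 1):
            candidate = mz - k * r
            if candidate < floor_mz:
                break
            out.append(DeglycosylationCandidate(candidate, name, k))
    return out


@dataclass(frozen=True)
class LibraryMatch:
    query_mz: float
    name: str
    formula: MolecularFormula
    theoretical_mz: float
    ppm: float


def load_library(path: str | Path) -> list[tuple[str, MolecularFormula]]:
    """Read a 2-column compound library (name, Hill formula); '#' comments."""
    entries = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[\t,;]", line)
        if len(parts) < 2:
            parts = line.rsplit(None, 1)
        name, formula = parts[0].strip(), parts[1].strip()
        entries.append((name, MolecularFormula.parse(formula)))
    return entries


def match_library(
    masses: Iterable[float],
    library: Sequence[tuple[str, MolecularFormula]],
    tol_ppm: float,
    ion: IonSpec = DEFAULT_ION,
) -> list[LibraryMatch]:
    """All (query m/z, library entry) pairs agreeing within ``tol_ppm``."""
    if not library:
        raise ValueError("library must not be empty")
    theo = [(name, f, ion_mz(f, ion)) for name, f in library]
    matches = []
    for q in masses:
        for name, f, t in theo:
            err = ppm_error(q, t)
            if abs(err) <= tol_ppm:
                matches.append(LibraryMatch(q, name, f, t, err))
    return matches
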