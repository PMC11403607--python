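"""Rule-based sulfur oxidation-state calls from negative-mode tandem spectra.

A sulfonate (C-SO3-) releases SO2- / SO3- radical anions and the SO3 neutral
loss under collision-induced dissociation, whereas an aliphatically bound
sulfate (O-SO3-) eliminates a bisulfate anion HSO4- (96.9601). The classifier
matches these diagnostic ions and neutral losses within a mass tolerance and
returns a verdict with the supporting evidence; bisulfate evidence always
dominates (a sulfate call overrides sulfonate-type fragments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .chem_core import ELECTRON_MASS, MONOISOTOPIC_MASS

_M = MONOISOTOPIC_MASS

#: Diagnostic anion m/z (monoisotopic, electron mass included), Th.
DIAGNOSTIC_IONS: dict[str, float] = {
    "SO2-": _M["S"] + 2 * _M["O"] + ELECTRON_MASS,          # 63.9625
    "SO3-": _M["S"] + 3 * _M["O"] + ELECTRON_MASS,          # 79.9574
    "HSO4-": _M["H"] + _M["S"] + 4 * _M["O"] + ELECTRON_MASS,  # 96.9601
}

#: Diagnostic neutral-loss masses, Da.
NEUTRAL_LOSSES: dict[str, float] = {
    "H2O": 2 * _M["H"] + _M["O"],            # 18.0106
    "SO3": _M["S"] + 3 * _M["O"],            # 79.9568
}

SULFONATE_IONS = ("SO2-", "SO3-")
SULFATE_ION = "HSO4-"


class MGFError(ValueError):
    """Malformed MGF input."""


@dataclass
class MS2Spectrum:
    """One product-ion spectrum: precursor m/z plus (m/z, intensity) fragments."""

    precursor_mz: float
    fragments: np.ndarray  # shape (n, 2), sorted by m/z ascending
    title: str = ""

    def __post_init__(self) -> None:
        frags = np.asarray(self.fragments, dtype=float).reshape(-1, 2)
        self.fragments = frags[np.argsort(frags[:, 0], kind="stable")]
        if len(self.fragments) and self.fragments[:, 0].max() >= self.precursor_mz + 0.5:
            raise MGFError(
                f"fragment above precursor in spectrum {self.title!r}"
            )

    @property
    def base_peak_intensity(self) -> float:
        return float(self.fragments[:, 1].max()) if len(self.fragments) else 0.0


def read_mgf(path: str | Path) -> list[MS2Spectrum]:
    """Parse an MGF file into spectra (fragments sorted ascending)."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise MGFError(f"block {i}: missing PEPMASS")
            frags = np.column_stack([
                entry.get("m/z array", np.empty(0)),
                entry.get("intensity array", np.empty(0)),
            ]) if len(entry.get("m/z array", ())) else np.empty((0, 2))
            try:
                spectra.append(MS2Spectrum(
                    precursor_mz=float(pepmass[0]),
                    fragments=frags,
                    title=str(params.get("title", f"spectrum_{i}")),
                ))
            except (TypeError, ValueError) as exc:
                raise MGFError(f"block {i}: {exc}") from exc
    return spectra


def write_mgf(spectra: Sequence[MS2Spectrum], path: str | Path) -> None:
    """Write spectra as MGF (synthetic fixtures and pipeline output)."""
    entries = [
        {
            "m/z array": s.fragments[:, 0],
            "intensity array": s.fragments[:, 1],
            "params": {"title": s.title or f"spectrum_{i}",
                       "pepmass": s.precursor_mz, "charge": "1-"},
        }
        for i, s in enumerate(spectra)
    ]
    _mgf.write(entries, str(path), file_mode="w")


def _tolerance_da(target_mz: float, tol_mda: float, tol_ppm: float) -> float:
    """Absolute window: the larger of the mDa and ppm tolerances."""
    return max(tol_mda * 1e-3, target_mz * tol_ppm * 1e-6)


@dataclass(frozen=True)
class FragmentMatch:
    target: str
    target_mz: float
    observed_mz: float
    error_da: float
    ppm: float


def match_fragment(
    spectrum: MS2Spectrum,
    target_mz: float,
    tol_mda: float = 10.0,
    tol_ppm: float = 15.0,
    min_relative_intensity: float = 0.005,
    label: str = "",
) -> FragmentMatch | None:
    """Nearest fragment to ``target_mz`` within tolerance, or None.

    Fragments below ``min_relative_intensity`` of the base peak are ignored;
    ties on |error| resolve toward the lower-m/z fragment.
    """
    if tol_mda <= 0 and tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    if not len(spectrum.fragments):
        return None
    floor = min_relative_intensity * spectrum.base_peak_intensity
    frags = spectrum.fragments[spectrum.fragments[:, 1] >= floor]
    if not len(frags):
        return None
    tol_da = _tolerance_da(target_mz, tol_mda, tol_ppm)
    err = frags[:, 0] - target_mz
    inside = np.abs(err) <= tol_da
    if not inside.any():
        return None
    cand = np.nonzero(inside)[0]
    # stable nearest-wins: on an exact |error| tie the lower m/z (already
    # first in the sorted array) is kept
    best = cand[np.lexsort((frags[cand, 0], np.abs(err[cand])))[0]]
    obs = float(frags[best, 0])
    return FragmentMatch(
        target=label, target_mz=target_mz, observed_mz=obs,
        error_da=obs - target_mz, ppm=1e6 * (obs - target_mz) / target_mz,
    )


@dataclass(frozen=True)
class NeutralLoss:
    loss_mass: float
    fragment_mz: float
    label: str | None  # 'H2O' / 'SO3' when diagnostic, else None


def neutral_losses(
    spectrum: MS2Spectrum,
    tol_mda: float = 10.0,
    tol_ppm: float = 15.0,
) -> list[NeutralLoss]:
    """Precursor-minus-fragment losses, flagging diagnostic H2O and SO3."""
    out = []
    for mz, _ in spectrum.fragments:
        loss = spectrum.precursor_mz - mz
        label = None
        for name, mass in NEUTRAL_LOSSES.items():
            if abs(loss - mass) <= _tolerance_da(mass, tol_mda, tol_ppm):
                label = name
                break
        out.append(NeutralLoss(float(loss), float(mz), label))
    return out


@dataclass
class SulfurCall:
    verdict: str  # 'sulfonate' | 'sulfate' | 'inconclusive'
    evidence: list = field(default_factory=list)


def classify_sulfur(
    spectrum: MS2Spectrum,
    tol_mda: float = 10.0,
    tol_ppm: float = 15.0,
    min_relative_intensity: float = 0.005,
) -> SulfurCall:
    """Sulfonate-vs-sulfate verdict from diagnostic fragments and losses.

    A bisulfate (HSO4-) match forces 'sulfate'. Otherwise SO2-/SO3- fragments
    or an SO3 neutral loss give 'sulfonate'. No evidence -> 'inconclusive'.
    """
    evidence: list = []
    sulfate_hit = match_fragment(
        spectrum, DIAGNOSTIC_IONS[SULFATE_ION], tol_mda, tol_ppm,
        min_relative_intensity, label=SULFATE_ION,
    )
    if sulfate_hit is not None:
        return SulfurCall("sulfate", [sulfate_hit])

    for name in SULFONATE_IONS:
        hit = match_fragment(
            spectrum, DIAGNOSTIC_IONS[name], tol_mda, tol_ppm,
            min_relative_intensity, label=name,
        )
        if hit is not None:
            evidence.append(hit)
    so3_losses = [
        nl for nl in neutral_losses(spectrum, tol_mda, tol_ppm) if nl.label == "SO3"
    ]
    evidence.extend(so3_losses)
    if evidence:
        return SulfurCall("sulfonate", evidence)
    return SulfurCall("inconclusive", [])
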