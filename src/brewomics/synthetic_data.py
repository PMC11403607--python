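"""Synthetic two-line beer-aging experiments with known ground truth.

Emulates the study design the pipeline targets: two brewing lines (T =
whole-malt, K = husk-separated) sampled at four storage timepoints in three
replicates, with thousands of features drawn from CHO / CHNO / CHOS formula
families occupying their van Krevelen class regions. A planted subset rises
multiplicatively with storage in both lines (attenuated in K, in slope and
baseline), line-specific markers are spiked (sulfonolipid- and
polyphenol/glycoside-like in T; N-containing conjugate-like in K), and
realistic nuisances are added: ppm-scale mass error, log-normal intensity
noise and replicate dropout. A manifest records every planted parameter so
all pipeline stages can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import chem_core, ms2_rules
from .chem_core import MolecularFormula, classify_compound_class, ion_mz
from .ms2_rules import MS2Spectrum, DIAGNOSTIC_IONS, NEUTRAL_LOSSES
from .preprocessing import FeatureMatrix

LIPID = "lipid-like"
SULFONOLIPID = "sulfonolipid-like"
CARBOHYDRATE = "carbohydrate-like"
POLYPHENOL = "polyphenol/glycoside-like"
MAILLARD = "amino-sugar/Maillard-conjugate-like"

T_MARKER_CLASSES = (SULFONOLIPID, POLYPHENOL)
K_MARKER_CLASSES = (MAILLARD,)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic experiment; defaults are the study conditions."""

    seed: int
    n_features: int = 3000
    class_mix: dict = field(default_factory=lambda: {
        LIPID: 0.25, SULFONOLIPID: 0.10, CARBOHYDRATE: 0.25,
        POLYPHENOL: 0.20, MAILLARD: 0.20,
    })
    aging_fraction: float = 0.15
    aging_slope_range: tuple[float, float] = (0.15, 0.6)
    k_attenuation: float = 0.6
    n_t_markers: int = 50
    n_k_markers: int = 50
    marker_fold: float = 3.0
    intensity_sdlog: float = 0.2
    mass_error_ppm_sd: float = 0.05  # FT-ICR regime; ~2 ppm for ToF
    dropout_probability: float = 0.05
    lines: tuple[str, ...] = ("T", "K")
    timepoints: tuple[str, ...] = ("t0", "t1", "t2", "t3")
    n_replicates: int = 3
    mz_window: tuple[float, float] = (120.0, 1000.0)
    baseline_log_mean: float = np.log(1e6)
    baseline_log_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if sum(self.class_mix.values()) > 1 + 1e-9:
            raise ValueError("class-mix fractions must sum to <= 1")
        for rate in (self.aging_fraction, self.dropout_probability):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")


def _even_near(x: float) -> int:
    return int(2 * round(x / 2))


def _sample_formula(label: str, rng: np.random.Generator) -> MolecularFormula | None:
    """One rejection-sampling draw aimed at the given class region."""
    if label == LIPID or label == SULFONOLIPID:
        c = int(rng.integers(12, 33))
        h = _even_near(c * rng.uniform(1.55, 2.25))
        o_hi = max(2, int(0.35 * c))
        o = int(rng.integers(2, o_hi + 1)) if label == LIPID else int(
            rng.integers(3, max(4, o_hi + 1))
        )
        s = 1 if label == SULFONOLIPID else 0
        kwargs = {"C": c, "H": h, "O": o, "S": s}
    elif label == CARBOHYDRATE:
        # mono- up to penta-saccharide-like sizes
        c = int(rng.integers(6, 37))
        h = _even_near(c * rng.uniform(1.55, 2.25))
        o = int(rng.integers(int(np.ceil(0.65 * c)), min(int(1.05 * c), 30) + 1))
        kwargs = {"C": c, "H": h, "O": o}
    elif label == POLYPHENOL:
        c = int(rng.integers(12, 41))
        h = _even_near(c * rng.uniform(0.65, 1.45))
        o = int(rng.integers(int(np.ceil(0.35 * c)), min(int(0.9 * c), 30) + 1))
        kwargs = {"C": c, "H": h, "O": o}
    elif label == MAILLARD:
        c = int(rng.integers(8, 31))
        n = int(rng.integers(1, 3))
        h = _even_near(c * rng.uniform(0.85, 1.95) - n) + n  # H = N (mod 2)
        o = int(rng.integers(int(np.ceil(0.2 * c)), min(int(0.8 * c), 30) + 1))
        kwargs = {"C": c, "H": h, "N": n, "O": o}
    else:
        raise ValueError(f"no sampler for class {label!r}")
    if kwargs["H"] < 1:
        return None
    try:
        f = MolecularFormula(**kwargs)
    except chem_core.FormulaError:
        return None
    if f.dbe < 0 or f.dbe != int(f.dbe):
        return None
    return f


def generate_library(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample ``n_features`` distinct formulas across the configured classes.

    Rejection sampling guarantees each formula lies in its class's van
    Krevelen region (per the default region table) and that its [M-H]- ion
    falls inside the mass window.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    counts = {
        label: int(round(frac * config.n_features))
        for label, frac in config.class_mix.items()
    }
    # fix rounding drift on the largest class
    drift = config.n_features - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift

    seen: set[MolecularFormula] = set()
    rows = []
    lo, hi = config.mz_window
    for label, want in counts.items():
        got = 0
        attempts = 0
        while got < want:
            attempts += 1
            if attempts > 2000 * max(want, 1):
                raise RuntimeError(f"class box {label!r} appears infeasible")
            f = _sample_formula(label, rng)
            if f is None or f in seen:
                continue
            if classify_compound_class(f) != label:
                continue
            mz = ion_mz(f)
            if not lo <= mz <= hi:
                continue
            seen.add(f)
            rows.append({"formula": f.hill(), "compound_class": label, "mz": mz})
            got += 1
    return pd.DataFrame(rows)


@dataclass
class SyntheticExperiment:
    peaklists: dict[str, pd.DataFrame]
    metadata: pd.DataFrame
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sid, df in self.peaklists.items():
            df.to_csv(outdir / f"{sid}.csv", index=False, float_format="%.8f")
        self.metadata.to_csv(outdir / "metadata.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=1))


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def generate_experiment(config: GeneratorConfig) -> SyntheticExperiment:
    """Simulate per-sample peak lists for the full two-line design.

    Intensity model per feature i, line L, timepoint index tau, replicate r::

        I = baseline_i * a_L * (1 + beta_i * b_L)^tau * fold_i(L) * exp(eps)

    with (a_L, b_L) = (1, 1) in line T and (delta, delta) in line K for aging
    features (non-aging features have beta = 0 and no attenuation), marker
    fold applied only in the marker's own line, and eps ~ N(0, sdlog^2).
    Observed m/z get relative Gaussian error of the configured ppm scale, and
    each (feature, sample) pair drops out independently.
    """
    rng = np.random.default_rng(config.seed)
    library = generate_library(config, rng)
    n = len(library)

    baselines = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)

    marker = np.array([None] * n, dtype=object)
    t_pool = library.index[library["compound_class"].isin(T_MARKER_CLASSES)].to_numpy()
    k_pool = library.index[library["compound_class"].isin(K_MARKER_CLASSES)].to_numpy()
    if len(t_pool) < config.n_t_markers or len(k_pool) < config.n_k_markers:
        raise ValueError(
            f"marker pools too small ({len(t_pool)} T-class, {len(k_pool)} K-class "
            f"features) for {config.n_t_markers}/{config.n_k_markers} markers; "
            "lower the marker counts or raise n_features"
        )
    t_ids = rng.choice(t_pool, size=config.n_t_markers, replace=False)
    k_ids = rng.choice(k_pool, size=config.n_k_markers, replace=False)
    marker[t_ids] = "T"
    marker[k_ids] = "K"

    aging = np.zeros(n, dtype=bool)
    non_marker = np.nonzero(marker == None)[0]  # noqa: E711 - object array
    n_aging = int(round(config.aging_fraction * n))
    aging[rng.choice(non_marker, size=n_aging, replace=False)] = True
    betas = np.where(
        aging, rng.uniform(*config.aging_slope_range, n), 0.0
    )

    samples = []
    for line in config.lines:
        for tp in config.timepoints:
            for r in range(1, config.n_replicates + 1):
                samples.append({
                    "sample_id": f"B_{line}_{tp}_R{r}",
                    "line": line, "timepoint": tp, "replicate": f"R{r}",
                })
    metadata = pd.DataFrame(samples)

    theo_mz = library["mz"].to_numpy()
    delta = config.k_attenuation
    peaklists: dict[str, pd.DataFrame] = {}
    for sample in samples:
        line, tau = sample["line"], config.timepoints.index(sample["timepoint"])
        atten = delta if line == "K" else 1.0
        base = np.where(aging, baselines * atten, baselines)
        slope = np.where(aging, (1.0 + betas * (atten if line == "K" else 1.0)) ** tau, 1.0)
        fold = np.where(marker == line, config.marker_fold, 1.0)
        noise = np.exp(rng.normal(0.0, config.intensity_sdlog, n))
        intensity = base * slope * fold * noise
        mz_obs = theo_mz * (1.0 + rng.normal(0.0, config.mass_error_ppm_sd * 1e-6, n))
        snr = rng.uniform(10.0, 100.0, n)
        keep = rng.random(n) >= config.dropout_probability
        df = pd.DataFrame({
            "mz": mz_obs[keep], "intensity": intensity[keep], "snr": snr[keep],
        }).sort_values("mz", kind="stable").reset_index(drop=True)
        peaklists[sample["sample_id"]] = df

    manifest = {
        "config": {**asdict(config)},
        "features": [
            {
                "id": f"L{i:05d}",
                "formula": library.at[i, "formula"],
                "compound_class": library.at[i, "compound_class"],
                "mz": float(theo_mz[i]),
                "baseline": float(baselines[i]),
                "aging": bool(aging[i]),
                "beta": float(betas[i]),
                "marker": marker[i],
            }
            for i in range(n)
        ],
    }
    return SyntheticExperiment(peaklists, metadata, manifest)


def generate_ms2(
    formula: MolecularFormula,
    sulfur_kind: str,
    rng: np.random.Generator,
    n_decoys: int = 8,
    mass_error_ppm_sd: float = 2.0,
    title: str = "",
) -> MS2Spectrum:
    """Synthetic product-ion spectrum with planted diagnostic evidence.

    ``sulfur_kind``: 'sulfonate' injects SO2-/SO3- ions plus SO3 and H2O
    losses; 'sulfate' injects the bisulfate anion; 'none' emits decoys only.
    """
    if sulfur_kind not in ("sulfonate", "sulfate", "none"):
        raise ValueError(f"unknown sulfur kind {sulfur_kind!r}")
    if sulfur_kind != "none" and formula.S < 1:
        raise ValueError("sulfur kind requires an S-containing formula")
    precursor = ion_mz(formula)

    mzs, intens = [], []
    if sulfur_kind == "sulfonate":
        mzs += [DIAGNOSTIC_IONS["SO2-"], DIAGNOSTIC_IONS["SO3-"],
                precursor - NEUTRAL_LOSSES["SO3"], precursor - NEUTRAL_LOSSES["H2O"]]
        intens += list(rng.uniform(200.0, 1000.0, 4))
    elif sulfur_kind == "sulfate":
        mzs += [DIAGNOSTIC_IONS["HSO4-"]]
        intens += [float(rng.uniform(200.0, 1000.0))]
    decoys = rng.uniform(50.0, precursor - 5.0, n_decoys)
    mzs += list(decoys)
    intens += list(rng.uniform(10.0, 500.0, n_decoys))

    mz_arr = np.asarray(mzs) * (1.0 + rng.normal(0.0, mass_error_ppm_sd * 1e-6, len(mzs)))
    return MS2Spectrum(
        precursor_mz=precursor,
        fragments=np.column_stack([mz_arr, intens]),
        title=title or f"{formula.hill()}_{sulfur_kind}",
    )


# ---------------------------------------------------------------------------
# ground-truth scoring helpers
# ---------------------------------------------------------------------------

def match_features_to_truth(
    matrix: FeatureMatrix, manifest: dict, tol_ppm: float = 1.0
) -> pd.Series:
    """Map each matrix feature to the nearest planted feature within tol (ppm).

    Returns a Series indexed by matrix feature id holding the manifest id or
    None. Each planted feature is matched at most once (nearest wins).
    """
    truth = pd.DataFrame(manifest["features"]).set_index("id")
    truth_mz = truth["mz"].sort_values()
    mapping = {}
    used = set()
    for fid, mz in matrix.features["mz"].items():
        pos = np.searchsorted(truth_mz.to_numpy(), mz)
        best, best_err = None, np.inf
        for j in (pos - 1, pos):
            if 0 <= j < len(truth_mz):
                err = abs(mz - truth_mz.iloc[j]) / truth_mz.iloc[j] * 1e6
                if err < best_err:
                    best, best_err = truth_mz.index[j], err
        if best is not None and best_err <= tol_ppm and best not in used:
            mapping[fid] = best
            used.add(best)
        else:
            mapping[fid] = None
    return pd.Series(mapping, name="truth_id")


def annotation_recovery(matrix: FeatureMatrix, manifest: dict, tol_ppm: float = 1.0) -> float:
    """Fraction of planted features present in the matrix whose unique formula
    annotation equals the planted formula."""
    truth = {f["id"]: f["formula"] for f in manifest["features"]}
    mapping = match_features_to_truth(matrix, manifest, tol_ppm)
    matched = mapping.dropna()
    if matched.empty:
        return 0.0
    correct = sum(
        matrix.features.at[fid, "formula"] == truth[tid]
        for fid, tid in matched.items()
    )
    return correct / len(matched)


def selection_metrics(
    selected_ids: Sequence[str],
    matrix: FeatureMatrix,
    manifest: dict,
    flag: str = "aging",
    tol_ppm: float = 1.0,
) -> dict:
    """Sensitivity and false-discovery proportion of a selected feature set.

    ``flag`` is 'aging' (boolean truth) or 'marker' (truth = any non-null
    marker line). Sensitivity is computed against planted positives that are
    present in the matrix at all.
    """
    truth = pd.DataFrame(manifest["features"]).set_index("id")
    if flag == "aging":
        positive = set(truth.index[truth["aging"]])
    elif flag == "marker":
        positive = set(truth.index[truth["marker"].notna()])
    else:
        raise ValueError(f"unknown truth flag {flag!r}")
    mapping = match_features_to_truth(matrix, manifest, tol_ppm)
    present_positive = {tid for tid in mapping.dropna() if tid in positive}

    selected = set(selected_ids)
    true_hits = {fid for fid in selected if mapping.get(fid) in positive}
    sensitivity = len(true_hits) / len(present_positive) if present_positive else 0.0
    fdp = 1.0 - len(true_hits) / len(selected) if selected else 0.0
    return {
        "sensitivity": sensitivity,
        "fdp": fdp,
        "precision": 1.0 - fdp,
        "n_selected": len(selected),
        "n_positive_present": len(present_positive),
    }
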