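"""Peak-list ingestion, replicate consensus and feature-matrix assembly.

Direct-infusion peak lists (one per line x timepoint x replicate) are filtered
to the working mass window and signal-to-noise floor, merged across replicates
with the at-least-2-of-3 presence rule (intensities averaged over contributing
replicates), aligned across sample groups on a ppm tolerance, and annotated
with unique molecular formulas.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import chem_core
from .chem_core import (
    ANNOTATION_BOUNDS,
    Constraints,
    DEFAULT_CONSTRAINTS,
    DEFAULT_REGIONS,
)

LINES = ("T", "K")
TIMEPOINTS = ("t0", "t1", "t2", "t3")


class PeaklistError(ValueError):
    """Malformed peak-list input."""


def read_peaklist(path_or_buf) -> pd.DataFrame:
    """Read a delimited peak list with header ``mz,intensity[,snr]``.

    Raises :class:`PeaklistError` naming the offending line for non-numeric
    rows or negative intensities. Input row order is preserved.
    """
    df = pd.read_csv(path_or_buf, sep=None, engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if "mz" not in df.columns or "intensity" not in df.columns:
        raise PeaklistError("peak list must have 'mz' and 'intensity' columns")
    cols = ["mz", "intensity"] + (["snr"] if "snr" in df.columns else [])
    df = df[cols]
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            # +2: 1-based lines plus the header row
            raise PeaklistError(
                f"non-numeric {col!r} value at line {int(bad.idxmax()) + 2}"
            )
        df[col] = vals
    if df["mz"].isna().any() or df["intensity"].isna().any():
        line = int(df[["mz", "intensity"]].isna().any(axis=1).idxmax()) + 2
        raise PeaklistError(f"missing mz/intensity at line {line}")
    if (df["mz"] <= 0).any():
        line = int((df["mz"] <= 0).idxmax()) + 2
        raise PeaklistError(f"non-positive m/z at line {line}")
    if (df["intensity"] < 0).any():
        line = int((df["intensity"] < 0).idxmax()) + 2
        raise PeaklistError(f"negative intensity at line {line}")
    return df.reset_index(drop=True)


def filter_peaks(
    peaks: pd.DataFrame,
    mass_window: tuple[float, float] = (120.0, 1000.0),
    min_snr: float = 6.0,
) -> pd.DataFrame:
    """Keep peaks inside the mass window and at/above the S/N floor.

    Peaks without an S/N column (or with missing S/N) pass the S/N filter.
    """
    low, high = mass_window
    if low >= high:
        raise ValueError("mass window low must be below high")
    keep = (peaks["mz"] >= low) & (peaks["mz"] <= high)
    if "snr" in peaks.columns:
        keep &= peaks["snr"].isna() | (peaks["snr"] >= min_snr)
    return peaks.loc[keep].reset_index(drop=True)


def _cluster_mz(mz: np.ndarray, tol_ppm: float) -> np.ndarray:
    """Single-linkage cluster ids for sorted-order grouping on relative gaps."""
    order = np.argsort(mz, kind="stable")
    sorted_mz = mz[order]
    gaps = np.diff(sorted_mz) / sorted_mz[:-1] * 1e6
    breaks = np.concatenate([[0], np.cumsum(gaps > tol_ppm)])
    ids = np.empty(len(mz), dtype=np.int64)
    ids[order] = breaks
    return ids


def _split_duplicate_sources(df: pd.DataFrame, cluster_col: str, source_col: str) -> pd.DataFrame:
    """Split clusters containing two peaks from one source at the widest gap.

    Keeps the alignment a partition: every input peak lands in exactly one
    cluster and no cluster holds two peaks from the same replicate/group.
    """
    df = df.sort_values([cluster_col, "mz"], kind="stable").reset_index(drop=True)
    next_id = df[cluster_col].max() + 1 if len(df) else 0
    while True:
        dup = df.groupby(cluster_col)[source_col].apply(lambda s: s.duplicated().any())
        bad = dup[dup].index
        if len(bad) == 0:
            return df
        for cid in bad:
            idx = df.index[df[cluster_col] == cid]
            mzs = df.loc[idx, "mz"].to_numpy()
            split = int(np.argmax(np.diff(mzs))) + 1
            df.loc[idx[split:], cluster_col] = next_id
            next_id += 1


def consensus_replicates(
    replicates: Sequence[pd.DataFrame],
    tol_ppm: float = 1.0,
    min_presence: int = 2,
) -> pd.DataFrame:
    """Merge replicate peak lists into consensus peaks.

    Peaks are grouped across replicates by single-linkage on m/z with a ppm
    gap threshold. Groups observed in at least ``min_presence`` replicates
    emit one consensus peak: m/z is the intensity-weighted mean, intensity
    the arithmetic mean over contributing replicates.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    if min_presence > len(replicates):
        raise ValueError(
            f"min_presence={min_presence} exceeds replicate count {len(replicates)}"
        )
    frames = []
    for i, rep in enumerate(replicates):
        if len(rep):
            frames.append(pd.DataFrame(
                {"mz": rep["mz"], "intensity": rep["intensity"], "rep": i}
            ))
    if not frames:
        return pd.DataFrame(columns=["mz", "intensity", "n_replicates"])
    allpeaks = pd.concat(frames, ignore_index=True)
    allpeaks["cluster"] = _cluster_mz(allpeaks["mz"].to_numpy(), tol_ppm)
    allpeaks = _split_duplicate_sources(allpeaks, "cluster", "rep")

    rows = []
    for _, grp in allpeaks.groupby("cluster"):
        if grp["rep"].nunique() < min_presence:
            continue
        w = grp["intensity"].to_numpy()
        mz = grp["mz"].to_numpy()
        cons_mz = float(np.average(mz, weights=w)) if w.sum() > 0 else float(mz.mean())
        rows.append((cons_mz, float(grp["intensity"].mean()), int(grp["rep"].nunique())))
    out = pd.DataFrame(rows, columns=["mz", "intensity", "n_replicates"])
    return out.sort_values("mz", kind="stable").reset_index(drop=True)


@dataclass
class FeatureMatrix:
    """Features x sample-groups intensity table with feature annotations.

    ``features`` holds per-feature metadata (consensus mz, formula, H/C, O/C,
    compound class, annotation flag); ``intensities`` is indexed identically
    with one column per sample group; missing cells are NaN. ``samples``
    carries the sample metadata table when available.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.intensities.index):
            raise ValueError("feature and intensity indexes must match")
        if len(self.intensities) and self.intensities.isna().all(axis=1).any():
            raise ValueError("all-missing feature row")

    @property
    def n_features(self) -> int:
        return len(self.features)

    def to_tsv(self, path: str | Path) -> None:
        pd.concat([self.features, self.intensities], axis=1).to_csv(
            path, sep="\t", index_label="feature_id"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, samples: pd.DataFrame | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        meta_cols = [c for c in ("mz", "formula", "hc", "oc", "compound_class", "flag")
                     if c in df.columns]
        return cls(df[meta_cols], df.drop(columns=meta_cols), samples)


def align_groups(
    groups: Mapping[str, pd.DataFrame],
    tol_ppm: float = 1.0,
) -> FeatureMatrix:
    """Align per-group consensus peak lists into a feature matrix.

    Features are matched across groups by the same single-linkage ppm rule
    used for replicate consensus; cells with no peak stay missing. Every
    input peak contributes to exactly one feature.
    """
    if len(groups) < 2:
        raise ValueError("need at least two sample groups to align")
    frames = []
    for name, df in groups.items():
        if len(df):
            frames.append(pd.DataFrame(
                {"mz": df["mz"], "intensity": df["intensity"], "group": name}
            ))
    allpeaks = pd.concat(frames, ignore_index=True)
    allpeaks["cluster"] = _cluster_mz(allpeaks["mz"].to_numpy(), tol_ppm)
    allpeaks = _split_duplicate_sources(allpeaks, "cluster", "group")

    records = []
    for _, grp in allpeaks.groupby("cluster"):
        w = grp["intensity"].to_numpy()
        mz = grp["mz"].to_numpy()
        cons = float(np.average(mz, weights=w)) if w.sum() > 0 else float(mz.mean())
        rec = {"mz": cons}
        rec.update(dict(zip(grp["group"], grp["intensity"])))
        records.append(rec)
    records.sort(key=lambda r: r["mz"])
    ids = pd.Index([f"F{i:06d}" for i in range(len(records))], name="feature_id")
    table = pd.DataFrame(records, index=ids)
    features = table[["mz"]].copy()
    for col in ("formula", "compound_class", "flag"):
        features[col] = pd.Series(dtype="object")
    features["hc"] = np.nan
    features["oc"] = np.nan
    features = features[["mz", "formula", "hc", "oc", "compound_class", "flag"]]
    intensities = table.reindex(columns=list(groups), fill_value=np.nan)
    return FeatureMatrix(features, intensities)


def annotate_matrix(
    matrix: FeatureMatrix,
    tol_ppm: float = 0.2,
    bounds: dict | None = None,
    constraints: Constraints = DEFAULT_CONSTRAINTS,
    regions=DEFAULT_REGIONS,
) -> FeatureMatrix:
    """Assign unique molecular formulas to features in place.

    A feature is annotated only when formula enumeration at the working
    tolerance returns exactly one candidate; features with several candidates
    are flagged ``ambiguous``, features with none ``unassigned``. The default
    search space is CHNOS (:data:`brewomics.chem_core.ANNOTATION_BOUNDS`):
    P/Cl alternatives are close enough in mass to common CHO compositions
    that unique assignment in the full space would need isotope verification.
    """
    feats = matrix.features
    if bounds is None:
        bounds = ANNOTATION_BOUNDS
    for fid, mz in feats["mz"].items():
        cands = chem_core.enumerate_formulas(
            float(mz), tol_ppm, bounds=bounds, constraints=constraints
        )
        if len(cands) == 1:
            f = cands[0].formula
            feats.at[fid, "formula"] = f.hill()
            feats.at[fid, "hc"] = f.hc
            feats.at[fid, "oc"] = f.oc
            feats.at[fid, "compound_class"] = chem_core.classify_compound_class(f, regions)
            feats.at[fid, "flag"] = "unique"
        elif len(cands) == 0:
            feats.at[fid, "flag"] = "unassigned"
        else:
            feats.at[fid, "flag"] = "ambiguous"
    return matrix


def read_metadata(path_or_buf) -> pd.DataFrame:
    """Read the sample metadata table (sample_id,line,timepoint,replicate[,stage]).

    Sample ids in the ``B_T_t0_R1`` style are accepted and parsed as a
    fallback when the explicit columns are absent.
    """
    df = pd.read_csv(path_or_buf)
    df.columns = [c.strip().lower() for c in df.columns]
    if "sample_id" not in df.columns:
        raise ValueError("metadata must have a sample_id column")
    if not {"line", "timepoint", "replicate"} <= set(df.columns):
        parts = df["sample_id"].str.split("_", expand=True)
        if parts.shape[1] < 4:
            raise ValueError("cannot infer line/timepoint/replicate from sample ids")
        df["line"], df["timepoint"], df["replicate"] = parts[1], parts[2], parts[3]
    dupes = df.duplicated(subset=["line", "timepoint", "replicate"])
    if dupes.any():
        raise ValueError("duplicate (line, timepoint, replicate) in metadata")
    return df


def build_group_matrix(
    peaklists: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
    tol_ppm: float = 1.0,
    min_presence: int = 2,
    mass_window: tuple[float, float] = (120.0, 1000.0),
    min_snr: float = 6.0,
    timepoints: Sequence[str] = TIMEPOINTS,
) -> FeatureMatrix:
    """Full replicate-averaged pipeline: filter, consensus per group, align.

    Groups are (line, timepoint) pairs; the resulting columns are named
    ``{line}_{timepoint}``.
    """
    groups: dict[str, pd.DataFrame] = {}
    meta = metadata[metadata["timepoint"].isin(timepoints)]
    for (line, tp), sub in meta.groupby(["line", "timepoint"], sort=False):
        reps = [
            filter_peaks(peaklists[sid], mass_window, min_snr)
            for sid in sub["sample_id"]
        ]
        groups[f"{line}_{tp}"] = consensus_replicates(reps, tol_ppm, min_presence)
    ordered = {
        f"{line}_{tp}": groups[f"{line}_{tp}"]
        for line in sorted(meta["line"].unique())
        for tp in timepoints
        if f"{line}_{tp}" in groups
    }
    fm = align_groups(ordered, tol_ppm)
    fm.samples = metadata
    return fm


def build_sample_matrix(
    peaklists: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
    tol_ppm: float = 1.0,
    min_presence: int = 2,
    mass_window: tuple[float, float] = (120.0, 1000.0),
    min_snr: float = 6.0,
    timepoints: Sequence[str] = TIMEPOINTS,
    max_missing_fraction: float = 0.5,
) -> FeatureMatrix:
    """Replicate-level matrix for supervised statistics (one column per sample).

    Per-sample peak lists are aligned directly; features failing the
    ``min_presence``-of-replicates rule in every (line, timepoint) group, or
    missing in more than ``max_missing_fraction`` of samples, are dropped.
    """
    meta = metadata[metadata["timepoint"].isin(timepoints)]
    filtered = {
        sid: filter_peaks(peaklists[sid], mass_window, min_snr)
        for sid in meta["sample_id"]
    }
    fm = align_groups(filtered, tol_ppm)
    inten = fm.intensities

    present = inten.notna()
    group_ok = pd.DataFrame(index=inten.index)
    for (line, tp), sub in meta.groupby(["line", "timepoint"], sort=False):
        group_ok[f"{line}_{tp}"] = present[list(sub["sample_id"])].sum(axis=1) >= min_presence
    keep = group_ok.any(axis=1) & (present.mean(axis=1) >= 1 - max_missing_fraction)
    fm = FeatureMatrix(fm.features.loc[keep].copy(), inten.loc[keep].copy(), metadata)
    return fm


def percent_change(reference: float, comparison: float) -> float:
    """Relative change of ``comparison`` vs ``reference`` in percent."""
    if reference <= 0:
        raise ValueError("reference value must be positive")
    return 100.0 * (comparison - reference) / reference


def dlg_score(
    odor: float, taste: float, palate_fullness: float,
    carbonation: float, bitterness_quality: float,
) -> float:
    """Weighted 5-point sensory score.

    score = (2*odor + 2*taste + palate fullness + carbonation
             + 2*quality of bitterness) / 8, each rating in [0, 5].
    """
    ratings = (odor, taste, palate_fullness, carbonation, bitterness_quality)
    for r in ratings:
        if not 0 <= r <= 5:
            raise ValueError(f"rating {r} outside [0, 5]")
    return (2 * odor + 2 * taste + palate_fullness + carbonation
            + 2 * bitterness_quality) / 8.0
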