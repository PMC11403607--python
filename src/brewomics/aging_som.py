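"""Self-organizing-map extraction of aging-related intensity trajectories.

Each feature's replicate-averaged intensities over the storage series of both
brewing lines (T: t0..t3, then K: t0..t3) form one 8-vector, z-scored jointly
so that trajectory *shape*, not scale, drives clustering. A rectangular
Kohonen map is trained online; a map node qualifies as "aging" when its mean
member profile rises consistently with storage time in BOTH lines (Spearman
rank correlation with time above a threshold and last > first in each line
segment). The aging set is the union of features assigned to qualifying nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from .preprocessing import FeatureMatrix, LINES, TIMEPOINTS


@dataclass
class TrajectorySet:
    """Per-feature raw and z-normalized trajectories over (T then K) timepoints."""

    feature_ids: list[str]
    raw: np.ndarray          # n_features x (n_lines * n_timepoints)
    normalized: np.ndarray   # same shape, per-row mean 0 / unit variance
    filled: np.ndarray       # boolean mask of imputed cells
    lines: tuple[str, ...]
    timepoints: tuple[str, ...]
    excluded: list[str] = field(default_factory=list)


def build_trajectories(
    matrix: FeatureMatrix,
    lines: Sequence[str] = LINES,
    timepoints: Sequence[str] = TIMEPOINTS,
) -> TrajectorySet:
    """Assemble per-feature trajectories from a group-level feature matrix.

    Missing cells are filled with the feature's minimum observed intensity in
    that line (flagged in ``filled``); features missing an entire line are
    excluded. Rows are z-scored over the concatenated vector; constant rows
    become all zeros.
    """
    if len(timepoints) < 3:
        raise ValueError("need at least three timepoints")
    cols = [f"{line}_{tp}" for line in lines for tp in timepoints]
    missing_cols = [c for c in cols if c not in matrix.intensities.columns]
    if missing_cols:
        raise ValueError(f"matrix lacks sample groups: {missing_cols}")
    block = matrix.intensities[cols]
    n_tp = len(timepoints)

    ids, rows, fills, excluded = [], [], [], []
    for fid, row in block.iterrows():
        vec = row.to_numpy(dtype=float)
        fill = np.isnan(vec)
        segs = []
        ok = True
        for i in range(len(lines)):
            seg = vec[i * n_tp:(i + 1) * n_tp]
            if np.isnan(seg).all():
                ok = False
                break
            seg = np.where(np.isnan(seg), np.nanmin(seg), seg)
            segs.append(seg)
        if not ok:
            excluded.append(fid)
            continue
        ids.append(fid)
        rows.append(np.concatenate(segs))
        fills.append(fill)

    raw = np.asarray(rows, dtype=float).reshape(len(ids), len(cols))
    sd = raw.std(axis=1, keepdims=True)
    mean = raw.mean(axis=1, keepdims=True)
    normalized = np.where(sd > 0, (raw - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return TrajectorySet(
        ids, raw, normalized, np.asarray(fills, dtype=bool).reshape(raw.shape),
        tuple(lines), tuple(timepoints), excluded,
    )


@njit(cache=False)
def _train_online(codebook, data, order, lr0, lr1, rad0, rad1, node_dist2):
    n_nodes, dim = codebook.shape
    steps = order.size
    for s in range(steps):
        frac = s / steps
        lr = lr0 * (lr1 / lr0) ** frac
        rad = rad0 * (rad1 / rad0) ** frac
        x = data[order[s]]
        best = 0
        best_d = 1e300
        for j in range(n_nodes):
            acc = 0.0
            for k in range(dim):
                diff = codebook[j, k] - x[k]
                acc += diff * diff
            if acc < best_d:
                best_d = acc
                best = j
        denom = 2.0 * rad * rad
        for j in range(n_nodes):
            h = lr * math.exp(-node_dist2[best, j] / denom)
            if h > 1e-12:
                for k in range(dim):
                    codebook[j, k] += h * (x[k] - codebook[j, k])


@dataclass
class SOMModel:
    grid: tuple[int, int]
    codebook: np.ndarray           # n_nodes x dim
    assignments: np.ndarray        # feature index -> node index
    node_profiles: np.ndarray      # n_nodes x dim mean member trajectory (NaN if empty)
    feature_ids: list[str]
    settings: dict
    qe_initial: float
    qe_final: float
    lines: tuple[str, ...] = LINES
    timepoints: tuple[str, ...] = TIMEPOINTS

    @property
    def n_nodes(self) -> int:
        return self.grid[0] * self.grid[1]

    def node_members(self, node: int) -> list[str]:
        return [self.feature_ids[i] for i in np.nonzero(self.assignments == node)[0]]


def _node_distances_sq(grid: tuple[int, int]) -> np.ndarray:
    rows, cols = grid
    pos = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)
    diff = pos[:, None, :] - pos[None, :, :]
    return (diff ** 2).sum(axis=2)


def quantization_error(codebook: np.ndarray, data: np.ndarray) -> float:
    """Mean Euclidean distance of each trajectory to its best-matching unit."""
    return float(cdist(data, codebook).min(axis=1).mean())


def train_som(
    trajectories: TrajectorySet,
    grid: tuple[int, int] = (10, 10),
    epochs: int = 500,
    learning_rate: tuple[float, float] = (0.5, 0.01),
    radius: tuple[float, float] | None = None,
    seed: int = 0,
) -> SOMModel:
    """Train a rectangular Kohonen map on the normalized trajectories.

    Classic online updates: codebook seeded uniformly within the per-dimension
    data span; per step the best-matching unit (minimum Euclidean distance) is
    pulled toward the sample together with its Gaussian neighborhood; learning
    rate and radius decay exponentially between their initial and final values.
    One epoch presents every trajectory once in a seeded random order. Final
    assignments are recomputed in a single vectorized pass.
    """
    data = np.ascontiguousarray(trajectories.normalized, dtype=np.float64)
    if data.shape[0] == 0:
        raise ValueError("no trajectories to train on")
    n_nodes = grid[0] * grid[1]
    if data.shape[0] < n_nodes:
        import warnings

        warnings.warn(
            f"{data.shape[0]} trajectories for {n_nodes} map nodes; "
            "consider a smaller grid", stacklevel=2,
        )
    if radius is None:
        radius = (max(grid) / 2.0, 1.0)

    rng = np.random.default_rng(seed)
    lo, hi = data.min(axis=0), data.max(axis=0)
    codebook = rng.uniform(lo, hi, size=(n_nodes, data.shape[1]))
    qe_init = quantization_error(codebook, data)

    order = np.concatenate(
        [rng.permutation(data.shape[0]) for _ in range(epochs)]
    ).astype(np.int64)
    node_dist2 = _node_distances_sq(grid)
    _train_online(
        codebook, data, order,
        float(learning_rate[0]), float(learning_rate[1]),
        float(radius[0]), float(radius[1]), node_dist2,
    )

    assignments = cdist(data, codebook).argmin(axis=1)
    profiles = np.full((n_nodes, data.shape[1]), np.nan)
    for node in range(n_nodes):
        members = assignments == node
        if members.any():
            profiles[node] = data[members].mean(axis=0)

    return SOMModel(
        grid=grid,
        codebook=codebook,
        assignments=assignments,
        node_profiles=profiles,
        feature_ids=list(trajectories.feature_ids),
        settings={
            "epochs": epochs, "learning_rate": learning_rate,
            "radius": radius, "seed": seed,
        },
        qe_initial=qe_init,
        qe_final=quantization_error(codebook, data),
        lines=trajectories.lines,
        timepoints=trajectories.timepoints,
    )


@dataclass
class AgingSet:
    """Features whose map nodes rise consistently with aging in both lines."""

    selected_ids: list[str]
    qualifying_nodes: np.ndarray   # boolean per node
    rho_min: float


def _segment_qualifies(segment: np.ndarray, rho_min: float) -> bool:
    if segment[-1] <= segment[0]:
        return False
    rho = spearmanr(segment, np.arange(len(segment))).statistic
    return bool(rho >= rho_min - 1e-9)


def select_aging_clusters(som: SOMModel, rho_min: float = 0.9) -> AgingSet:
    """Apply the consistent-increase rule to every map node.

    A node qualifies iff its mean member profile, split into the per-line
    segments, has Spearman rank correlation with time >= ``rho_min`` AND a
    last value above the first value in EVERY line segment.

    With four timepoints the achievable per-segment correlations are
    {1, 0.8, 0.6, ...}; the default ``rho_min`` of 0.9 therefore demands a
    strictly monotone mean profile ("consistent increase"), while 0.8 would
    also admit profiles with one internal rank swap.
    """
    n_tp = len(som.timepoints)
    flags = np.zeros(som.n_nodes, dtype=bool)
    for node in range(som.n_nodes):
        prof = som.node_profiles[node]
        if np.isnan(prof).any():
            continue
        flags[node] = all(
            _segment_qualifies(prof[i * n_tp:(i + 1) * n_tp], rho_min)
            for i in range(len(som.lines))
        )
    selected = [
        fid for fid, node in zip(som.feature_ids, som.assignments) if flags[node]
    ]
    return AgingSet(selected, flags, rho_min)


def compare_lines(
    matrix: FeatureMatrix,
    aging_ids: Sequence[str],
    lines: Sequence[str] = LINES,
    timepoints: Sequence[str] = TIMEPOINTS,
) -> pd.DataFrame:
    """Relative-intensity box-plot summaries of the aging set per line.

    Each feature is scaled by its own maximum across all line/timepoint
    groups; the table reports median, quartiles and n for each line both
    aggregated over all timepoints and resolved per timepoint.
    """
    if len(aging_ids) == 0:
        raise ValueError("aging set is empty")
    cols = [f"{line}_{tp}" for line in lines for tp in timepoints]
    block = matrix.intensities.loc[list(aging_ids), cols]
    rel = block.div(block.max(axis=1), axis=0)

    rows = []
    for line in lines:
        line_cols = [f"{line}_{tp}" for tp in timepoints]
        pooled = rel[line_cols].to_numpy().ravel()
        pooled = pooled[~np.isnan(pooled)]
        rows.append({
            "line": line, "scope": "aggregated",
            "median": float(np.median(pooled)),
            "q1": float(np.percentile(pooled, 25)),
            "q3": float(np.percentile(pooled, 75)),
            "n": int(pooled.size),
        })
        for tp in timepoints:
            vals = rel[f"{line}_{tp}"].dropna().to_numpy()
            rows.append({
                "line": line, "scope": tp,
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25)),
                "q3": float(np.percentile(vals, 75)),
                "n": int(vals.size),
            })
    return pd.DataFrame(rows)
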