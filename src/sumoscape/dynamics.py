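"""Temporal label-free-quantification (LFQ) profiling.

The quantitative pipeline mirrors a standard Perseus/Morpheus workflow over a
6-timepoint × 3-replicate meiotic time course:

    RAW (per-sample intensities)
      → AVERAGED (replicate means per timepoint)
      → LOG2
      → IMPUTED (per-column downshifted normal for missing values)
      → ZSCORED (per-row mean 0 / sample SD 1)

followed by hierarchical clustering of rows under the 1 − Pearson
correlation distance, a Pearson similarity matrix, min–max-normalized
profiles, cumulative site intensities, and per-timepoint identification
counts.  Each stage validates the state of its input so the pipeline order
cannot be violated silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from sumoscape.tables_io import ProteinRecord, SampleDesign, SiteRecord

DEFAULT_IMPUTE_WIDTH = 0.3
DEFAULT_IMPUTE_DOWNSHIFT = 1.8
DEFAULT_LINKAGE = "average"


class MatrixState(str, Enum):
    RAW = "RAW"
    AVERAGED = "AVERAGED"
    LOG2 = "LOG2"
    IMPUTED = "IMPUTED"
    ZSCORED = "ZSCORED"


class PipelineStateError(ValueError):
    """An operation received a matrix in the wrong pipeline state."""


@dataclass
class ProfileMatrix:
    """Rows = proteins or sites, columns = samples or timepoints.

    ``data`` holds floats with NaN for missing; ``state`` records the
    pipeline stage; ``flagged_rows`` lists row ids excluded from a stage
    (currently: zero-variance rows that cannot be z-scored).
    """

    data: pd.DataFrame
    state: MatrixState
    flagged_rows: list[str] = field(default_factory=list)

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def _require(self, state: MatrixState, op: str) -> None:
        if self.state is not state:
            raise PipelineStateError(
                f"{op} expects a {state.value} matrix, got {self.state.value}"
            )


def matrix_from_sites(sites: Sequence[SiteRecord], design: SampleDesign) -> ProfileMatrix:
    """RAW per-sample site-intensity matrix (rows = site ids)."""
    data = pd.DataFrame(
        [[_nan(s.intensities.get(c)) for c in design.samples] for s in sites],
        index=[s.site_id for s in sites],
        columns=list(design.samples),
        dtype=float,
    )
    return ProfileMatrix(data, MatrixState.RAW)


def matrix_from_proteins(proteins: Sequence[ProteinRecord], design: SampleDesign) -> ProfileMatrix:
    """RAW per-sample protein LFQ matrix (rows = protein ids)."""
    data = pd.DataFrame(
        [[_nan(p.lfq.get(c)) for c in design.samples] for p in proteins],
        index=[p.protein_id for p in proteins],
        columns=list(design.samples),
        dtype=float,
    )
    return ProfileMatrix(data, MatrixState.RAW)


def _nan(v: float | None) -> float:
    return np.nan if v is None else float(v)


def average_replicates(matrix: ProfileMatrix, design: SampleDesign) -> ProfileMatrix:
    """Mean of non-missing replicate values per timepoint; all-missing stays missing."""
    matrix._require(MatrixState.RAW, "average_replicates")
    for col in matrix.columns:
        if col not in design.timepoint_of:
            raise KeyError(f"column {col!r} is not assigned in the sample design")
    cols = {}
    for tp in design.timepoints:
        reps = [s for s in design.replicates_of(tp) if s in matrix.data.columns]
        cols[tp] = matrix.data[reps].mean(axis=1, skipna=True)
    return ProfileMatrix(pd.DataFrame(cols, index=matrix.data.index), MatrixState.AVERAGED)


def log2_transform(matrix: ProfileMatrix) -> ProfileMatrix:
    """Elementwise log2; missing values preserved; non-positive values rejected."""
    matrix._require(MatrixState.AVERAGED, "log2_transform")
    vals = matrix.data.to_numpy()
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        row = matrix.row_ids[int(np.argwhere(bad)[0][0])]
        raise ValueError(f"non-positive intensity in row {row!r}; cannot log2-transform")
    return ProfileMatrix(
        pd.DataFrame(np.log2(vals), index=matrix.data.index, columns=matrix.data.columns),
        MatrixState.LOG2,
    )


def impute_downshift(
    matrix: ProfileMatrix,
    width: float = DEFAULT_IMPUTE_WIDTH,
    downshift: float = DEFAULT_IMPUTE_DOWNSHIFT,
    seed: int = 0,
) -> ProfileMatrix:
    """Impute missing cells from a downshifted normal, separately per column.

    For a column with observed mean m and sample SD s, each missing cell is
    drawn from Normal(m − downshift·s, (width·s)²).  The Perseus-style
    defaults (width 0.3, downshift 1.8) emulate the intensity-dependent
    missingness of label-free data: imputed values land in the low tail of
    the observed distribution.  Deterministic given ``seed``.
    """
    matrix._require(MatrixState.LOG2, "impute_downshift")
    rng = np.random.default_rng(seed)
    vals = matrix.data.to_numpy().copy()
    for j, col in enumerate(matrix.columns):
        colv = vals[:, j]
        obs = colv[~np.isnan(colv)]
        n_missing = int(np.isnan(colv).sum())
        if obs.size < 2 and n_missing:
            raise ValueError(
                f"column {col!r} has {obs.size} observed values; "
                "at least 2 are needed to impute"
            )
        if n_missing:
            m, s = obs.mean(), obs.std(ddof=1)
            draws = rng.normal(m - downshift * s, width * s, size=n_missing)
            colv[np.isnan(colv)] = draws
    return ProfileMatrix(
        pd.DataFrame(vals, index=matrix.data.index, columns=matrix.data.columns),
        MatrixState.IMPUTED,
    )


def zscore_rows(matrix: ProfileMatrix) -> ProfileMatrix:
    """Per-row z-scoring with the sample (n−1) SD.

    Zero-variance rows are returned unscaled and listed in ``flagged_rows``.
    """
    matrix._require(MatrixState.IMPUTED, "zscore_rows")
    vals = matrix.data.to_numpy()
    if np.isnan(vals).any():
        raise ValueError("z-scoring requires a fully imputed matrix (no missing values)")
    means = vals.mean(axis=1, keepdims=True)
    sds = vals.std(axis=1, ddof=1, keepdims=True)
    flat = sds[:, 0] == 0
    out = vals.copy()
    nz = ~flat
    out[nz] = (vals[nz] - means[nz]) / sds[nz]
    return ProfileMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        MatrixState.ZSCORED,
        flagged_rows=[rid for rid, f in zip(matrix.row_ids, flat) if f],
    )


@dataclass
class ClusterResult:
    """Agglomerative merge tree under the 1 − Pearson correlation distance."""

    linkage: np.ndarray          # scipy linkage matrix, n−1 merges
    row_ids: list[str]
    method: str
    distance: str = "one minus Pearson correlation"

    @property
    def leaf_order(self) -> list[str]:
        return [self.row_ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def flat_clusters(self, k: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.row_ids, (int(l) for l in labels)))

    def to_newick(self) -> str:
        """Merge tree as a Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.row_ids[node.id]
            left, right = node.get_left(), node.get_right()
            bl = lambda child: max(node.dist - child.dist, 0.0)
            return (
                f"({rec(left)}:{bl(left):.6g},{rec(right)}:{bl(right):.6g})"
            )

        return rec(tree) + ";"


def _pearson_condensed(vals: np.ndarray) -> np.ndarray:
    sds = vals.std(axis=1, ddof=1)
    if np.any(sds == 0):
        raise ValueError(
            "zero-variance row; z-score first and consult flagged_rows"
        )
    corr = np.corrcoef(vals)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return squareform(dist, checks=False)


def hierarchical_cluster(
    matrix: ProfileMatrix, linkage_method: str = DEFAULT_LINKAGE
) -> ClusterResult:
    """Cluster rows by 1 − Pearson correlation (average linkage by default)."""
    matrix._require(MatrixState.ZSCORED, "hierarchical_cluster")
    vals = matrix.data.to_numpy()
    if vals.shape[0] < 2:
        raise ValueError("clustering needs at least 2 rows")
    condensed = _pearson_condensed(vals)
    Z = hierarchy.linkage(condensed, method=linkage_method)
    return ClusterResult(linkage=Z, row_ids=matrix.row_ids, method=linkage_method)


def similarity_matrix(matrix: ProfileMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlations of rows; symmetric, unit diagonal."""
    if matrix.state not in (MatrixState.AVERAGED, MatrixState.LOG2,
                            MatrixState.IMPUTED, MatrixState.ZSCORED):
        raise PipelineStateError("similarity_matrix expects an averaged-or-later matrix")
    vals = matrix.data.to_numpy()
    sds = vals.std(axis=1, ddof=1)
    if np.isnan(vals).any():
        raise ValueError("similarity matrix requires complete rows")
    if np.any(sds == 0):
        raise ValueError("zero-variance row; cannot compute Pearson similarity")
    corr = np.corrcoef(vals)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.row_ids, columns=matrix.row_ids)


def normalized_profile(row: Sequence[float]) -> np.ndarray:
    """Min–max scale a temporal profile to [0, 1]."""
    v = np.asarray(row, dtype=float)
    if np.isnan(v).any():
        raise ValueError("profile contains missing values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("constant profile cannot be min-max normalized")
    return (v - lo) / (hi - lo)


def cumulative_site_intensity(
    sites: Sequence[SiteRecord],
) -> tuple[dict[str, float], set[str]]:
    """Total intensity per site across all samples.

    Returns the per-site sums (missing cells contribute 0) and the set of
    site ids whose intensities were all missing (reported as 0 and flagged).
    """
    totals: dict[str, float] = {}
    all_missing: set[str] = set()
    for s in sites:
        vals = [v for v in s.intensities.values() if v is not None]
        totals[s.site_id] = float(sum(vals))
        if not vals:
            all_missing.add(s.site_id)
    return totals, all_missing


def rank_sites_within_protein(
    sites: Sequence[SiteRecord],
) -> dict[str, list[str]]:
    """Per-protein site ids ordered by decreasing cumulative intensity."""
    totals, _ = cumulative_site_intensity(sites)
    by: dict[str, list[SiteRecord]] = {}
    for s in sites:
        by.setdefault(s.protein_id, []).append(s)
    return {
        pid: [s.site_id for s in sorted(group, key=lambda s: -totals[s.site_id])]
        for pid, group in by.items()
    }


def count_identified(
    matrix: ProfileMatrix, design: SampleDesign, mode: str = "any"
) -> dict[str, int]:
    """Rows identified per timepoint.

    A row counts at a timepoint when at least one replicate cell there holds
    a valid value (non-missing and > 0); ``mode="all"`` requires every
    replicate to be valid.
    """
    matrix._require(MatrixState.RAW, "count_identified")
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    counts: dict[str, int] = {}
    for tp in design.timepoints:
        reps = [s for s in design.replicates_of(tp) if s in matrix.data.columns]
        sub = matrix.data[reps].to_numpy()
        valid = ~np.isnan(sub) & (sub > 0)
        counts[tp] = int((valid.any(axis=1) if mode == "any" else valid.all(axis=1)).sum())
    return counts
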