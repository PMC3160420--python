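"""The differential regulome: cartesian-product counts and null models.

For every (TF, disease) pair the observed statistic b is, in the default
mode, the number of the disease's gene regions containing at least one of
the TF's binding locations.  Deviation from expectation is measured under
two analytic null models plus a Monte-Carlo permutation null, all sharing
the same placement assumption: gene regions are fixed, the number of
binding locations n_t of each TF is fixed, and the locations are placed
among the N *universe positions* — the positions carrying a binding
location for any TF in the study.

* hypergeometric null: the TF's n_t locations fall uniformly among the N
  universe positions, of which m_d lie inside disease d's regions;
  X ~ Hypergeom(N, m_d, n_t).
* binomial (differential) null: the TF lands inside disease d's regions in
  proportion to how often it lands inside gene-region sets across *all*
  diseases; X ~ Binom(n_t, p) with p = m_d * sum_d' b[t,d'] / (n_t * sum_d' m_d').
  This makes each cell differential: measured against the TF's own average.
* permutation null: direct resampling of the placement null; the reference
  when the analytic models' point-count approximation is in doubt.

The analytic tails are exact for point counts; with the segments-hit
statistic they are exact whenever each gene region contains at most one
universe position (true for TSS-style tracks, one point per target gene)
and approximate otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.stats import binom, hypergeom
from statsmodels.stats.multitest import multipletests

from .tracks import (
    PointTrack,
    SegmentTrack,
    TrackSet,
    count_points_in_segments,
    count_segments_hit,
    universe_positions,
)

logger = logging.getLogger(__name__)

StatisticMode = Literal["segments_hit", "points_in_segments"]
NullModel = Literal["hypergeometric", "binomial", "permutation"]
Correction = Literal["none", "bonferroni", "bh"]

__all__ = [
    "CountMatrix",
    "RegulomeMatrix",
    "build_count_matrix",
    "hypergeometric_null",
    "binomial_null",
    "permutation_null",
    "significance_flags",
]


@dataclass
class CountMatrix:
    """Observed counts b[t, d] plus the null-model margins.

    n_t[t] is the TF's number of binding locations (universe positions it
    occupies); N the universe size; m_d[d] the number of universe positions
    inside at least one gene region of disease d.
    """

    row_names: list[str]
    col_names: list[str]
    observed: np.ndarray  # (T, D) int
    n_t: np.ndarray  # (T,) int
    N: int
    m_d: np.ndarray  # (D,) int
    mode: StatisticMode = "segments_hit"

    def __post_init__(self) -> None:
        T, D = len(self.row_names), len(self.col_names)
        self.observed = np.asarray(self.observed, dtype=np.int64)
        self.n_t = np.asarray(self.n_t, dtype=np.int64)
        self.m_d = np.asarray(self.m_d, dtype=np.int64)
        if self.observed.shape != (T, D):
            raise ValueError("observed shape does not match names")
        if np.any(self.observed < 0) or np.any(self.n_t < 0) or np.any(self.m_d < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.n_t > self.N) or np.any(self.m_d > self.N):
            raise ValueError("margins exceed universe size")

    @property
    def shape(self) -> tuple[int, int]:
        return self.observed.shape


@dataclass
class RegulomeMatrix:
    """Per-cell expectation, variance, z and exact tail p-values under a null.

    z is NaN where the null variance is zero (no information in the cell);
    such cells are rendered as missing, never as z = 0.
    """

    counts: CountMatrix
    null_model: NullModel
    expected: np.ndarray
    variance: np.ndarray
    z: np.ndarray  # NaN = undefined
    p_over: np.ndarray
    p_under: np.ndarray
    sig_over: np.ndarray | None = None
    sig_under: np.ndarray | None = None
    alpha: float | None = None
    correction: Correction | None = None
    meta: dict = field(default_factory=dict)

    @property
    def row_names(self) -> list[str]:
        return self.counts.row_names

    @property
    def col_names(self) -> list[str]:
        return self.counts.col_names

    @property
    def z_defined(self) -> np.ndarray:
        return ~np.isnan(self.z)


def build_count_matrix(
    tf_tracks: TrackSet,
    disease_tracks: TrackSet,
    mode: StatisticMode = "segments_hit",
) -> CountMatrix:
    """Evaluate the statistic on the cartesian product of two track sets.

    Rows are the point tracks (TFs), columns the segment tracks (diseases).
    Also computes the universe size N and the per-disease margin m_d (a
    universe position inside several overlapping regions of one disease
    still counts once toward m_d).
    """
    if not all(isinstance(t, PointTrack) for t in tf_tracks):
        raise ValueError("tf_tracks must contain point tracks")
    if not all(isinstance(t, SegmentTrack) for t in disease_tracks):
        raise ValueError("disease_tracks must contain segment tracks")
    stat = count_segments_hit if mode == "segments_hit" else count_points_in_segments
    universe = universe_positions(tf_tracks)
    T, D = len(tf_tracks), len(disease_tracks)
    observed = np.zeros((T, D), dtype=np.int64)
    for ti, tf in enumerate(tf_tracks):
        for di, dis in enumerate(disease_tracks):
            observed[ti, di] = stat(dis, tf)
    n_t = np.array([t.n_points for t in tf_tracks], dtype=np.int64)
    m_d = np.array(
        [count_segments_containing_positions(dis, universe) for dis in disease_tracks],
        dtype=np.int64,
    )
    return CountMatrix(
        list(tf_tracks.names),
        list(disease_tracks.names),
        observed,
        n_t,
        universe.n_points,
        m_d,
        mode,
    )


def count_segments_containing_positions(
    segments: SegmentTrack, points: PointTrack
) -> int:
    """Number of distinct point positions inside >= 1 segment of the track."""
    counted = 0
    for chrom in points.chroms():
        arr = points.positions(chrom)
        if arr.size == 0:
            continue
        inside = np.zeros(arr.size, dtype=bool)
        for s in segments:
            if s.chrom != chrom:
                continue
            lo = np.searchsorted(arr, s.start, side="left")
            hi = np.searchsorted(arr, s.end, side="left")
            inside[lo:hi] = True
        counted += int(inside.sum())
    return counted


def _zscores(
    observed: np.ndarray, expected: np.ndarray, variance: np.ndarray
) -> np.ndarray:
    z = np.full(observed.shape, np.nan)
    ok = variance > 0
    z[ok] = (observed[ok] - expected[ok]) / np.sqrt(variance[ok])
    return z


def hypergeometric_null(counts: CountMatrix) -> RegulomeMatrix:
    """First test: uniform placement among universe positions.

    X[t, d] ~ Hypergeom(population N, successes m_d, draws n_t).
    E = n_t m_d / N; Var = n_t m_d (N - m_d)(N - n_t) / (N^2 (N - 1));
    p_over = P(X >= b) and p_under = P(X <= b) as exact tail sums.
    """
    N = counts.N
    if N <= 0:
        raise ValueError("empty universe")
    n_t = counts.n_t[:, None].astype(float)
    m_d = counts.m_d[None, :].astype(float)
    b = counts.observed
    if np.any(b > np.minimum(counts.n_t[:, None], counts.m_d[None, :])):
        raise ValueError("observed count exceeds min(n_t, m_d): inconsistent inputs")
    expected = n_t * m_d / N
    if N == 1:
        variance = np.zeros_like(expected)
    else:
        variance = n_t * m_d * (N - m_d) * (N - n_t) / (N**2 * (N - 1))
    M = np.broadcast_to(counts.m_d[None, :], b.shape)
    n = np.broadcast_to(counts.n_t[:, None], b.shape)
    p_over = hypergeom.sf(b - 1, N, M, n)
    p_under = hypergeom.cdf(b, N, M, n)
    return RegulomeMatrix(
        counts,
        "hypergeometric",
        expected,
        variance,
        _zscores(b, expected, variance),
        p_over,
        p_under,
        meta={"N": N},
    )


def binomial_null(counts: CountMatrix) -> RegulomeMatrix:
    """Second (differential) test: the TF's average in-region rate.

    p[t, d] = m_d * sum_d' b[t, d'] / (n_t * sum_d' m_d'): the TF's mean
    per-universe-position rate of falling inside disease gene regions,
    applied to the m_d positions of disease d.  X ~ Binom(n_t, p).  Row
    sums of the expectation equal row sums of the observations (the test is
    calibrated against the TF's own average across diseases).  p is capped
    into [0, 1] with a logged warning; capping signals a degenerate input.
    """
    sum_m = counts.m_d.sum()
    if sum_m <= 0:
        raise ValueError("all m_d are zero: no universe positions in any region set")
    b = counts.observed
    n_t = counts.n_t.astype(float)
    row_sums = b.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (counts.m_d[None, :] * row_sums[:, None]) / (n_t[:, None] * sum_m)
    p = np.where(n_t[:, None] > 0, p, 0.0)
    n_capped = int(np.sum(p > 1.0) + np.sum(p < 0.0))
    if n_capped:
        logger.warning("binomial null: capped %d cell probabilities into [0, 1]", n_capped)
    p = np.clip(p, 0.0, 1.0)
    expected = n_t[:, None] * p
    variance = n_t[:, None] * p * (1.0 - p)
    n = np.broadcast_to(counts.n_t[:, None], b.shape)
    p_over = binom.sf(b - 1, n, p)
    p_under = binom.cdf(b, n, p)
    mat = RegulomeMatrix(
        counts,
        "binomial",
        expected,
        variance,
        _zscores(b, expected, variance),
        p_over,
        p_under,
        meta={"N": counts.N, "capped_cells": n_capped},
    )
    return mat


def permutation_null(
    tf_tracks: TrackSet,
    disease_tracks: TrackSet,
    n_reps: int = 1000,
    seed: int = 0,
    mode: StatisticMode = "segments_hit",
) -> RegulomeMatrix:
    """Monte-Carlo realisation of the placement null.

    For each replicate and TF, n_t positions are drawn uniformly without
    replacement from the N universe positions and the statistic recomputed
    against every disease.  Empirical mean, sd (ddof=1) and z, with
    add-one-corrected tail p-values p = (r + 1) / (n_reps + 1).
    Deterministic given the seed.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    counts = build_count_matrix(tf_tracks, disease_tracks, mode)
    universe = universe_positions(tf_tracks)
    N = universe.n_points
    if np.any(counts.n_t > N):
        raise ValueError("a TF has more points than the universe")

    # Flatten universe positions and precompute, per disease, the
    # (universe-position, segment) containment pairs.
    uni_chroms: list[str] = []
    uni_pos: list[np.ndarray] = []
    offsets: dict[str, int] = {}
    off = 0
    for chrom in universe.chroms():
        arr = universe.positions(chrom)
        offsets[chrom] = off
        uni_chroms.append(chrom)
        uni_pos.append(arr)
        off += arr.size

    disease_pairs: list[tuple[np.ndarray, np.ndarray, int]] = []
    for dis in disease_tracks:
        uidx_parts, seg_parts = [], []
        for si, s in enumerate(dis):
            arr = universe.positions(s.chrom)
            lo = np.searchsorted(arr, s.start, side="left")
            hi = np.searchsorted(arr, s.end, side="left")
            if hi > lo:
                uidx_parts.append(np.arange(lo, hi) + offsets[s.chrom])
                seg_parts.append(np.full(hi - lo, si))
        uidx = np.concatenate(uidx_parts) if uidx_parts else np.empty(0, dtype=int)
        segs = np.concatenate(seg_parts) if seg_parts else np.empty(0, dtype=int)
        disease_pairs.append((uidx.astype(int), segs.astype(int), len(dis)))

    # Index of each TF's own points in the flattened universe (for b).
    rng = np.random.default_rng(seed)
    T, D = counts.shape
    stats = np.zeros((n_reps, T, D), dtype=np.int64)
    mask = np.zeros(N, dtype=bool)
    for rep in range(n_reps):
        for ti in range(T):
            n = int(counts.n_t[ti])
            draw = rng.choice(N, size=n, replace=False)
            mask[:] = False
            mask[draw] = True
            for di, (uidx, segs, n_segs) in enumerate(disease_pairs):
                sel = mask[uidx]
                if mode == "segments_hit":
                    if sel.any():
                        hits = np.bincount(segs[sel], minlength=n_segs)
                        stats[rep, ti, di] = int(np.count_nonzero(hits))
                else:
                    stats[rep, ti, di] = int(sel.sum())

    b = counts.observed
    expected = stats.mean(axis=0)
    sd = stats.std(axis=0, ddof=1)
    variance = sd**2
    z = _zscores(b, expected, variance)
    r_over = (stats >= b[None, :, :]).sum(axis=0)
    r_under = (stats <= b[None, :, :]).sum(axis=0)
    p_over = (r_over + 1) / (n_reps + 1)
    p_under = (r_under + 1) / (n_reps + 1)
    return RegulomeMatrix(
        counts,
        "permutation",
        expected,
        variance,
        z,
        p_over,
        p_under,
        meta={"N": N, "n_reps": n_reps, "seed": seed},
    )


def significance_flags(
    matrix: RegulomeMatrix,
    alpha: float = 0.05,
    correction: Correction = "bonferroni",
) -> RegulomeMatrix:
    """Flag significantly over-/under-represented cells.

    Two one-sided tests per cell; the multiple-testing family is the pooled
    2*T*D one-sided p-values.  Bonferroni compares each p to
    alpha / (2 T D); BH applies the step-up procedure over the pool.
    """
    T, D = matrix.counts.shape
    p_over, p_under = matrix.p_over, matrix.p_under
    if correction == "none":
        sig_over = p_over <= alpha
        sig_under = p_under <= alpha
    elif correction == "bonferroni":
        thresh = alpha / (2 * T * D)
        sig_over = p_over <= thresh
        sig_under = p_under <= thresh
    elif correction == "bh":
        pooled = np.concatenate([p_over.ravel(), p_under.ravel()])
        reject, *_ = multipletests(pooled, alpha=alpha, method="fdr_bh")
        sig_over = reject[: T * D].reshape(T, D)
        sig_under = reject[T * D :].reshape(T, D)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return replace(
        matrix,
        sig_over=sig_over,
        sig_under=sig_under,
        alpha=alpha,
        correction=correction,
    )
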