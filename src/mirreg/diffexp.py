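"""Paired tumor/normal differential expression.

The analysis chain for each expression bundle is:

1. drop features never detected in any sample (``detection_filter``),
2. log2-transform and median-center each array (``log2_median_center``),
3. call a feature up- or down-regulated only when the tumor-normal
   difference has the same sign in every patient pair
   (``consistent_direction``) -- with six pairs this consistency filter is
   the primary guard against spurious calls at tiny sample size,
4. attach a SAM-style paired d-statistic and a sign-flip permutation FDR
   (``permutation_fdr``), significance being declared at q below the
   configured threshold (default 0.1).

The d-statistic is d = mean(delta) / (se(delta) + s0) where delta are the
per-patient paired log2 differences and s0 is a small "fudge" constant that
keeps low-variance features from dominating the ranking. Here s0 is a
percentile (default 5th) of the feature-wise standard errors, a deliberate
simplification of the original coefficient-of-variation minimisation.

The q-value of a feature with observed |d| = t is the median, over sign-flip
permutations, of the count of null statistics at least t, divided by the
count of observed statistics at least t, capped at one and monotonized so
that q never decreases as |d| decreases. With n patient pairs there are
only 2^n distinct sign patterns, so at the study's scale (n = 6, 64
patterns) the permutation distribution is enumerated exhaustively.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .core_io import (
    LOG2_CENTERED,
    NORMAL,
    RAW,
    TUMOR,
    DiffExpResult,
    ExpressionBundle,
)

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NONE = "none"


@dataclass
class SamConfig:
    """Parameters of the SAM-style paired test."""

    s0_percentile: float = 5.0
    n_permutations: int = 1000
    fdr_threshold: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.s0_percentile <= 100:
            raise ValueError(f"s0_percentile must be in [0, 100], got {self.s0_percentile}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")


def detection_filter(bundle: ExpressionBundle) -> ExpressionBundle:
    """Retain exactly the features detected in at least one sample."""
    keep = bundle.detection.any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("detection_filter: dropped %d of %d features", n_dropped, len(keep))
    if not keep.any():
        logger.warning("detection_filter: no feature detected in any sample")
    return bundle.subset_features(bundle.values.index[keep])


def log2_median_center(bundle: ExpressionBundle) -> ExpressionBundle:
    """log2-transform and center each sample column on its median."""
    if bundle.scale != RAW:
        raise ValueError(f"expected raw-scale bundle, got scale={bundle.scale!r}")
    bad = bundle.values <= 0
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            "non-positive intensity for feature "
            f"{bundle.values.index[i]!r} in sample {bundle.values.columns[j]!r}"
        )
    logged = np.log2(bundle.values)
    centered = logged - logged.median(axis=0)
    return replace(bundle, values=centered, scale=LOG2_CENTERED)


def paired_deltas(bundle: ExpressionBundle) -> pd.DataFrame:
    """Per-patient tumor minus normal differences (features x patients)."""
    if bundle.scale != LOG2_CENTERED:
        raise ValueError("paired_deltas expects a log2-centered bundle")
    cols = {}
    for patient in bundle.patients:
        t = bundle.sample_of(patient, TUMOR)
        n = bundle.sample_of(patient, NORMAL)
        cols[patient] = bundle.values[t] - bundle.values[n]
    return pd.DataFrame(cols, index=bundle.values.index)


def consistent_direction(bundle: ExpressionBundle) -> list[DiffExpResult]:
    """Direction calls requiring the same sign of change in every pair.

    A feature is ``up`` iff tumor-normal > 0 for every patient, ``down``
    iff < 0 for every patient, otherwise ``none``. An exact-zero difference
    in any pair breaks consistency (direction ``none``).
    """
    deltas = paired_deltas(bundle)
    arr = deltas.to_numpy()
    all_pos = (arr > 0).all(axis=1)
    all_neg = (arr < 0).all(axis=1)
    mean_delta = arr.mean(axis=1)
    results = []
    for fid, pos, neg, md in zip(deltas.index, all_pos, all_neg, mean_delta):
        direction = UP if pos else DOWN if neg else NONE
        results.append(DiffExpResult(feature_id=fid, direction=direction, mean_delta=float(md)))
    return results


def sam_paired_d(deltas: np.ndarray, s0: float) -> float:
    """SAM paired statistic d = mean(deltas) / (se(deltas) + s0)."""
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size < 2:
        raise ValueError(f"need at least 2 paired differences, got {deltas.size}")
    se = deltas.std(ddof=1) / np.sqrt(deltas.size)
    if se + s0 == 0:
        raise ValueError("degenerate scatter: se + s0 = 0")
    return float(deltas.mean() / (se + s0))


def _d_stats(delta_matrix: np.ndarray, s0: float) -> np.ndarray:
    """Vectorized d over rows, tolerant of zero scatter.

    A constant nonzero delta vector with s0 = 0 has an infinite statistic
    (it ranks above every finite one, as it should in a noise-free limit);
    a constant-zero vector maps to d = 0.
    """
    mean = delta_matrix.mean(axis=1)
    se = delta_matrix.std(axis=1, ddof=1) / np.sqrt(delta_matrix.shape[1])
    denom = se + s0
    degenerate = denom == 0
    d = np.zeros_like(mean)
    np.divide(mean, denom, out=d, where=~degenerate)
    d[degenerate & (mean > 0)] = np.inf
    d[degenerate & (mean < 0)] = -np.inf
    return d


def _sign_patterns(n_pairs: int, config: SamConfig) -> np.ndarray:
    """Sign-flip patterns (n_perm x n_pairs of +-1); exhaustive when cheap."""
    n_distinct = 2 ** n_pairs
    if n_distinct <= config.n_permutations:
        logger.info(
            "permutation_fdr: %d requested permutations >= %d distinct sign "
            "patterns; using exhaustive enumeration",
            config.n_permutations,
            n_distinct,
        )
        return np.array(list(itertools.product((1.0, -1.0), repeat=n_pairs)))
    rng = np.random.default_rng(config.rng_seed)
    return rng.choice([1.0, -1.0], size=(config.n_permutations, n_pairs))


def sam_s0(delta_matrix: np.ndarray, s0_percentile: float) -> float:
    """Fudge factor: a percentile of the feature-wise standard errors."""
    se = delta_matrix.std(axis=1, ddof=1) / np.sqrt(delta_matrix.shape[1])
    return float(np.percentile(se, s0_percentile))


def permutation_q_values(delta_matrix: np.ndarray, config: SamConfig) -> tuple[np.ndarray, np.ndarray]:
    """Observed d-statistics and permutation q-values for a delta matrix.

    Returns ``(d_obs, q)``. For each feature with threshold t = |d_obs|,
    q = median over permutations b of #{j : |d_b,j| >= t} divided by
    #{i : |d_obs,i| >= t}, capped at 1 and monotonized (non-increasing in t).
    """
    delta_matrix = np.asarray(delta_matrix, dtype=float)
    s0 = sam_s0(delta_matrix, config.s0_percentile)
    d_obs = _d_stats(delta_matrix, s0)
    patterns = _sign_patterns(delta_matrix.shape[1], config)
    abs_obs = np.abs(d_obs)
    sorted_obs = np.sort(abs_obs)
    n_feat = delta_matrix.shape[0]
    # observed counts >= t via position in the sorted observed statistics
    denom = n_feat - np.searchsorted(sorted_obs, abs_obs, side="left")
    null_counts = np.empty((patterns.shape[0], n_feat))
    for b, signs in enumerate(patterns):
        d_null = np.abs(_d_stats(delta_matrix * signs, s0))
        d_null.sort()
        null_counts[b] = n_feat - np.searchsorted(d_null, abs_obs, side="left")
    med = np.median(null_counts, axis=0)
    q = np.minimum(med / denom, 1.0)
    # monotonize: q_i = min FDR over thresholds at or below |d_i|, so q is
    # non-increasing in |d| and never raised above its plug-in estimate
    order = np.argsort(abs_obs, kind="stable")
    q_sorted = np.minimum.accumulate(q[order])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return d_obs, q


def permutation_fdr(bundle: ExpressionBundle, config: SamConfig) -> list[DiffExpResult]:
    """Consistent-direction calls annotated with d-statistics and q-values."""
    results = consistent_direction(bundle)
    deltas = paired_deltas(bundle).to_numpy()
    d_obs, q = permutation_q_values(deltas, config)
    for res, d, qv in zip(results, d_obs, q):
        res.d_stat = float(d)
        res.q_value = float(qv)
    return results


def percent_of(k: int | float, n: int | float) -> float:
    """100*k/n rounded half-up to two decimals, as printed in report tables."""
    if n == 0:
        raise ValueError("percent_of: denominator must be nonzero")
    pct = Decimal(k) * Decimal(100) / Decimal(n)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def percent_str(k: int | float, n: int | float) -> str:
    return f"{percent_of(k, n):.2f}%"
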