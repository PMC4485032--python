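"""Profile noise statistics: the mean-scaled first-order variance.

The estimator quantifies bin-to-bin scatter of a (mean-scaled) count
profile as

    v = sum_i (y_i - y_{i-1})**2 / (2 * n_diffs),    y_i = count_i / mean

summing over pairs of adjacent usable bins on the same chromosome.  For
iid noise E[(y_i - y_{i-1})**2] = 2 Var(y), hence the factor 2 in the
denominator; pure Poisson counting at average depth N then gives
v = 1/N, the counting-statistics floor.  Unlike the global sample
variance, v is nearly insensitive to genuine copy-number steps (a
single step contributes one squared difference, O(1/n)), which makes it
a depth-independent measure of the noise added by sample handling and
amplification: ``excess = v - 1/N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .preprocess import BinTrack, NormalizedProfile

__all__ = ["NoiseReport", "NoiseComparison", "first_order_variance", "compare_noise"]


@dataclass(frozen=True)
class NoiseReport:
    """First-order variance and its decomposition against 1/N."""

    v: float
    N: float
    counting_var: float
    excess: float
    n_bins: int
    n_diffs: int
    excess_below_floor: bool  # excess < 0: only sampling noise can cause it

    def to_dict(self) -> dict:
        return {
            "v": self.v,
            "N": self.N,
            "counting_var": self.counting_var,
            "excess": self.excess,
            "n_bins": self.n_bins,
            "n_diffs": self.n_diffs,
            "excess_below_floor": self.excess_below_floor,
        }


def first_order_variance(
    counts: BinTrack | NormalizedProfile | np.ndarray,
    chrom_ids: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    depth: float | None = None,
) -> NoiseReport:
    """Mean-scaled first-order variance of a bin-count profile.

    Accepts a :class:`BinTrack` (chromosome structure and mask taken
    from it), a :class:`NormalizedProfile` (whose pre-normalization
    depth supplies the 1/N floor), or a plain vector, optionally with
    per-bin chromosome ids and a usability mask.  Differences are formed
    only between adjacent bins on the same chromosome with no masked bin
    in between; the denominator counts the differences actually formed.

    ``depth`` overrides the N of the counting floor; by default N is the
    mean of the usable values, which is correct for raw or corrected
    counts but not for already-normalized ratios.

    Scale-invariant: multiplying the counts by any c > 0 leaves v
    unchanged.
    """
    if isinstance(counts, NormalizedProfile):
        if depth is None:
            depth = counts.N
        counts = counts.track
    if isinstance(counts, BinTrack):
        chrom_ids = counts.grid.chrom_ids
        mask = counts.mask
        values = counts.values
    else:
        values = np.asarray(counts, dtype=float)
    n = values.size
    mask = np.ones(n, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    chrom_ids = np.zeros(n, dtype=int) if chrom_ids is None else np.asarray(chrom_ids)

    usable = values[mask]
    if usable.size < 2:
        raise ValueError("need at least 2 usable bins")
    mean = float(usable.mean())
    if mean <= 0:
        raise ValueError("mean of usable bins must be positive")
    y = values / mean

    adjacent = mask[1:] & mask[:-1] & (chrom_ids[1:] == chrom_ids[:-1])
    n_diffs = int(adjacent.sum())
    if n_diffs < 1:
        raise ValueError("no adjacent usable bin pairs on any chromosome")
    d = (y[1:] - y[:-1])[adjacent]
    v = float((d * d).sum() / (2.0 * n_diffs))
    N = mean if depth is None else float(depth)
    counting = 1.0 / N
    excess = v - counting
    return NoiseReport(
        v=v,
        N=N,
        counting_var=counting,
        excess=excess,
        n_bins=int(usable.size),
        n_diffs=n_diffs,
        excess_below_floor=excess < 0,
    )


@dataclass(frozen=True)
class NoiseComparison:
    """Two-group comparison of replicate first-order variances."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    difference: float
    p_value: float
    test: str


def compare_noise(v_a: Sequence[float], v_b: Sequence[float]) -> NoiseComparison:
    """Welch two-sample test on replicate variance estimates.

    Falls back to an exact rank test when both groups are constant
    (Welch's statistic is undefined there).
    """
    a = np.asarray(list(v_a), dtype=float)
    b = np.asarray(list(v_b), dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 replicates per group")
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        test = "degenerate (both groups constant)"
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        p, test = float(res.pvalue), "Welch t"
        if np.isnan(p):  # pragma: no cover - defensive
            p = float(stats.mannwhitneyu(a, b, method="exact").pvalue)
            test = "Mann-Whitney (fallback)"
    return NoiseComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        difference=float(a.mean() - b.mean()),
        p_value=p,
        test=test,
    )
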