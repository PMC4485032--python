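"""Circular binary segmentation (CBS) of per-bin copy-number ratios.

CBS recursively tests each interval for a change in mean: the statistic
is the maximal two-sample t statistic over all arcs ``[i, j)`` of the
interval,

    T = max_{i<j} |mean(x[i:j]) - mean(rest)| / (s_p * sqrt(1/n1 + 1/n2))

with ``s_p`` the pooled standard deviation, and significance is assessed
by permuting the interval's values.  If the permutation p-value is at or
below ``alpha`` the interval is split at the best arc's boundaries (into
three pieces when the arc is interior, two when it abuts an end) and the
pieces are segmented recursively; otherwise the interval is emitted as
one segment.  Segmentation never crosses a chromosome boundary.

Arc widths are constrained so that every resulting piece has at least
``min_width`` bins; ties in the statistic break toward the smallest
``(i, j)`` so results are deterministic given the seed.

Masked bins are removed before segmentation; reported segments span the
genomic bins between their first and last unmasked bin while ``n_bins``
counts unmasked bins only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from .grid import BinGrid

__all__ = ["CBSParams", "Segment", "max_arc_t", "segment_values", "segment_genome"]

_EPS = 1e-12


@dataclass(frozen=True)
class CBSParams:
    """Tuning knobs of the segmentation stage.

    alpha
        Permutation significance level for accepting a split (0.01).
    min_width
        Minimum bins per segment (2); 1-bin outliers cannot become
        segments of their own.
    n_permutations
        Permutations per significance test (1000).
    seed
        Seed of the permutation RNG.
    """

    alpha: float = 0.01
    min_width: int = 2
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


@dataclass(frozen=True)
class Segment:
    """A run of bins with a common mean ratio.

    ``start_bin``/``end_bin`` are half-open indices into the grid;
    ``n_bins`` counts the unmasked bins the mean was computed over
    (smaller than ``end_bin - start_bin`` when masked gaps fall inside).
    """

    chrom: str
    start_bin: int
    end_bin: int
    mean_ratio: float
    n_bins: int


def _valid_arc_mask(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    """All (i, j) arc boundaries whose split pieces respect min_width."""
    i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    w = j - i
    ok = (w >= min_width) & (w <= n - min_width)
    ok &= (i == 0) | (i >= min_width)
    ok &= (j == n) | (j <= n - min_width)
    return i[ok], j[ok]


def max_arc_t(x: np.ndarray, min_width: int = 2) -> tuple[float, int, int]:
    """Best arc split of one interval.

    Returns ``(T, i, j)`` maximizing the pooled two-sample t statistic of
    arc ``x[i:j]`` against the rest of ``x``, subject to every resulting
    piece having at least ``min_width`` points.  Ties break toward the
    smallest ``(i, j)``.  Returns ``(0.0, 0, n)`` when no valid arc
    exists (interval too short to split).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * min_width or n < 3:
        return 0.0, 0, n
    S = np.concatenate(([0.0], np.cumsum(x)))
    Q = np.concatenate(([0.0], np.cumsum(x * x)))
    i, j = _valid_arc_mask(n, min_width)
    n1 = (j - i).astype(float)
    n2 = n - n1
    sum1 = S[j] - S[i]
    sum2 = S[n] - sum1
    ss = (Q[n]) - sum1**2 / n1 - sum2**2 / n2
    sp2 = np.maximum(ss, 0.0) / (n - 2)
    t = np.abs(sum1 / n1 - sum2 / n2) / np.sqrt(np.maximum(sp2 * (1.0 / n1 + 1.0 / n2), _EPS))
    # leftmost (i, j) among numerically tied maxima (prefix and suffix arcs
    # are exact complements and tie up to rounding)
    m = float(t.max())
    k = int(np.flatnonzero(t >= m - 1e-9 * max(m, 1.0))[0])
    return float(t[k]), int(i[k]), int(j[k])


def _perm_max_t(x: np.ndarray, min_width: int, t_obs: float, alpha: float,
                n_perm: int, rng: np.random.Generator) -> bool:
    """Permutation test: is the observed max arc t significant?

    Processes permutations in chunks and stops early once enough
    exceedances have accrued that ``p > alpha`` is certain; the decision
    is identical to running all ``n_perm`` permutations.
    """
    n = x.size
    stop = math.floor(alpha * (n_perm + 1))  # p > alpha once exceedances exceed this
    exceed = 0
    done = 0
    thr = t_obs - 1e-9
    widths = np.arange(min_width, n - min_width + 1)
    while done < n_perm:
        b = min(128, n_perm - done)
        perms = rng.permuted(np.broadcast_to(x, (b, n)).copy(), axis=1)
        S = np.concatenate((np.zeros((b, 1)), np.cumsum(perms, axis=1)), axis=1)
        Q = np.concatenate((np.zeros((b, 1)), np.cumsum(perms * perms, axis=1)), axis=1)
        tot, qtot = S[:, -1:], Q[:, -1:]
        best = np.zeros(b)
        for w in widths:
            n1, n2 = float(w), float(n - w)
            sum1 = S[:, w:] - S[:, :-w]
            ss = qtot - sum1**2 / n1 - (tot - sum1) ** 2 / n2
            t2 = (sum1 / n1 - (tot - sum1) / n2) ** 2 / (
                np.maximum(ss, 0.0) / (n - 2) * (1.0 / n1 + 1.0 / n2) + _EPS
            )
            # zero out arc starts that would leave a sub-min_width edge piece
            if min_width > 1:
                t2[:, 1:min_width] = 0.0
                lo = max(n - w - min_width + 1, 0)
                t2[:, lo : n - w] = 0.0
            best = np.maximum(best, t2.max(axis=1))
        exceed += int((np.sqrt(best) >= thr).sum())
        done += b
        if exceed > stop:
            return False
    return (1 + exceed) / (1 + n_perm) <= alpha


def segment_values(x: np.ndarray, params: CBSParams, rng: np.random.Generator | None = None) -> list[tuple[int, int]]:
    """Segment one chromosome's (unmasked) ratio vector.

    Returns half-open index intervals tiling ``[0, len(x))`` in order.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return []
    if rng is None:
        rng = np.random.default_rng(params.seed)
    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = hi - lo
        if n < 2 * params.min_width or n < 3 or np.ptp(seg) == 0.0:
            out.append((lo, hi))
            return
        t_obs, i, j = max_arc_t(seg, params.min_width)
        if t_obs <= 0.0 or not _perm_max_t(
            seg, params.min_width, t_obs, params.alpha, params.n_permutations, rng
        ):
            out.append((lo, hi))
            return
        cuts = [c for c in (i, j) if 0 < c < n]
        pieces = list(zip([0] + cuts, cuts + [n]))
        for a, b in pieces:
            recurse(lo + a, lo + b)

    recurse(0, x.size)
    return out


def segment_genome(
    grid: BinGrid,
    ratios: np.ndarray,
    mask: np.ndarray | None = None,
    params: CBSParams | None = None,
) -> list[Segment]:
    """Apply CBS per chromosome and concatenate in grid order.

    ``mask`` marks usable bins (True); masked bins are dropped before
    segmentation and never contribute to segment means.  Segments never
    cross chromosome boundaries.
    """
    if params is None:
        params = CBSParams()
    ratios = np.asarray(ratios, dtype=float)
    if ratios.shape != (grid.n_bins,):
        raise ValueError("ratios are not aligned to the grid")
    mask = np.ones(grid.n_bins, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    rng = np.random.default_rng(params.seed)
    segments: list[Segment] = []
    for chrom, sl in grid.chrom_slices().items():
        keep = np.flatnonzero(mask[sl])
        if keep.size == 0:
            continue
        vals = ratios[sl][keep]
        for a, b in segment_values(vals, params, rng):
            idx = keep[a:b]  # unmasked-bin indices within the chromosome
            segments.append(
                Segment(
                    chrom=chrom,
                    start_bin=sl.start + int(idx[0]),
                    end_bin=sl.start + int(idx[-1]) + 1,
                    mean_ratio=float(vals[a:b].mean()),
                    n_bins=int(b - a),
                )
            )
    return segments
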