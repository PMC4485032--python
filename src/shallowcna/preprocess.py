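"""From aligned read positions to normalized per-bin copy-number ratios.

The preprocessing chain is: count reads into fixed 1 Mb bins, divide by
per-bin mappability (masking repetitive bins), remove GC-content bias
with a LOESS fit that is neutral with respect to the total read count,
and finally median-normalize so the diploid level sits at ratio 1.0.

Masking is hereditary: a bin masked at any stage stays masked in every
downstream output and is excluded from every statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .grid import BinGrid

__all__ = [
    "BinTrack",
    "NormalizedProfile",
    "bin_reads",
    "correct_mappability",
    "gc_correct",
    "median_normalize",
    "preprocess_counts",
]

log = logging.getLogger(__name__)

GC_INTERVAL = 0.001  # GC grouping resolution: intervals of 0.1%


@dataclass(frozen=True)
class BinTrack:
    """A per-bin numeric vector aligned to a :class:`BinGrid`.

    ``mask`` is True for usable bins; masked bins are carried along but
    excluded from every downstream statistic.
    """

    grid: BinGrid
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = (
            np.ones(self.grid.n_bins, dtype=bool)
            if self.mask is None
            else np.asarray(self.mask, dtype=bool)
        )
        if values.shape != (self.grid.n_bins,):
            raise ValueError(
                f"track has {values.shape} values for a grid of {self.grid.n_bins} bins"
            )
        if mask.shape != values.shape:
            raise ValueError("mask shape differs from values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)

    @classmethod
    def from_values(cls, grid: BinGrid, values, mask=None) -> "BinTrack":
        return cls(grid=grid, values=np.asarray(values, dtype=float), mask=mask)

    @property
    def usable(self) -> np.ndarray:
        """Values at unmasked bins."""
        return self.values[self.mask]

    def to_frame(self, name: str = "value") -> pd.DataFrame:
        df = self.grid.to_frame()
        df[name] = self.values
        df["mask"] = self.mask
        return df


@dataclass(frozen=True)
class NormalizedProfile:
    """Median-normalized ratios plus the pre-normalization depth N.

    ``N`` is the average reads per usable bin before normalization; it is
    the N of the 1/N counting-noise floor and the mean of the diploid
    component in the calling model.
    """

    track: BinTrack
    N: float

    def __post_init__(self) -> None:
        if not self.N > 0:
            raise ValueError("N must be positive")

    @property
    def ratios(self) -> np.ndarray:
        return self.track.values

    @property
    def mask(self) -> np.ndarray:
        return self.track.mask

    @property
    def grid(self) -> BinGrid:
        return self.track.grid


def bin_reads(grid: BinGrid, reads: pd.DataFrame | Iterable[tuple[str, int]]) -> tuple[BinTrack, int]:
    """Count reads into bins by read start coordinate.

    ``reads`` is a BED-like frame with ``chrom`` and ``start`` columns
    (0-based), or an iterable of ``(chrom, start)``.  A read lands in the
    bin whose half-open interval contains its start.  Returns the count
    track and the number of reads skipped because they fall on unknown
    chromosomes or beyond the last full bin.
    """
    if not isinstance(reads, pd.DataFrame):
        reads = pd.DataFrame(list(reads), columns=["chrom", "start"])
    if reads.empty:
        return BinTrack.from_values(grid, np.zeros(grid.n_bins)), 0
    missing = {"chrom", "start"} - set(reads.columns)
    if missing:
        raise ValueError(f"reads table lacks columns: {sorted(missing)}")

    name_to_id = {name: k for k, (name, _) in enumerate(grid.chromosomes)}
    nbins_per_chrom = np.asarray(
        [length // grid.bin_size for _, length in grid.chromosomes], dtype=np.int64
    )
    offsets = np.concatenate(([0], np.cumsum(nbins_per_chrom)))[:-1]

    chrom_id = reads["chrom"].map(name_to_id)
    known = chrom_id.notna().to_numpy()
    cid = chrom_id.to_numpy(dtype=float)
    start = pd.to_numeric(reads["start"], errors="raise").to_numpy(dtype=np.int64)
    local = start // grid.bin_size
    inside = known & (start >= 0)
    cid_i = np.where(inside, cid, 0).astype(np.int64)
    inside &= local < nbins_per_chrom[cid_i]
    skipped = int((~inside).sum())
    idx = offsets[cid_i[inside]] + local[inside]
    counts = np.bincount(idx, minlength=grid.n_bins).astype(float)
    if skipped:
        log.warning("bin_reads: skipped %d reads outside the grid", skipped)
    return BinTrack.from_values(grid, counts), skipped


def correct_mappability(
    counts: BinTrack, map_track: np.ndarray, min_mappability: float = 0.75
) -> BinTrack:
    """Divide counts by per-bin mappability; mask poorly mappable bins.

    Bins with mappability below ``min_mappability`` are masked rather
    than corrected (the division would amplify noise without bound).
    Totals are not rescaled at this stage.
    """
    m = np.asarray(map_track, dtype=float)
    if m.shape != (counts.grid.n_bins,):
        raise ValueError("mappability track is not aligned to the grid")
    if (m < 0).any() or (m > 1).any():
        raise ValueError("mappability values must lie in [0, 1]")
    ok = counts.mask & (m >= min_mappability)
    values = np.where(ok, counts.values / np.where(m > 0, m, 1.0), counts.values)
    n_masked = int(counts.mask.sum() - ok.sum())
    if n_masked:
        log.info("correct_mappability: masked %d bins below %.2f", n_masked, min_mappability)
    return BinTrack(grid=counts.grid, values=values, mask=ok)


def gc_correct(
    counts: BinTrack,
    gc_track: np.ndarray,
    span: float = 0.3,
    min_bins: int = 100,
) -> BinTrack:
    """Remove GC-content bias additively, preserving the total count.

    Usable bins are grouped into GC intervals of width 0.1%; the mean
    depth per interval is LOESS-smoothed against the interval midpoint
    (each interval weighted by its bin count); every bin is then shifted
    by ``median depth - loess(GC_i)``, and all corrected values are
    rescaled by one global factor so the total over usable bins equals
    the input total exactly.

    The correction is skipped (with a warning, returning the input) when
    fewer than ``min_bins`` usable bins or fewer than 3 populated GC
    intervals are available.
    """
    gc = np.asarray(gc_track, dtype=float)
    if gc.shape != (counts.grid.n_bins,):
        raise ValueError("GC track is not aligned to the grid")
    if (gc < 0).any() or (gc > 1).any():
        raise ValueError("GC fractions must lie in [0, 1]")
    use = counts.mask
    if int(use.sum()) < min_bins:
        log.warning("gc_correct: only %d usable bins (<%d); correction skipped", use.sum(), min_bins)
        return counts

    values = counts.values[use]
    interval = np.floor(gc[use] / GC_INTERVAL).astype(int)
    uniq, inverse, per_count = np.unique(interval, return_inverse=True, return_counts=True)
    if uniq.size < 3:
        log.warning("gc_correct: only %d populated GC intervals (<3); correction skipped", uniq.size)
        return counts
    mean_depth = np.bincount(inverse, weights=values) / per_count
    midpoints = (uniq + 0.5) * GC_INTERVAL

    # weight intervals by bin count by repeating each (midpoint, mean) point
    x = np.repeat(midpoints, per_count)
    y = np.repeat(mean_depth, per_count)
    fitted_at_mid = lowess(y, x, frac=span, xvals=midpoints)
    fitted = np.interp(gc[use], midpoints, fitted_at_mid)

    median_depth = float(np.median(values))
    corrected = values + (median_depth - fitted)
    total_in = values.sum()
    total_out = corrected.sum()
    if total_out <= 0:
        raise ValueError("gc_correct produced a non-positive total; input too sparse")
    corrected *= total_in / total_out

    out = counts.values.copy()
    out[use] = corrected
    return BinTrack(grid=counts.grid, values=out, mask=counts.mask)


def median_normalize(counts: BinTrack) -> NormalizedProfile:
    """Scale usable bins so their median is exactly 1.

    Records ``N``, the mean pre-normalization value over usable bins,
    for the 1/N counting floor and the calling model.
    """
    usable = counts.usable
    if usable.size == 0:
        raise ValueError("no usable bins to normalize")
    med = float(np.median(usable))
    if med <= 0:
        raise ValueError("degenerate profile: median of usable bins is not positive")
    ratios = counts.values / med
    return NormalizedProfile(
        track=BinTrack(grid=counts.grid, values=ratios, mask=counts.mask),
        N=float(usable.mean()),
    )


def preprocess_counts(
    grid: BinGrid,
    counts: np.ndarray | BinTrack,
    gc_track: np.ndarray | None = None,
    map_track: np.ndarray | None = None,
    min_mappability: float = 0.75,
    loess_span: float = 0.3,
) -> NormalizedProfile:
    """Full preprocessing chain: mappability -> GC -> median normalize.

    GC and mappability stages are applied only when their track is
    provided, so the function also covers count tables that are already
    corrected upstream.
    """
    track = counts if isinstance(counts, BinTrack) else BinTrack.from_values(grid, counts)
    if map_track is not None:
        track = correct_mappability(track, map_track, min_mappability)
    if gc_track is not None:
        track = gc_correct(track, gc_track, span=loess_span)
    return median_normalize(track)
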