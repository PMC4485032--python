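"""Synthetic shallow-sequencing data with whole-genome-amplification bias.

Real libraries amplified from 1-5 cells carry strong locus-specific
multiplicative bias on top of Poisson counting noise.  This module
emulates that regime at the level of per-bin read counts:

    count_i ~ Poisson( N * (cn_i / 2) * b_i * g_i )

where ``N`` is the expected reads per diploid bin (~4000 at 0.1X coverage
and 1 Mb bins), ``cn_i`` the truth copy number of bin i (area-weighted
where an aberration covers a bin partially), ``b_i`` a mean-one
log-normal amplification-bias factor with optional AR(1) correlation
along the chromosome, and ``g_i`` a mean-one GC-dependent tilt.

The log-normal standard deviation ``sigma_log`` is the single knob that
sets the mean-scaled profile variance; :func:`sigma_for_target_variance`
inverts the relation ``v = exp(sigma_log**2) - 1 + 1/N`` so presets can
be calibrated to a measured profile variance.  Named presets mirror the
noise levels of MALBAC- and SurePlex-amplified libraries.

A truth profile matching the LOUCY T-ALL cell line (female; X monosomy
plus five deletions and one duplication of 2.5-72 Mb) is packaged as the
standard fixture for sensitivity/precision studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import BinGrid

__all__ = [
    "TruthCNA",
    "BiasModel",
    "PRESETS",
    "loucy_truth",
    "truth_copy_number",
    "simulate_counts",
    "simulate_reads",
    "simulate_gc_track",
    "simulate_mappability_track",
    "sigma_for_target_variance",
    "get_preset",
]


@dataclass(frozen=True)
class TruthCNA:
    """One true copy-number aberration (diploid background is implicit)."""

    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if self.copy_number == 2:
            raise ValueError("truth profiles list aberrations only (copy_number != 2)")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BiasModel:
    """Parameters of the per-bin count model.

    mean_depth
        Expected reads per diploid bin (N).
    sigma_log
        Std of the log-normal multiplicative bias; the location is fixed
        at ``-sigma_log**2 / 2`` so the bias factor has mean exactly 1.
    rho
        AR(1) correlation of log-bias between adjacent bins, in [0, 1).
        The marginal std stays ``sigma_log`` regardless of rho.
    gc_slope
        Linear coefficient of log-bias on (GC - mean GC); the resulting
        tilt is renormalized to mean 1 across bins.
    seed
        Seed for the bias and Poisson draws.
    """

    mean_depth: float = 4000.0
    sigma_log: float = 0.0
    rho: float = 0.0
    gc_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")


def sigma_for_target_variance(v: float, mean_depth: float) -> float:
    """Log-normal sigma reproducing a target mean-scaled profile variance.

    For iid mean-one log-normal bias on top of Poisson sampling at depth
    N, the mean-scaled variance of a flat profile is
    ``exp(sigma**2) - 1 + 1/N``; this solves for sigma.  Raises if the
    target is at or below the 1/N counting floor.
    """
    excess = v - 1.0 / mean_depth
    if excess <= 0:
        raise ValueError(
            f"target variance {v} is not above the counting floor 1/N = {1.0 / mean_depth:.2g}"
        )
    return math.sqrt(math.log1p(excess))


# Mean-scaled profile variances by amplification chemistry and input cells
# (1/3/5 cells; "nopcr" = PCR-free library prep), used to calibrate
# sigma_log at the default depth of 4000 reads per bin.  MALBAC presets
# add AR(1) correlation of the bias (rho 0.3) to emulate its segmental,
# false-positive-prone character; the correlation scale is a free choice.
_PRESET_TABLE: dict[str, tuple[float | None, float]] = {
    # name: (target mean-scaled variance or None for no bias, rho)
    "flat": (None, 0.0),
    "sureplex-1cell": (0.083, 0.0),
    "sureplex-3cell": (0.077, 0.0),
    "sureplex-5cell": (0.073, 0.0),
    "sureplex-nopcr": (0.064, 0.0),
    "malbac-1cell": (0.165, 0.3),
    "malbac-3cell": (0.138, 0.3),
    "malbac-5cell": (0.146, 0.3),
    "malbac-nopcr": (0.120, 0.3),
}


def get_preset(name: str, mean_depth: float = 4000.0, seed: int = 0) -> BiasModel:
    """Named :class:`BiasModel` calibrated to a preset noise level."""
    try:
        target_v, rho = _PRESET_TABLE[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(_PRESET_TABLE))}"
        ) from None
    sigma = 0.0 if target_v is None else sigma_for_target_variance(target_v, mean_depth)
    return BiasModel(mean_depth=mean_depth, sigma_log=sigma, rho=rho, seed=seed)


PRESETS = tuple(_PRESET_TABLE)


# LOUCY reference aberrations.  Sizes are the contract (X monosomy;
# 72/45/13/3/2.5 Mb deletions; 3 Mb duplication); positions approximate
# the cytobands on hg19 and are aligned to the Mb grid except for the
# 2.5 Mb chromosome 9 deletion, which deliberately straddles three 1 Mb
# bins (overlap fractions 0.75/1.0/0.75) the way a real sub-resolution
# event would.
_LOUCY_ABERRATIONS: tuple[tuple[str, int, int, int], ...] = (
    ("chr5", 108_000_000, 180_000_000, 1),   # distal 72 Mb del, 5q21.3-q35.3
    ("chr6", 126_000_000, 171_000_000, 1),   # distal 45 Mb del, 6q22.31-q27
    ("chr9", 130_250_000, 132_750_000, 1),   # 2.5 Mb del, 9q34.11-q34.12
    ("chr13", 103_000_000, 106_000_000, 3),  # 3 Mb dup, 13q33-q33.3
    ("chr16", 0, 13_000_000, 1),             # 13 Mb del, 16p13.3-p13.12
    ("chr16", 87_000_000, 90_000_000, 1),    # 3 Mb del, 16q24.2-q24.3
)


def loucy_truth(grid: BinGrid) -> list[TruthCNA]:
    """Seven-aberration truth profile of the LOUCY cell line.

    Returns the X monosomy plus the six focal events, as
    :class:`TruthCNA` records on ``grid``'s chromosomes.  The grid must
    cover chromosomes 5, 6, 9, 13, 16 and X.
    """
    lengths = grid.chrom_lengths
    required = {"chr5", "chr6", "chr9", "chr13", "chr16", "chrX"}
    missing = required - set(lengths)
    if missing:
        raise ValueError(f"grid lacks chromosomes required by the LOUCY fixture: {sorted(missing)}")
    events = [TruthCNA("chrX", 0, lengths["chrX"], 1)]
    for chrom, start, end, cn in _LOUCY_ABERRATIONS:
        events.append(TruthCNA(chrom, start, min(end, lengths[chrom]), cn))
    return events


def truth_copy_number(grid: BinGrid, truth: Sequence[TruthCNA]) -> np.ndarray:
    """Per-bin effective copy number, area-weighted for partial overlap.

    A bin covered by an aberration over a fraction f of its width gets
    ``2 + f * (cn - 2)``; uncovered bins are 2.0.
    """
    cn = np.full(grid.n_bins, 2.0)
    name_to_id = {name: k for k, (name, _) in enumerate(grid.chromosomes)}
    intervals = sorted(truth, key=lambda t: (t.chrom, t.start))
    for a, b in zip(intervals, intervals[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"overlapping truth intervals on {a.chrom}")
    for t in truth:
        if t.chrom not in name_to_id:
            raise ValueError(f"truth chromosome {t.chrom!r} not on grid")
        on_chrom = grid.chrom_ids == name_to_id[t.chrom]
        overlap = np.minimum(grid.ends, t.end) - np.maximum(grid.starts, t.start)
        frac = np.clip(overlap, 0, None) / grid.bin_size
        cn += np.where(on_chrom, frac * (t.copy_number - 2), 0.0)
    return cn


def _ar1_lognormal_bias(grid: BinGrid, sigma: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Mean-one log-normal bias, AR(1) along bins, restarted per chromosome."""
    if sigma == 0.0:
        return np.ones(grid.n_bins)
    z = rng.standard_normal(grid.n_bins)
    log_b = np.empty(grid.n_bins)
    innov = math.sqrt(1.0 - rho * rho)
    for sl in grid.chrom_slices().values():
        zc = z[sl]
        lc = np.empty(zc.size)
        lc[0] = zc[0]
        for i in range(1, zc.size):  # stationary AR(1), marginal sd == 1
            lc[i] = rho * lc[i - 1] + innov * zc[i]
        log_b[sl] = lc
    return np.exp(sigma * log_b - 0.5 * sigma * sigma)


def simulate_counts(
    grid: BinGrid,
    truth: Sequence[TruthCNA],
    bias_model: BiasModel,
    gc_track: np.ndarray | None = None,
) -> np.ndarray:
    """Draw per-bin read counts under the WGA-bias model.

    Counts are ``Poisson(N * cn_i/2 * b_i * g_i)``; see the module
    docstring.  ``gc_track`` (per-bin GC fraction aligned to ``grid``) is
    required only when ``gc_slope`` is non-zero.  Reproducible given
    ``bias_model.seed``.
    """
    rng = np.random.default_rng(bias_model.seed)
    cn = truth_copy_number(grid, truth)
    b = _ar1_lognormal_bias(grid, bias_model.sigma_log, bias_model.rho, rng)
    g = np.ones(grid.n_bins)
    if bias_model.gc_slope != 0.0:
        if gc_track is None:
            raise ValueError("gc_track required when gc_slope != 0")
        gc = np.asarray(gc_track, dtype=float)
        if gc.shape != (grid.n_bins,):
            raise ValueError("gc_track is not aligned to the grid")
        g = np.exp(bias_model.gc_slope * (gc - gc.mean()))
        g /= g.mean()
    lam = bias_model.mean_depth * (cn / 2.0) * b * g
    return rng.poisson(lam).astype(np.int64)


def simulate_reads(grid: BinGrid, counts: np.ndarray, seed: int = 0) -> pd.DataFrame:
    """Place single-end reads uniformly inside each bin.

    Emits exactly ``counts[i]`` read start positions in bin i, as a BED
    frame (chrom, start, end; 0-based half-open) with the read length
    fixed at 75 bp, truncated at the chromosome end.  Re-binning the
    output by read start recovers ``counts`` exactly.
    """
    counts = np.asarray(counts)
    if counts.shape != (grid.n_bins,):
        raise ValueError("counts are not aligned to the grid")
    if (counts < 0).any():
        raise ValueError("negative read counts")
    rng = np.random.default_rng(seed)
    total = int(counts.sum())
    bin_idx = np.repeat(np.arange(grid.n_bins), counts)
    offsets = rng.integers(0, grid.bin_size, size=total)
    starts = grid.starts[bin_idx] + offsets
    chroms = grid.bin_chroms()[bin_idx]
    lengths = np.asarray([grid.chrom_lengths[c] for c in chroms], dtype=np.int64) if total else np.empty(0, dtype=np.int64)
    ends = np.minimum(starts + 75, lengths)
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def simulate_gc_track(grid: BinGrid, seed: int = 0, mean: float = 0.42, sd: float = 0.04, smooth: float = 0.9) -> np.ndarray:
    """Smoothly varying per-bin GC fraction (AR(1) along each chromosome).

    Defaults approximate the human genome's ~42% average GC with slow
    megabase-scale variation; values are clipped to [0.2, 0.75].
    """
    rng = np.random.default_rng(seed)
    z = np.log(_ar1_lognormal_bias(grid, 1.0, smooth, rng)) + 0.5  # unit-sd AR(1)
    return np.clip(mean + sd * z, 0.2, 0.75)


def simulate_mappability_track(
    grid: BinGrid, seed: int = 0, low_fraction: float = 0.03
) -> np.ndarray:
    """Per-bin mappability: most bins near 1, a few repetitive bins low.

    ``low_fraction`` of bins (centromere/telomere-like) get mappability
    drawn uniformly from [0.1, 0.6); the rest from Beta(40, 2) (~0.95).
    """
    rng = np.random.default_rng(seed)
    m = rng.beta(40.0, 2.0, size=grid.n_bins)
    low = rng.random(grid.n_bins) < low_fraction
    m[low] = rng.uniform(0.1, 0.6, size=int(low.sum()))
    return m
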