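"""Negative-binomial threshold calling of copy-number alterations.

Three negative-binomial count distributions are modeled for monosomic,
diploid and trisomic states, with means N/2, N and 3N/2 (N = average
reads per diploid bin), common overdispersion ``variance = d * mean``
(d = 5 by default; d -> 1 is the Poisson limit) and prior weights
(0.05, 0.90, 0.05) for loss, diploid and gain.  The calling thresholds
are the points where adjacent prior-weighted mass functions cross
between their modes — the boundaries at which the three peaks are
maximally separated, i.e. the minimal-misclassification decision rule.

Segments whose mean ratio falls below the loss threshold or above the
gain threshold become CNA calls; copy number is estimated as
``2 * seg_mean`` under the assumption that the bulk of the genome is
diploid, and the log2 ratio is ``log2(seg_mean)`` (0 for diploid, -1 for
a monosomy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import nbinom

from .grid import BinGrid
from .preprocess import NormalizedProfile
from .segmentation import Segment

__all__ = ["NBThresholdModel", "CNACall", "fit_thresholds", "call_segments", "profile_table"]


@dataclass(frozen=True)
class NBThresholdModel:
    """Fitted three-component model and its two decision thresholds.

    ``t_low`` and ``t_high`` are in ratio units (count / N), with
    ``t_low < 1 < t_high``.
    """

    mu: float
    overdispersion: float
    priors: tuple[float, float, float]
    t_low: float
    t_high: float

    @property
    def component_means(self) -> tuple[float, float, float]:
        return (self.mu / 2.0, self.mu, 1.5 * self.mu)

    def classify(self, seg_mean: float) -> str:
        if seg_mean < self.t_low:
            return "loss"
        if seg_mean > self.t_high:
            return "gain"
        return "neutral"

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "overdispersion": self.overdispersion,
            "priors": list(self.priors),
            "t_low": self.t_low,
            "t_high": self.t_high,
        }


@dataclass(frozen=True)
class CNACall:
    """One called copy-number alteration."""

    chrom: str
    start: int
    end: int
    n_bins: int
    seg_mean: float
    copy_number: float
    copy_number_int: int
    log2_ratio: float
    direction: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _nb_logpmf(x: np.ndarray, mean: float, d: float) -> np.ndarray:
    # variance = d * mean  =>  p = 1/d, r = mean / (d - 1)
    return nbinom.logpmf(x, mean / (d - 1.0), 1.0 / d)


def fit_thresholds(
    N: float,
    d: float = 5.0,
    priors: Sequence[float] = (0.05, 0.90, 0.05),
) -> NBThresholdModel:
    """Locate the two crossing points of the weighted component masses.

    Scans integer counts between adjacent component means and takes the
    first count where the next component's prior-weighted mass overtakes
    the current one's; the threshold is that count divided by N.
    Raises when a pair of weighted densities never crosses between their
    modes (pathological d / priors).
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if d <= 1:
        raise ValueError("overdispersion d must be > 1 (d -> 1 is the Poisson limit)")
    priors = tuple(float(p) for p in priors)
    if len(priors) != 3 or any(p <= 0 for p in priors):
        raise ValueError("priors must be three positive weights")
    if not math.isclose(sum(priors), 1.0, abs_tol=1e-6):
        raise ValueError("priors must sum to 1")

    means = (N / 2.0, N, 1.5 * N)
    x = np.arange(0, int(math.ceil(3.0 * N)) + 1)
    logw = [math.log(p) + _nb_logpmf(x, m, d) for p, m in zip(priors, means)]

    def crossing(lo_c: int, hi_c: int, m_lo: float, m_hi: float) -> float:
        inside = (x > m_lo) & (x < m_hi)
        take_hi = logw[hi_c][inside] >= logw[lo_c][inside]
        if not take_hi.any() or take_hi.all():
            raise ValueError(
                f"weighted components {lo_c} and {hi_c} do not cross between their modes "
                f"(N={N}, d={d}, priors={priors})"
            )
        return float(x[inside][np.argmax(take_hi)])

    t_low = crossing(0, 1, means[0], means[1]) / N
    t_high = crossing(1, 2, means[1], means[2]) / N
    return NBThresholdModel(
        mu=float(N), overdispersion=float(d), priors=priors, t_low=t_low, t_high=t_high
    )


def call_segments(
    segments: Sequence[Segment], model: NBThresholdModel, grid: BinGrid
) -> list[CNACall]:
    """Flag segments beyond the model thresholds as CNA calls."""
    calls: list[CNACall] = []
    for seg in segments:
        direction = model.classify(seg.mean_ratio)
        if direction == "neutral":
            continue
        cn = 2.0 * seg.mean_ratio
        log2 = float(np.log2(seg.mean_ratio)) if seg.mean_ratio > 0 else float("-inf")
        calls.append(
            CNACall(
                chrom=seg.chrom,
                start=int(grid.starts[seg.start_bin]),
                end=int(grid.ends[seg.end_bin - 1]),
                n_bins=seg.n_bins,
                seg_mean=seg.mean_ratio,
                copy_number=cn,
                copy_number_int=int(round(cn)),
                log2_ratio=log2,
                direction=direction,
            )
        )
    return calls


def profile_table(
    profile: NormalizedProfile,
    segments: Sequence[Segment],
    model: NBThresholdModel | None = None,
) -> pd.DataFrame:
    """Per-bin, plot-ready log2 profile (masked bins absent).

    Columns: bin coordinates, the bin ratio and its log2, the spanning
    segment's mean (and log2), the two thresholds in log2 units, and an
    alternating chromosome group index for coloring.
    """
    grid = profile.grid
    df = grid.to_frame()
    with np.errstate(divide="ignore"):
        df["ratio"] = profile.ratios
        df["log2_ratio"] = np.log2(profile.ratios)
    seg_mean = np.full(grid.n_bins, np.nan)
    for seg in segments:
        seg_mean[seg.start_bin : seg.end_bin] = seg.mean_ratio
    with np.errstate(divide="ignore", invalid="ignore"):
        df["seg_mean"] = seg_mean
        df["seg_log2"] = np.log2(seg_mean)
    if model is not None:
        with np.errstate(divide="ignore"):
            df["t_low_log2"] = np.log2(model.t_low)
            df["t_high_log2"] = np.log2(model.t_high)
    df["chrom_group"] = (grid.chrom_ids % 2).astype(int)
    return df[profile.mask].reset_index(drop=True)
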