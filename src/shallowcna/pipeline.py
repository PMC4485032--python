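"""End-to-end run: counts -> normalized profile -> segments -> calls.

One convenience layer shared by the command-line interface, the
replicate study and the analysis scripts, so every entry point executes
the identical chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calling import CNACall, NBThresholdModel, call_segments, fit_thresholds
from .grid import BinGrid
from .noise import NoiseReport, first_order_variance
from .preprocess import BinTrack, NormalizedProfile, preprocess_counts
from .segmentation import CBSParams, Segment, segment_genome

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineResult:
    profile: NormalizedProfile
    segments: list[Segment]
    model: NBThresholdModel
    calls: list[CNACall]
    noise: NoiseReport


def run_pipeline(
    grid: BinGrid,
    counts: np.ndarray | BinTrack,
    gc_track: np.ndarray | None = None,
    map_track: np.ndarray | None = None,
    min_mappability: float = 0.75,
    loess_span: float = 0.3,
    cbs: CBSParams | None = None,
    overdispersion: float = 5.0,
    priors: Sequence[float] = (0.05, 0.90, 0.05),
) -> PipelineResult:
    """Preprocess, segment and call one sample's bin counts."""
    profile = preprocess_counts(
        grid,
        counts,
        gc_track=gc_track,
        map_track=map_track,
        min_mappability=min_mappability,
        loess_span=loess_span,
    )
    segments = segment_genome(grid, profile.ratios, profile.mask, cbs or CBSParams())
    model = fit_thresholds(profile.N, d=overdispersion, priors=priors)
    calls = call_segments(segments, model, grid)
    noise = first_order_variance(profile)
    return PipelineResult(profile=profile, segments=segments, model=model, calls=calls, noise=noise)
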