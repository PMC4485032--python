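"""Scoring called CNAs against a truth profile.

A truth region is a true positive when at least one call of the correct
direction (loss for copy number < 2, gain for > 2) overlaps it by at
least one base pair (optionally by a reciprocal-overlap fraction);
multiple calls hitting one region still count once.  Calls of at least
``min_size`` (3 Mb by default, the resolution the 1 Mb bin grid is
designed for) that overlap no truth region of matching direction are
false positives; smaller unmatched calls are tallied separately rather
than counted as FP.  Sensitivity is TP / (TP + FN) over truth regions,
PPV is TP / (TP + FP) over calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import CNACall
from .grid import BinGrid, hg19_grid
from .pipeline import run_pipeline
from .segmentation import CBSParams
from .simulate import (
    TruthCNA,
    get_preset,
    loucy_truth,
    simulate_counts,
    simulate_gc_track,
    simulate_mappability_track,
)

__all__ = ["EvalReport", "match_calls", "replicate_study", "summarize_study"]


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and derived metrics for one sample."""

    tp: int
    fp: int
    fn: int
    sensitivity: float | None
    ppv: float | None
    n_small_unmatched: int
    truth_table: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "n_small_unmatched": self.n_small_unmatched,
        }


def _direction(copy_number: float) -> str:
    return "loss" if copy_number < 2 else "gain"


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return min(a_end, b_end) - max(a_start, b_start)


def match_calls(
    calls: Sequence[CNACall],
    truth: Sequence[TruthCNA],
    min_size: int = 3_000_000,
    reciprocal: float = 0.0,
) -> EvalReport:
    """Score calls against truth regions.

    ``reciprocal`` optionally raises the overlap requirement from >= 1 bp
    to a fraction of both the call's and the truth region's length.
    """
    if not truth:
        raise ValueError("empty truth set: nothing to evaluate")

    def matches(call: CNACall, region: TruthCNA) -> bool:
        if call.chrom != region.chrom or call.direction != _direction(region.copy_number):
            return False
        ov = _overlap(call.start, call.end, region.start, region.end)
        if ov <= 0:
            return False
        if reciprocal > 0.0:
            return ov >= reciprocal * call.length and ov >= reciprocal * region.length
        return True

    rows = []
    hit = np.zeros(len(truth), dtype=bool)
    call_matched = np.zeros(len(calls), dtype=bool)
    for i, region in enumerate(truth):
        for j, call in enumerate(calls):
            if matches(call, region):
                hit[i] = True
                call_matched[j] = True
        rows.append(
            {
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "copy_number": region.copy_number,
                "detected": bool(hit[i]),
            }
        )

    tp = int(hit.sum())
    fn = int(len(truth) - tp)
    unmatched = [c for c, m in zip(calls, call_matched) if not m]
    fp = sum(1 for c in unmatched if c.length >= min_size)
    small = len(unmatched) - fp
    sens = tp / (tp + fn) if (tp + fn) else None
    ppv = tp / (tp + fp) if (tp + fp) else None
    return EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        sensitivity=sens,
        ppv=ppv,
        n_small_unmatched=small,
        truth_table=pd.DataFrame(rows),
    )


def replicate_study(
    presets: Sequence[str],
    n_replicates: int = 25,
    grid: BinGrid | None = None,
    truth: Sequence[TruthCNA] | None = None,
    mean_depth: float = 4000.0,
    seed: int = 0,
    cbs: CBSParams | None = None,
    use_tracks: bool = True,
) -> pd.DataFrame:
    """Simulation study: generate -> preprocess -> segment -> call -> score.

    Runs ``n_replicates`` independent samples per preset over the given
    grid (hg19 autosomes + X by default) and truth profile (the LOUCY
    fixture by default).  Replicate r of any preset uses seed
    ``seed + r`` for the counts and the segmentation permutations; GC
    and mappability tracks are genome properties, generated once from
    ``seed``.  Returns one tidy row per (preset, replicate) with
    sensitivity, PPV, confusion counts and the first-order variance.
    """
    if grid is None:
        grid = hg19_grid()
    if truth is None:
        truth = loucy_truth(grid)
    gc = simulate_gc_track(grid, seed=seed) if use_tracks else None
    mp = simulate_mappability_track(grid, seed=seed) if use_tracks else None
    base_cbs = cbs or CBSParams()

    rows = []
    for preset in presets:
        for r in range(n_replicates):
            rep_seed = seed + r
            bias = get_preset(preset, mean_depth=mean_depth, seed=rep_seed)
            counts = simulate_counts(grid, truth, bias, gc_track=gc)
            result = run_pipeline(
                grid,
                counts,
                gc_track=gc,
                map_track=mp,
                cbs=CBSParams(
                    alpha=base_cbs.alpha,
                    min_width=base_cbs.min_width,
                    n_permutations=base_cbs.n_permutations,
                    seed=rep_seed,
                ),
            )
            report = match_calls(result.calls, truth)
            rows.append(
                {
                    "preset": preset,
                    "replicate": r,
                    "sensitivity": report.sensitivity,
                    "ppv": report.ppv,
                    "tp": report.tp,
                    "fp": report.fp,
                    "fn": report.fn,
                    "v": result.noise.v,
                    "N": result.noise.N,
                }
            )
    return pd.DataFrame(rows)


def summarize_study(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of sensitivity, PPV and noise per preset."""
    g = per_replicate.groupby("preset")
    out = g.agg(
        n=("replicate", "size"),
        sensitivity_mean=("sensitivity", "mean"),
        sensitivity_sd=("sensitivity", "std"),
        ppv_mean=("ppv", "mean"),
        ppv_sd=("ppv", "std"),
        fp_mean=("fp", "mean"),
        v_mean=("v", "mean"),
        v_sd=("v", "std"),
    )
    return out.reset_index()
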