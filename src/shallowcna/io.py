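"""Readers and writers for the pipeline's plain-text formats.

Formats: BED (0-based half-open) for reads and truth profiles, the
bin-table TSV (``chrom start end count gc mappability [mask]``), SEG for
segments, BED+ for calls, and a JSON run report.  BAM input is read
through pysam (aligned start coordinates only).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import CNACall
from .grid import BinGrid, build_grid
from .segmentation import Segment
from .simulate import TruthCNA

__all__ = [
    "read_bed_reads",
    "read_bam_reads",
    "write_reads_bed",
    "write_bin_table",
    "read_bin_table",
    "write_truth_bed",
    "read_truth_bed",
    "write_seg",
    "write_calls_bed",
    "write_run_report",
]

BIN_TABLE_COLUMNS = ["chrom", "start", "end", "count", "gc", "mappability"]


def read_bed_reads(path) -> pd.DataFrame:
    """Read a BED of single-end reads (first three columns used)."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], comment="#", dtype={0: str},
        )
        df["start"] = pd.to_numeric(df["start"], errors="raise").astype(np.int64)
        df["end"] = pd.to_numeric(df["end"], errors="raise").astype(np.int64)
    except Exception as exc:
        raise ValueError(f"malformed BED file {path}: {exc}") from exc
    return df


def read_bam_reads(path) -> pd.DataFrame:
    """Aligned read start positions from a BAM/SAM file (pysam)."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            rows.append((rec.reference_name, rec.reference_start))
    return pd.DataFrame(rows, columns=["chrom", "start"])


def write_reads_bed(reads: pd.DataFrame, path) -> None:
    reads[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def write_bin_table(
    path,
    grid: BinGrid,
    counts: np.ndarray,
    gc: np.ndarray | None = None,
    mappability: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> None:
    """Write the per-bin table (`chrom start end count gc mappability [mask]`)."""
    df = grid.to_frame()
    df["count"] = np.asarray(counts)
    df["gc"] = np.ones(grid.n_bins) * np.nan if gc is None else np.asarray(gc)
    df["mappability"] = 1.0 if mappability is None else np.asarray(mappability)
    if mask is not None:
        df["mask"] = np.asarray(mask).astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_bin_table(path) -> tuple[BinGrid, pd.DataFrame]:
    """Read a bin-table TSV back into a grid and its aligned columns.

    The grid is reconstructed from the bin coordinates; bin width must
    be constant.  Raises with the offending line for malformed input.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BIN_TABLE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"bin table {path} lacks columns {missing} (line 1)")
    widths = (df["end"] - df["start"]).unique()
    if len(widths) != 1:
        raise ValueError(f"bin table {path} has non-constant bin width: {sorted(widths)[:5]}")
    bin_size = int(widths[0])
    chroms = []
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        if not (np.diff(starts) == bin_size).all() or starts[0] != 0:
            first_bad = int(sub.index[0]) + 2
            raise ValueError(f"bin table {path}: bins not contiguous from 0 on {chrom} (line {first_bad})")
        chroms.append((str(chrom), int(sub["end"].max())))
    grid = build_grid(chroms, bin_size=bin_size)
    if grid.n_bins != len(df):
        raise ValueError(f"bin table {path} does not tile its chromosomes")
    return grid, df


def write_truth_bed(truth: Sequence[TruthCNA], path) -> None:
    with open(path, "w") as fh:
        for t in truth:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.copy_number}\n")


def read_truth_bed(path) -> list[TruthCNA]:
    out: list[TruthCNA] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"truth BED {path} line {ln}: need 4 columns (chrom start end copy_number)")
            out.append(TruthCNA(parts[0], int(parts[1]), int(parts[2]), int(parts[3])))
    return out


def write_seg(segments: Sequence[Segment], grid: BinGrid, path, sample: str = "sample") -> None:
    """SEG-style TSV: sample chrom start end n_bins seg_mean."""
    rows = [
        {
            "sample": sample,
            "chrom": s.chrom,
            "start": int(grid.starts[s.start_bin]),
            "end": int(grid.ends[s.end_bin - 1]),
            "n_bins": s.n_bins,
            "seg_mean": s.mean_ratio,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "n_bins", "seg_mean"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_calls_bed(calls: Sequence[CNACall], path) -> None:
    """BED+ calls: chrom start end copy_number log2_ratio direction n_bins."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tcopy_number\tlog2_ratio\tdirection\tn_bins\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.copy_number:.4f}\t"
                f"{c.log2_ratio:.4f}\t{c.direction}\t{c.n_bins}\n"
            )


def write_run_report(path, **sections) -> None:
    """JSON run report: parameters, versions and stage summaries."""
    from . import __version__

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        return str(o)

    payload = {"shallowcna_version": __version__, **sections}
    Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")
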