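"""Fixed-width genomic bin grids.

The bin grid is the coordinate backbone of the pipeline: every track
(read counts, GC fraction, mappability, normalized ratios) is a vector
aligned 1:1 with the bins of a :class:`BinGrid`.

Bins are non-overlapping, equal-width windows laid left to right along
each chromosome.  A trailing window shorter than ``bin_size`` is dropped,
so every bin has exactly ``bin_size`` base pairs and each chromosome
contributes ``floor(length / bin_size)`` bins.  Coordinates are 0-based,
half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_BIN_SIZE = 1_000_000


@dataclass(frozen=True)
class BinGrid:
    """Ordered genomic bins at fixed width.

    Attributes
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs the grid was built from.
    bin_size
        Bin width in base pairs.
    chrom_ids
        Per-bin integer index into ``chrom_names``.
    starts, ends
        Per-bin 0-based half-open coordinates.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int
    chrom_ids: np.ndarray = field(repr=False)
    starts: np.ndarray = field(repr=False)
    ends: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return int(self.chrom_ids.size)

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def chrom_slices(self) -> dict[str, slice]:
        """Map chromosome name -> slice of its bins (grid order)."""
        out: dict[str, slice] = {}
        ids = self.chrom_ids
        for k, (name, _) in enumerate(self.chromosomes):
            idx = np.flatnonzero(ids == k)
            if idx.size:
                out[name] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def bin_chroms(self) -> np.ndarray:
        """Per-bin chromosome name array."""
        names = np.asarray(self.chrom_names, dtype=object)
        return names[self.chrom_ids]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.bin_chroms(), "start": self.starts, "end": self.ends}
        )

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_bins


def build_grid(
    chromosomes: Sequence[tuple[str, int]] | Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> BinGrid:
    """Tile chromosomes with non-overlapping, equal-width bins.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs (or a mapping preserving
        insertion order).
    bin_size
        Window width in bp (default 1 Mb).

    Returns
    -------
    BinGrid
        ``floor(length / bin_size)`` bins per chromosome; the trailing
        partial window, if any, is dropped.

    Raises
    ------
    ValueError
        On non-positive bin size or chromosome length, or duplicate names.
    """
    if isinstance(chromosomes, Mapping):
        chromosomes = list(chromosomes.items())
    chromosomes = [(str(name), int(length)) for name, length in chromosomes]
    if int(bin_size) <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    bin_size = int(bin_size)
    names = [name for name, _ in chromosomes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names")
    for name, length in chromosomes:
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    chrom_ids: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    for k, (_, length) in enumerate(chromosomes):
        n = length // bin_size
        s = np.arange(n, dtype=np.int64) * bin_size
        starts.append(s)
        chrom_ids.append(np.full(n, k, dtype=np.int64))
    start = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
    ids = np.concatenate(chrom_ids) if chrom_ids else np.empty(0, dtype=np.int64)
    return BinGrid(
        chromosomes=tuple(chromosomes),
        bin_size=bin_size,
        chrom_ids=ids,
        starts=start,
        ends=start + bin_size,
    )


def load_chrom_lengths(path=None) -> list[tuple[str, int]]:
    """Read a 2-column ``chrom length`` TSV (header required).

    With no path, returns the packaged hg19 main-chromosome table
    (22 autosomes + X; the study's cell line is female, so Y is absent).
    """
    if path is None:
        ref = resources.files("shallowcna.data") / "hg19_chrom_lengths.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if not {"chrom", "length"}.issubset(df.columns):
        raise ValueError("chromosome-length table needs columns 'chrom' and 'length'")
    return [(str(r.chrom), int(r.length)) for r in df.itertuples()]


def hg19_grid(bin_size: int = DEFAULT_BIN_SIZE) -> BinGrid:
    """1 Mb-default grid over hg19 autosomes + X."""
    return build_grid(load_chrom_lengths(), bin_size=bin_size)
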