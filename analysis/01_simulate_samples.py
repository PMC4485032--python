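"""Simulate LOUCY-like shallow-sequencing samples under both WGA presets.

Generates one SurePlex-3-cell-like and one MALBAC-3-cell-like sample on
the hg19 1 Mb grid (autosomes + X) carrying the seven-region LOUCY truth
profile, plus shared GC and mappability tracks.  Full per-bin tables go
to scratch/samples/ (large, regenerable); a compact per-chromosome
overview and the raw-count noise estimates go to results/.
"""

from pathlib import Path

import pandas as pd

from shallowcna.grid import hg19_grid
from shallowcna.io import write_bin_table, write_truth_bed
from shallowcna.noise import first_order_variance
from shallowcna.preprocess import BinTrack
from shallowcna.simulate import (
    get_preset,
    loucy_truth,
    simulate_counts,
    simulate_gc_track,
    simulate_mappability_track,
)

SEED = 20150630
OUT = Path("results")
SCRATCH = Path("scratch/samples")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    grid = hg19_grid()
    truth = loucy_truth(grid)
    gc = simulate_gc_track(grid, seed=SEED)
    mp = simulate_mappability_track(grid, seed=SEED)
    write_truth_bed(truth, OUT / "01_loucy_truth.bed")

    rows = []
    for preset in ("sureplex-3cell", "malbac-3cell"):
        bias = get_preset(preset, seed=SEED)
        counts = simulate_counts(grid, truth, bias, gc_track=gc)
        write_bin_table(SCRATCH / f"{preset}.tsv", grid, counts, gc=gc, mappability=mp)
        noise = first_order_variance(BinTrack.from_values(grid, counts))
        print(
            f"{preset}: sigma_log={bias.sigma_log:.3f} rho={bias.rho} "
            f"total_reads={counts.sum():,} v={noise.v:.4f} (1/N={noise.counting_var:.5f})"
        )
        df = grid.to_frame().assign(count=counts)
        per_chrom = df.groupby("chrom", sort=False)["count"].mean().round(1)
        rows.append(per_chrom.rename(preset))
    overview = pd.concat(rows, axis=1)
    overview.to_csv(OUT / "01_sample_overview.tsv", sep="\t")
    print(f"\nper-chromosome mean counts -> {OUT / '01_sample_overview.tsv'}")
    print(overview.loc[["chr5", "chr6", "chr9", "chr13", "chr16", "chrX"]].to_string())


if __name__ == "__main__":
    main()
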