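"""Call CNAs on the simulated SurePlex-like LOUCY sample.

Runs the full pipeline (mappability correction, GC-LOESS normalization,
median scaling, CBS, negative-binomial threshold calling) on the sample
generated by 01_simulate_samples.py (regenerated here deterministically)
and scores the calls against the LOUCY truth profile.  Writes segments,
calls and the evaluation to results/; the per-bin profile table and the
genome plot go to scratch/ (large / binary).
"""

from pathlib import Path

from shallowcna.calling import profile_table
from shallowcna.cli import _plot_profile
from shallowcna.evaluate import match_calls
from shallowcna.grid import hg19_grid
from shallowcna.io import write_calls_bed, write_run_report, write_seg
from shallowcna.pipeline import run_pipeline
from shallowcna.segmentation import CBSParams
from shallowcna.simulate import (
    get_preset,
    loucy_truth,
    simulate_counts,
    simulate_gc_track,
    simulate_mappability_track,
)

SEED = 20150630
OUT = Path("results")
SCRATCH = Path("scratch")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    grid = hg19_grid()
    truth = loucy_truth(grid)
    gc = simulate_gc_track(grid, seed=SEED)
    mp = simulate_mappability_track(grid, seed=SEED)
    counts = simulate_counts(grid, truth, get_preset("sureplex-3cell", seed=SEED), gc_track=gc)

    result = run_pipeline(grid, counts, gc_track=gc, map_track=mp, cbs=CBSParams(seed=SEED))
    write_seg(result.segments, grid, OUT / "02_segments.seg", sample="sureplex-3cell")
    write_calls_bed(result.calls, OUT / "02_calls.bed")
    table = profile_table(result.profile, result.segments, result.model)
    table.to_csv(SCRATCH / "02_profile.tsv", sep="\t", index=False, float_format="%.6g")
    _plot_profile(table, SCRATCH / "02_profile.png", "sureplex-3cell LOUCY")

    report = match_calls(result.calls, truth)
    report.truth_table.to_csv(OUT / "02_truth_table.tsv", sep="\t", index=False)
    write_run_report(
        OUT / "02_run_report.json",
        command="analysis/02_call_loucy_profile.py",
        parameters={"preset": "sureplex-3cell", "seed": SEED},
        thresholds=result.model.to_dict(),
        noise=result.noise.to_dict(),
        evaluation=report.to_dict(),
    )

    print(f"N = {result.profile.N:.0f} reads/bin; thresholds "
          f"t_low={result.model.t_low:.3f} t_high={result.model.t_high:.3f} (ratio units)")
    print(f"{len(result.segments)} segments, {len(result.calls)} calls; "
          f"noise v={result.noise.v:.4f}, excess over 1/N: {result.noise.excess:.4f}")
    print(f"sensitivity={report.sensitivity:.3f} ppv={report.ppv}")
    for c in result.calls:
        print(f"  {c.chrom}:{c.start//10**6}-{c.end//10**6} Mb {c.direction} "
              f"CN={c.copy_number:.2f} log2={c.log2_ratio:.2f}")
    print(report.truth_table.to_string(index=False))


if __name__ == "__main__":
    main()
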