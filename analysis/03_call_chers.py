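#!/usr/bin/env python
"""Threshold the smoothed track and call ChIP-enriched regions (chers).

The threshold y0 is the 99th percentile of the maximum smoothed level of
the candidate regions (>= 7 consecutive probes above the median floor);
runs of >= 7 probes strictly above y0, merged when closer than 450 bp,
become chers.  Writes results/chers.tsv and results/chers.bed.
"""

import argparse

from pycher.cher_calling import (
    ThresholdSpec,
    call_chers_all,
    chers_to_bed,
    chers_to_table,
    compute_threshold,
)
from pycher.cli import _tracks_from_table


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--results", default="results")
    parser.add_argument("--quantile", type=float, default=0.99)
    args = parser.parse_args()

    tracks = _tracks_from_table(f"{args.results}/probes_smoothed.tsv", 450, 7)
    tr = compute_threshold(tracks, ThresholdSpec(quantile=args.quantile))
    chers = call_chers_all(tracks, tr.y0)

    table = chers_to_table(chers)
    table.to_csv(f"{args.results}/chers.tsv", sep="\t", index=False, float_format="%.6g")
    with open(f"{args.results}/chers.bed", "w") as fh:
        fh.write(chers_to_bed(chers))

    print(f"threshold y0 = {tr.y0:.4f} log2 "
          f"({args.quantile:.0%} quantile of {tr.n_candidates} candidate regions)")
    print(f"called {len(chers)} chers; "
          f"median span {int(table['cher_end'].sub(table['cher_start']).median())} bp, "
          f"median score {table['score'].median():.2f}")
    print(f"wrote {args.results}/chers.tsv and chers.bed")


if __name__ == "__main__":
    main()
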