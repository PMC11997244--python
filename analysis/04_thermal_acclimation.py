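#!/usr/bin/env python
"""PSII thermal-tolerance acclimation vs gene-set expression responses.

Reads the acclimation linear-model table produced by the pipeline run in
02_expression_responses.py and writes the top-10 associations per trait
(heat traits against the hot-vs-control fold change, cold traits against
cold-vs-control) under results/, mirroring the trait-by-trait reporting of
the acclimation analysis.
"""

import argparse
from pathlib import Path

import pandas as pd

from thermoresp import models as mdl
from thermoresp.io_tables import write_tsv

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--pipeline", type=Path, default=ROOT / "scratch" / "pipeline")
    ap.add_argument("--top", type=int, default=10)
    args = ap.parse_args()
    path = args.pipeline / "acclimation_results.tsv"
    if not path.exists():
        raise SystemExit("run 02_expression_responses.py first")

    ar = pd.read_csv(path, sep="\t")
    deltas = pd.read_csv(args.pipeline / "acclimation_deltas.tsv", sep="\t")
    results_dir = ROOT / "results"
    frames = []
    for trait in ("Tcrit_hot", "Tmax_hot", "Tcrit_cold", "Tmax_cold"):
        sub = ar[ar.trait == trait]
        if sub.empty:
            continue
        ranked = mdl.rank_results(sub, by="adj_r2", top_k=args.top)
        frames.append(ranked)
        top = ranked.iloc[0]
        print(f"{trait}: top association {top.set_id} "
              f"(adj R2={top.adj_r_squared:.2f}, t={top.t:.2f}, "
              f"p={top.p_value:.3g}, min n={int(top.min_n)}, "
              f"FC median {top.fc_median:+.2f} "
              f"[{top.fc_min:+.2f}, {top.fc_max:+.2f}])")
    write_tsv(pd.concat(frames, ignore_index=True),
              results_dir / "acclimation_top_associations.tsv")
    write_tsv(deltas, results_dir / "acclimation_deltas.tsv")
    print(f"species acclimation deltas and top associations in {results_dir}")


if __name__ == "__main__":
    main()
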