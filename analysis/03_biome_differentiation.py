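#!/usr/bin/env python
"""Biome differentiation of fold-change responses.

Reads the species-level bootstrapped fold changes produced by
02_expression_responses.py, ranks the biome linear models, and writes the
biome x treatment group means (the species-by-treatment averages) under
results/.
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
    biome_results = args.pipeline / "biome_results.tsv"
    if not biome_results.exists():
        raise SystemExit("run 02_expression_responses.py first")

    br = pd.read_csv(biome_results, sep="\t")
    summary = pd.read_csv(args.pipeline / "biome_fc_summary.tsv", sep="\t")
    results_dir = ROOT / "results"
    for contrast in ("HvsN", "CvsN"):
        sub = br[br.contrast == contrast].rename(columns={"r_squared": "adj_r_squared"})
        ranked = mdl.rank_results(sub, by="adj_r2", top_k=args.top)
        ranked = ranked.rename(columns={"adj_r_squared": "r_squared"})
        write_tsv(ranked, results_dir / f"biome_top_{contrast}.tsv")
        top = ranked.iloc[0]
        means = summary[(summary.set_id == top.set_id) & (summary.contrast == contrast)]
        print(f"{contrast}: strongest biome differentiation {top.set_id} "
              f"(R2={top.r_squared:.2f}, p={top.p_value:.3f})")
        for _, row in means.iterrows():
            print(f"    {row.biome:<10} mean FC {row['mean']:+.2f} "
                  f"(SE {row.se:.2f}, n={int(row.n)})")
    write_tsv(summary, results_dir / "biome_fc_group_means.tsv")


if __name__ == "__main__":
    main()
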