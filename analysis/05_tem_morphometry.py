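#!/usr/bin/env python
"""Morphometry arm: rule-based AP/AL classification of annotated vesicles,
per-cell autophagy summaries (counts, maturation, AP area fractions,
mitochondrial counts/areas), and stratified Student comparisons across age
and naive/memory subset.
"""

import argparse
from pathlib import Path

from immunoflux import io as ifio
from immunoflux.pipeline import run_morphometry_arm


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study-dir", type=Path, default=Path("results/synthetic_study"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    morpho = args.study_dir / "morphometry"
    cells = ifio.read_cells(morpho / "vesicles.tsv", morpho / "mitochondria.tsv", morpho / "cells.tsv")
    res = run_morphometry_arm(cells)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    res["summaries"].round(4).to_csv(args.out_dir / "morphometry_summaries.tsv", sep="\t", index=False)
    res["comparisons"].round(4).to_csv(args.out_dir / "morphometry_comparisons.tsv", sep="\t", index=False)

    summ = res["summaries"]
    print(summ.groupby(["age_group", "subset"])[["ap_count", "al_count", "av_count", "maturation_pct", "mito_count"]]
          .mean().round(2))
    comp = res["comparisons"].set_index(["contrast", "metric"])
    for metric in ("ap_count", "av_count", "maturation_pct"):
        row = comp.loc[("young_vs_old_in_naive", metric)]
        print(f"naive young vs old, {metric}: {row['mean_a']:.2f} vs {row['mean_b']:.2f}, p = {row['p_value']:.4g}")


if __name__ == "__main__":
    main()
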