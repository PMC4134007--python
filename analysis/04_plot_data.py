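#!/usr/bin/env python
"""Summarize the Manhattan-style plot export and the threshold lines.

The pipeline already writes results/pipeline/plot_data.tsv (one x position
per phenotype, category-contiguous blocks, -log10 p, triangle = unadjusted /
dot = BMI-adjusted markers); this driver verifies its invariants and prints
what a plotting layer would draw.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    outdir = ROOT / "results" / "pipeline"
    plot = pd.read_csv(outdir / "plot_data.tsv", sep="\t", dtype={"phecode": str})
    with open(outdir / "thresholds.json") as fh:
        ts = json.load(fh)
    assert (plot.groupby("phecode")["x"].nunique() == 1).all()
    # TSV stores 6 significant digits, so compare with matching slack
    assert np.allclose(plot["neg_log10_p"], -np.log10(plot["p"]), atol=5e-4)
    print(f"{plot['phecode'].nunique()} phenotypes across "
          f"{plot['category'].nunique()} categories; "
          f"{len(plot)} plotted points (unadjusted + adjusted)")
    print(f"threshold lines: bonferroni -log10 p = "
          f"{-np.log10(ts['bonferroni_p']):.3f}, "
          f"BH = {-np.log10(ts['bh_p']):.3f}" if ts["bh_p"] > 0 else
          "no BH discoveries")
    above = plot[plot["p"] <= ts["bonferroni_p"]]
    print("points above the Bonferroni line:")
    print(above[["x", "phecode", "description", "bmi_adjusted", "or",
                 "neg_log10_p"]].to_string(index=False,
                                           float_format=lambda v: f"{v:.3g}"))


if __name__ == "__main__":
    main()
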